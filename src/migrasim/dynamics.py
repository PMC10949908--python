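"""Daily perception-decision loop for conflict-induced migration.

Each simulated day, every not-yet-migrated person perceives past conflict
events through a spatio-temporally decaying impact kernel, accumulates a
memory-retained perceived impact scaled by their risk proneness, and converts
it to an individual migration probability through a logistic function
(attitude and perceived behavior control). Households average their members'
probabilities, draw a Bernoulli initial decision, and a synchronous
peer-threshold pass over the household network can force migration on or off
(subjective norm). Migrating households are classified refugee or internally
displaced (IDP), recorded, and removed from all subsequent dynamics.

The model covers initial displacement only: no destinations, no return or
onward migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._geo import haversine_km
from .population import ConfigurationError, NeighborhoodGraph

__all__ = [
    "ModelParameters",
    "Trajectory",
    "event_impact",
    "attitude",
    "perceived_impact",
    "migration_probability",
    "household_probability",
    "sample_initial_decision",
    "apply_peer_threshold",
    "classify_destination",
    "run_simulation",
]


def _kernel_pow(base, exponent: float):
    """x**a for positive x via exp(a*log(x)).

    The exp/log composition gives bitwise-identical results whether evaluated
    elementwise on arrays or on scalars, which keeps the vectorized engine
    exactly reproducible against scalar reference computations.
    """
    return np.exp(exponent * np.log(base))


@dataclass(frozen=True)
class ModelParameters:
    """Tunable parameters of the migration model.

    tau, delta : float
        Temporal and spatial decay exponents of the impact kernel (both > 1).
    theta : float
        Daily memory retention of perceived impact, in [0, 1].
    v : float
        Logistic growth rate: how fast migration intent rises with perceived
        impact. The effective rate is v*b*w; the bias scale b and conflict
        scale w are carried for completeness but fold into v and default to 1.
    Q : float
        No-risk migration control: with zero perceived impact the daily
        migration probability is 1/(1+Q).
    i_hi, i_lo : int
        Peer thresholds: a household is forced to migrate when more than
        ``i_hi`` neighbors made an initial go decision, forced to stay when
        fewer than ``i_lo`` did.
    refugee_prob : float
        Probability a migrating household crosses a border (refugee) rather
        than displacing internally (IDP).
    decision_lag : int
        Days between the migration decision and the counted border crossing.
    martial_law : bool
        If set, households whose only adults are males aged 18-60 never leave
        the country (always IDP), mirroring exit restrictions on men of
        conscription age.
    dt_floor, ds_floor_km : float
        Floors on elapsed days and distance in the kernel denominator,
        preventing unbounded impact at an event's time or location.
    event_horizon_days : int
        Events older than this are dropped from the attitude sum.
    min_impact : float
        Per-event contributions below this are treated as zero.
    """

    tau: float = 2.0
    delta: float = 2.0
    theta: float = 0.5
    v: float = 1.0
    Q: float = 500.0
    i_hi: int = 1000
    i_lo: int = 0
    b: float = 1.0
    w: float = 1.0
    refugee_prob: float = 0.6
    decision_lag: int = 0
    martial_law: bool = False
    dt_floor: float = 1.0
    ds_floor_km: float = 1.0
    event_horizon_days: int = 30
    min_impact: float = 1e-9

    def __post_init__(self) -> None:
        if not self.tau > 1 or not self.delta > 1:
            raise ConfigurationError("decay exponents tau and delta must exceed 1")
        if not 0.0 <= self.theta <= 1.0:
            raise ConfigurationError("theta must be in [0, 1]")
        if self.v <= 0 or self.Q <= 0:
            raise ConfigurationError("v and Q must be positive")
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.w <= 1.0):
            raise ConfigurationError("scale parameters b, w must be in [0, 1]")
        if self.i_hi < 0 or self.i_lo < 0 or self.i_lo > self.i_hi:
            raise ConfigurationError("thresholds must satisfy 0 <= i_lo <= i_hi")
        if not 0.0 <= self.refugee_prob <= 1.0:
            raise ConfigurationError("refugee_prob must be in [0, 1]")
        if self.decision_lag < 0:
            raise ConfigurationError("decision_lag must be nonnegative")
        if self.dt_floor <= 0 or self.ds_floor_km <= 0:
            raise ConfigurationError("kernel floors must be positive")

    @property
    def effective_growth_rate(self) -> float:
        """v scaled by the bias and conflict scales (the v = z*b*w folding)."""
        return self.v * self.b * self.w

    def with_values(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Elementary operations (scalar or vectorized)


def event_impact(intensity, dt_days, ds_km, tau: float, delta: float,
                 dt_floor: float = 1.0, ds_floor_km: float = 1.0):
    """Observed impact of one event: I / (dT^tau * dS^delta).

    ``dt_days`` is the elapsed time t - T_j (must be positive: only past
    events are observed) and ``ds_km`` the agent-event distance; both are
    floored before exponentiation.
    """
    dt_days = np.asarray(dt_days, dtype=float)
    if np.any(dt_days <= 0):
        raise ValueError("event_impact requires a strictly past event (dt > 0)")
    dt = np.maximum(dt_days, dt_floor)
    ds = np.maximum(np.asarray(ds_km, dtype=float), ds_floor_km)
    return np.asarray(intensity, dtype=float) / (_kernel_pow(dt, tau) * _kernel_pow(ds, delta))


def attitude(agent_lat, agent_lon, events: pd.DataFrame, t: int, params: ModelParameters):
    """Attitude toward risk at day t: sum of impacts of events with T_j < t.

    Events older than ``params.event_horizon_days`` and contributions below
    ``params.min_impact`` are dropped. Returns 0 for an empty event set.
    """
    total = 0.0
    for _, ev in events.iterrows():
        dt = t - int(ev["day"])
        if dt <= 0 or dt > params.event_horizon_days:
            continue
        ds = haversine_km(agent_lat, agent_lon, ev["latitude"], ev["longitude"])
        f = float(event_impact(ev["intensity"], dt, ds, params.tau, params.delta,
                               params.dt_floor, params.ds_floor_km))
        if f >= params.min_impact:
            total += f
    return total


def perceived_impact(f, f_prev, beta: float, theta: float):
    """Perceived behavior control recursion: f~(t) = beta*f(t) + theta*f~(t-1)."""
    return beta * np.asarray(f, dtype=float) + theta * np.asarray(f_prev, dtype=float)


def migration_probability(f_tilde, v: float, Q: float):
    """Logistic conversion of perceived impact: p' = 1/(1 + Q e^{-v f~})."""
    return 1.0 / (1.0 + Q * np.exp(-v * np.asarray(f_tilde, dtype=float)))


def household_probability(member_p_primes) -> float:
    """Household migration probability: arithmetic mean of member probabilities."""
    ps = np.asarray(member_p_primes, dtype=float)
    if ps.size == 0:
        raise ValueError("household has no members")
    return float(ps.sum() / ps.size)


def sample_initial_decision(p: float, rng: np.random.Generator) -> int:
    """Bernoulli(p) initial household decision."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    return int(rng.random() < p)


def apply_peer_threshold(m_initial_self, neighbor_sum, i_hi: int, i_lo: int):
    """Inter-household threshold override of the initial decision.

    More than ``i_hi`` initially-deciding neighbors force migration; fewer
    than ``i_lo`` force staying; boundary sums keep the household's own
    initial decision. Operates on same-day initial decisions only.
    """
    if i_lo > i_hi:
        raise ConfigurationError("i_lo must not exceed i_hi")
    s = np.asarray(neighbor_sum)
    m0 = np.asarray(m_initial_self)
    return np.where(s > i_hi, 1, np.where(s < i_lo, 0, m0))


def classify_destination(
    rng_value: float,
    refugee_prob: float,
    martial_law: bool = False,
    only_adults_are_conscription_age_males: bool = False,
) -> str:
    """Classify a just-migrated household as 'refugee' or 'idp'.

    Under martial law a household whose only adults are males aged 18-60
    cannot cross the border and is always IDP. Otherwise refugee with
    probability ``refugee_prob`` (``rng_value`` is a uniform draw).
    """
    if martial_law and only_adults_are_conscription_age_males:
        return "idp"
    return "refugee" if rng_value < refugee_prob else "idp"


# ---------------------------------------------------------------------------
# Simulation engine


@dataclass
class Trajectory:
    """Per-person ledger of migrations plus run metadata.

    ``records`` columns: day (decision day), crossing_day (day + lag),
    household_id, person_id, age, gender, admin1, admin2, migration_type.
    """

    records: pd.DataFrame
    horizon: int
    seed: int
    n_persons: int
    n_households: int
    params: ModelParameters
    state_history: list | None = field(default=None, repr=False)

    RECORD_COLUMNS = [
        "day", "crossing_day", "household_id", "person_id",
        "age", "gender", "admin1", "admin2", "migration_type",
    ]

    def household_records(self) -> pd.DataFrame:
        """One row per migrated household."""
        if self.records.empty:
            return self.records.iloc[0:0]
        return self.records.drop_duplicates("household_id")

    def migrated_person_count(self, migration_type: str | None = None) -> int:
        r = self.records
        if migration_type is not None:
            r = r[r["migration_type"] == migration_type]
        return int(len(r))

    def write_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day": pd.Series(dtype=np.int64),
            "crossing_day": pd.Series(dtype=np.int64),
            "household_id": pd.Series(dtype=np.int64),
            "person_id": pd.Series(dtype=np.int64),
            "age": pd.Series(dtype=np.int64),
            "gender": pd.Series(dtype=object),
            "admin1": pd.Series(dtype=object),
            "admin2": pd.Series(dtype=object),
            "migration_type": pd.Series(dtype=object),
        }
    )


def _adjacency_matrix(graph: NeighborhoodGraph, household_ids: np.ndarray) -> sp.csr_matrix:
    index = {int(h): i for i, h in enumerate(household_ids)}
    rows, cols = [], []
    for h, nbrs in graph.adjacency.items():
        i = index[int(h)]
        for u in nbrs:
            rows.append(i)
            cols.append(index[int(u)])
    n = len(household_ids)
    data = np.ones(len(rows), dtype=np.int64)
    return sp.csr_matrix((data, (rows, cols)), shape=(n, n))


def run_simulation(
    persons: pd.DataFrame,
    households: pd.DataFrame,
    graph: NeighborhoodGraph,
    events: pd.DataFrame,
    params: ModelParameters,
    horizon: int,
    seed: int,
    record_state: bool = False,
) -> Trajectory:
    """Run the daily loop for t = 1..horizon; reproducible from ``seed``.

    Update order within a day: impact kernel and attitude sum, perceived
    impact recursion, logistic individual probability, household averaging,
    Bernoulli initial decision, one synchronous peer-threshold pass reading
    initial decisions only, refugee/IDP classification, then removal of
    migrated households.

    Randomness: one generator seeded with ``seed``; each day consumes two
    uniform vectors over all households in ascending household-id order (the
    decision draws, then the classification draws), so runs are bitwise
    reproducible and entries for frozen households are burned but unused.
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")

    households = households.sort_values("household_id", kind="stable").reset_index(drop=True)
    persons = persons.sort_values(["household_id", "person_id"], kind="stable").reset_index(drop=True)
    if "risk_proneness" not in persons.columns:
        persons = persons.assign(risk_proneness=1.0)

    h_ids = households["household_id"].to_numpy()
    h_index = {int(h): i for i, h in enumerate(h_ids)}
    n_h = len(h_ids)
    n_p = len(persons)
    hidx = persons["household_id"].map(h_index).to_numpy(dtype=np.int64)
    beta = persons["risk_proneness"].to_numpy(dtype=float)
    member_counts = np.bincount(hidx, minlength=n_h).astype(float)
    if (member_counts == 0).any():
        raise ConfigurationError("every household needs at least one member")

    h_lat = households["latitude"].to_numpy(dtype=float)
    h_lon = households["longitude"].to_numpy(dtype=float)

    # martial-law eligibility: only adults present are males aged 18-60
    age = persons["age"].to_numpy()
    is_adult = age >= 18
    is_male_1860 = (persons["gender"].to_numpy() == "male") & (age >= 18) & (age <= 60)
    adults_per_h = np.bincount(hidx, weights=is_adult.astype(float), minlength=n_h)
    male1860_adults_per_h = np.bincount(hidx, weights=(is_adult & is_male_1860).astype(float), minlength=n_h)
    martial_idp = (adults_per_h > 0) & (adults_per_h == male1860_adults_per_h)

    adj = _adjacency_matrix(graph, h_ids)

    events = events.sort_values(["day", "event_id"], kind="stable").reset_index(drop=True)
    ev_day = events["day"].to_numpy(dtype=np.int64) if len(events) else np.empty(0, dtype=np.int64)
    ev_int = events["intensity"].to_numpy(dtype=float) if len(events) else np.empty(0)
    ds_cache: dict[int, np.ndarray] = {}

    def distances(j: int) -> np.ndarray:
        if j not in ds_cache:
            d = haversine_km(h_lat, h_lon, events.at[j, "latitude"], events.at[j, "longitude"])
            ds_cache[j] = np.maximum(d, params.ds_floor_km)
        return ds_cache[j]

    rng = np.random.default_rng(seed)
    active = np.ones(n_h, dtype=bool)
    f_tilde = np.zeros(n_p)  # f~(i, 0) = 0
    v_eff = params.effective_growth_rate

    mig_day = np.full(n_h, -1, dtype=np.int64)
    mig_type = np.empty(n_h, dtype=object)
    history = [] if record_state else None

    for t in range(1, horizon + 1):
        # attitude: sum of floored-kernel impacts of recent past events
        f_house = np.zeros(n_h)
        recent = np.nonzero((ev_day < t) & (t - ev_day <= params.event_horizon_days))[0]
        for j in recent:
            dt = max(float(t - ev_day[j]), params.dt_floor)
            contrib = ev_int[j] / (_kernel_pow(dt, params.tau) * _kernel_pow(distances(j), params.delta))
            contrib[contrib < params.min_impact] = 0.0
            f_house += contrib

        # perceived behavior control + logistic intent (active persons only)
        person_active = active[hidx]
        f_person = f_house[hidx]
        f_tilde = np.where(person_active, beta * f_person + params.theta * f_tilde, f_tilde)
        p_prime = 1.0 / (1.0 + params.Q * np.exp(-v_eff * f_tilde))

        # intra-household averaging and Bernoulli initial decision
        p_house = np.bincount(hidx, weights=np.where(person_active, p_prime, 0.0), minlength=n_h) / member_counts
        u_decision = rng.random(n_h)
        m_init = active & (u_decision < p_house)

        # synchronous peer-threshold pass over initial decisions
        neighbor_sum = adj @ m_init.astype(np.int64)
        m_final = np.where(
            neighbor_sum > params.i_hi, True,
            np.where(neighbor_sum < params.i_lo, False, m_init),
        ).astype(bool) & active

        # classification and removal
        u_class = rng.random(n_h)
        new = np.nonzero(m_final)[0]
        for k in new:
            if params.martial_law and martial_idp[k]:
                mig_type[k] = "idp"
            else:
                mig_type[k] = "refugee" if u_class[k] < params.refugee_prob else "idp"
            mig_day[k] = t
        active[new] = False

        if record_state:
            history.append(
                {
                    "day": t,
                    "f_house": f_house.copy(),
                    "f_tilde": f_tilde.copy(),
                    "p_prime": p_prime.copy(),
                    "p_house": p_house.copy(),
                    "m_initial": m_init.copy(),
                    "m_final": m_final.copy(),
                    "newly_migrated": h_ids[new].copy(),
                }
            )

    migrated = mig_day >= 0
    person_migrated = migrated[hidx]
    if person_migrated.any():
        sel = persons[person_migrated]
        sel_h = hidx[person_migrated]
        records = pd.DataFrame(
            {
                "day": mig_day[sel_h],
                "crossing_day": mig_day[sel_h] + params.decision_lag,
                "household_id": sel["household_id"].to_numpy(),
                "person_id": sel["person_id"].to_numpy(),
                "age": sel["age"].to_numpy(),
                "gender": sel["gender"].to_numpy(),
                "admin1": households["admin1"].to_numpy()[sel_h],
                "admin2": households["admin2"].to_numpy()[sel_h],
                "migration_type": mig_type[sel_h],
            }
        ).sort_values(["day", "household_id", "person_id"], kind="stable").reset_index(drop=True)
    else:
        records = _empty_records()

    return Trajectory(
        records=records,
        horizon=horizon,
        seed=seed,
        n_persons=n_p,
        n_households=n_h,
        params=params,
        state_history=history,
    )
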