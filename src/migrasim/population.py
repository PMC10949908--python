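"""Synthetic population generation, I/O, and the household neighborhood network.

A population is a pair of tables: ``persons`` (one row per individual with
demographic attributes) partitioned into ``households`` (one row per household
with a WGS84 location and admin-1/admin-2 region labels). Every person belongs
to exactly one household and shares its location. Households are linked into a
spatial neighborhood network used by the inter-household peer-effect rule of
the migration engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geo import chord_length, haversine_km, to_unit_sphere

PERSON_COLUMNS = ["person_id", "household_id", "age", "gender"]
HOUSEHOLD_COLUMNS = ["household_id", "latitude", "longitude", "admin1", "admin2"]

#: Default age bins: children, working-age adults, elderly.
DEFAULT_AGE_BINS: tuple[tuple[str, int, int], ...] = (
    ("child", 0, 17),
    ("adult", 18, 64),
    ("elderly", 65, 200),
)

_KM_PER_DEG_LAT = 111.32


class SchemaError(ValueError):
    """A population table violates the persons/households schema."""


class ConfigurationError(ValueError):
    """An invalid generator or model configuration value."""


@dataclass(frozen=True)
class Region:
    """A spatial cluster of households around an (admin1, admin2) centroid."""

    admin1: str
    admin2: str
    latitude: float
    longitude: float
    dispersion_km: float
    weight: float


@dataclass
class PopulationConfig:
    """Configuration of the synthetic population generator.

    ``household_size_probs[i]`` is the probability of household size ``i+1``.
    ``age_pyramid`` lists ``(lo, hi, prob)`` inclusive age ranges; ages are
    uniform within the sampled range. ``female_fraction`` is the marginal
    probability of a person being female.
    """

    n_households: int
    household_size_probs: Sequence[float]
    age_pyramid: Sequence[tuple[int, int, float]]
    female_fraction: float
    regions: Sequence[Region]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_households <= 0:
            raise ConfigurationError("n_households must be positive")
        for name, probs in (
            ("household_size_probs", list(self.household_size_probs)),
            ("age_pyramid", [p for _, _, p in self.age_pyramid]),
        ):
            probs = np.asarray(probs, dtype=float)
            if probs.size == 0 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be a probability vector summing to 1")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError("female_fraction must be in [0, 1]")
        if not self.regions:
            raise ConfigurationError("at least one region is required")
        if sum(r.weight for r in self.regions) <= 0:
            raise ConfigurationError("region weights must have positive sum")

    @property
    def mean_household_size(self) -> float:
        sizes = np.arange(1, len(self.household_size_probs) + 1)
        return float(sizes @ np.asarray(self.household_size_probs, dtype=float))


def default_config(n_households: int = 1000, seed: int = 0) -> PopulationConfig:
    """A small country-like default: two urban and two rural clusters.

    Marginals emulate a war-affected eastern European population: mean
    household size ~2.4, ~54% female, ~18% children and ~18% elderly.
    """
    return PopulationConfig(
        n_households=n_households,
        household_size_probs=(0.30, 0.30, 0.18, 0.13, 0.06, 0.03),
        age_pyramid=((0, 17, 0.18), (18, 64, 0.64), (65, 94, 0.18)),
        female_fraction=0.538,
        regions=(
            Region("East", "East-City", 49.99, 36.23, 8.0, 0.35),
            Region("East", "East-Rural", 49.60, 36.80, 25.0, 0.15),
            Region("Capital", "Capital-City", 50.45, 30.52, 10.0, 0.30),
            Region("West", "West-Rural", 49.84, 24.03, 30.0, 0.20),
        ),
        seed=seed,
    )


def generate_population(config: PopulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a synthetic population; deterministic given ``config.seed``.

    Returns ``(persons, households)`` DataFrames following the schema in
    :data:`PERSON_COLUMNS` / :data:`HOUSEHOLD_COLUMNS`.
    """
    rng = np.random.default_rng(config.seed)
    n_h = config.n_households

    size_probs = np.asarray(config.household_size_probs, dtype=float)
    sizes = rng.choice(np.arange(1, size_probs.size + 1), size=n_h, p=size_probs)

    weights = np.asarray([r.weight for r in config.regions], dtype=float)
    region_idx = rng.choice(len(config.regions), size=n_h, p=weights / weights.sum())

    lat = np.empty(n_h)
    lon = np.empty(n_h)
    admin1 = np.empty(n_h, dtype=object)
    admin2 = np.empty(n_h, dtype=object)
    for i, region in enumerate(config.regions):
        mask = region_idx == i
        n = int(mask.sum())
        if n == 0:
            continue
        dlat_km = rng.normal(0.0, region.dispersion_km, size=n)
        dlon_km = rng.normal(0.0, region.dispersion_km, size=n)
        lat[mask] = region.latitude + dlat_km / _KM_PER_DEG_LAT
        lon[mask] = region.longitude + dlon_km / (
            _KM_PER_DEG_LAT * np.cos(np.radians(region.latitude))
        )
        admin1[mask] = region.admin1
        admin2[mask] = region.admin2

    households = pd.DataFrame(
        {
            "household_id": np.arange(n_h, dtype=np.int64),
            "latitude": lat,
            "longitude": lon,
            "admin1": admin1,
            "admin2": admin2,
        }
    )

    n_persons = int(sizes.sum())
    household_id = np.repeat(households["household_id"].to_numpy(), sizes)

    bins = list(config.age_pyramid)
    bin_probs = np.asarray([p for _, _, p in bins], dtype=float)
    bin_idx = rng.choice(len(bins), size=n_persons, p=bin_probs / bin_probs.sum())
    lo = np.asarray([b[0] for b in bins])[bin_idx]
    hi = np.asarray([b[1] for b in bins])[bin_idx]
    ages = rng.integers(lo, hi + 1)

    gender = np.where(rng.random(n_persons) < config.female_fraction, "female", "male")

    persons = pd.DataFrame(
        {
            "person_id": np.arange(n_persons, dtype=np.int64),
            "household_id": household_id,
            "age": ages.astype(np.int64),
            "gender": gender,
        }
    )
    return persons, households


def age_bin_labels(ages: Iterable[int], age_bins=DEFAULT_AGE_BINS) -> np.ndarray:
    """Map ages to bin labels (vectorized)."""
    ages = np.asarray(list(ages) if not isinstance(ages, np.ndarray) else ages)
    out = np.empty(ages.shape, dtype=object)
    out[:] = None
    for label, lo, hi in age_bins:
        out[(ages >= lo) & (ages <= hi)] = label
    if (out == None).any():  # noqa: E711 - object array comparison
        raise ConfigurationError("age bins do not cover all ages")
    return out


def assign_risk_proneness(
    persons: pd.DataFrame,
    group_map: Mapping,
    age_bins=DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Attach a group-level risk-proneness multiplier beta to each person.

    ``group_map`` maps either an age-bin label (e.g. ``"child"``) or an
    ``(age-bin, gender)`` tuple to a positive multiplier; tuple keys take
    precedence. Higher beta means the same conflict impact is perceived more
    strongly (children and the elderly are typically more affected).
    Idempotent: re-running overwrites the ``risk_proneness`` column.
    """
    for key, value in group_map.items():
        if value <= 0:
            raise ConfigurationError(f"risk-proneness multiplier for {key!r} must be positive")
    labels = age_bin_labels(persons["age"].to_numpy(), age_bins)
    beta = np.empty(len(persons), dtype=float)
    genders = persons["gender"].to_numpy()
    for i, (label, gender) in enumerate(zip(labels, genders)):
        if (label, gender) in group_map:
            beta[i] = group_map[(label, gender)]
        elif label in group_map:
            beta[i] = group_map[label]
        else:
            raise ConfigurationError(f"no risk-proneness entry for group {(label, gender)!r}")
    persons = persons.copy()
    persons["risk_proneness"] = beta
    return persons


# ---------------------------------------------------------------------------
# Neighborhood network


@dataclass
class NeighborhoodGraph:
    """Symmetric household adjacency: ``adjacency[h]`` is the set N(h)."""

    adjacency: dict[int, frozenset[int]] = field(default_factory=dict)

    def neighbors(self, household_id: int) -> frozenset[int]:
        return self.adjacency.get(household_id, frozenset())

    def degree(self, household_id: int) -> int:
        return len(self.neighbors(household_id))

    def validate(self) -> None:
        ids = set(self.adjacency)
        for h, nbrs in self.adjacency.items():
            if h in nbrs:
                raise SchemaError(f"self-loop at household {h}")
            for u in nbrs:
                if u not in ids:
                    raise SchemaError(f"neighbor {u} of {h} is not a known household")
                if h not in self.adjacency[u]:
                    raise SchemaError(f"asymmetric edge {h}-{u}")


def build_neighborhood(
    households: pd.DataFrame,
    radius_km: float = 1.0,
    max_neighbors: int = 20,
    rule: Callable[[pd.DataFrame], dict[int, frozenset[int]]] | None = None,
) -> NeighborhoodGraph:
    """Construct the household peer network.

    Default rule: households within ``radius_km`` (haversine) are neighbors,
    each household keeps at most its ``max_neighbors`` nearest, and the graph
    is re-symmetrized by keeping only mutual edges so the degree cap holds
    exactly. A custom ``rule`` may replace the default entirely.
    """
    if rule is not None:
        return NeighborhoodGraph(adjacency=rule(households))
    if radius_km <= 0:
        raise ConfigurationError("radius_km must be positive")
    if max_neighbors < 0:
        raise ConfigurationError("max_neighbors must be nonnegative")

    ids = households["household_id"].to_numpy()
    lat = households["latitude"].to_numpy(dtype=float)
    lon = households["longitude"].to_numpy(dtype=float)
    n = len(ids)
    kept: list[set[int]] = [set() for _ in range(n)]

    if n > 1 and max_neighbors > 0:
        tree = cKDTree(to_unit_sphere(lat, lon))
        pairs = tree.query_pairs(chord_length(radius_km), output_type="ndarray")
        if len(pairs):
            d = haversine_km(lat[pairs[:, 0]], lon[pairs[:, 0]], lat[pairs[:, 1]], lon[pairs[:, 1]])
            within = d <= radius_km
            pairs, d = pairs[within], d[within]
            candidates: list[list[tuple[float, int]]] = [[] for _ in range(n)]
            for (i, j), dist in zip(pairs, d):
                candidates[i].append((dist, j))
                candidates[j].append((dist, i))
            for i, cand in enumerate(candidates):
                cand.sort()
                kept[i] = {j for _, j in cand[:max_neighbors]}
            # mutual-kNN re-symmetrization: keep an edge only if both ends kept it
            kept = [{j for j in kept[i] if i in kept[j]} for i in range(n)]

    adjacency = {int(ids[i]): frozenset(int(ids[j]) for j in kept[i]) for i in range(n)}
    graph = NeighborhoodGraph(adjacency=adjacency)
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# I/O


def validate_population(persons: pd.DataFrame, households: pd.DataFrame) -> None:
    """Check schema and referential integrity; raise :class:`SchemaError`."""
    for col in PERSON_COLUMNS:
        if col not in persons.columns:
            raise SchemaError(f"persons table missing column {col!r}")
    for col in HOUSEHOLD_COLUMNS:
        if col not in households.columns:
            raise SchemaError(f"households table missing column {col!r}")
    if persons["person_id"].duplicated().any():
        raise SchemaError("duplicate person_id")
    if households["household_id"].duplicated().any():
        raise SchemaError("duplicate household_id")
    known = set(households["household_id"])
    orphans = set(persons["household_id"]) - known
    if orphans:
        raise SchemaError(f"persons reference unknown households: {sorted(orphans)[:5]}")
    empty = known - set(persons["household_id"])
    if empty:
        raise SchemaError(f"households with no members: {sorted(empty)[:5]}")
    if (persons["age"] < 0).any():
        raise SchemaError("negative age")
    bad = set(persons["gender"]) - {"male", "female"}
    if bad:
        raise SchemaError(f"unknown gender values: {bad}")
    if "risk_proneness" in persons.columns and (persons["risk_proneness"] <= 0).any():
        raise SchemaError("risk_proneness must be positive")


def write_population(persons: pd.DataFrame, households: pd.DataFrame, persons_csv, households_csv) -> None:
    validate_population(persons, households)
    persons.to_csv(persons_csv, index=False)
    households.to_csv(households_csv, index=False)


def read_population(persons_csv, households_csv) -> tuple[pd.DataFrame, pd.DataFrame]:
    persons = pd.read_csv(persons_csv)
    households = pd.read_csv(households_csv)
    validate_population(persons, households)
    return persons, households
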