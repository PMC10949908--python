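"""Coordinate-descent calibration of the migration model.

The model is fitted to an observed daily border-crossing series by cycling
over free parameters one at a time: each line search evaluates a bounded grid
of candidate values, keeps the argmin, and the cycle repeats until a full
pass improves the loss by less than a tolerance. The objective simulates a
fixed number of replicate trajectories, averages their daily refugee series,
smooths both series with a moving average, and returns the RMSE (default) or
1 - Pearson correlation. Common random numbers — the same replicate seed
stream for every evaluation — keep the objective a deterministic function of
the parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import ModelParameters, run_simulation
from .population import ConfigurationError, NeighborhoodGraph
from .reporting import daily_series, moving_average

INTEGER_PARAMETERS = {"i_hi", "i_lo"}
CALIBRATABLE = ("tau", "delta", "theta", "v", "Q", "i_hi", "i_lo")


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance or length < 2)."""


def pcc(series_a, series_b) -> float:
    """Pearson correlation coefficient between two equal-length series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise UndefinedCorrelationError("series must have equal length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero variance series")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SimulationInputs:
    """The fixed world a calibration runs against."""

    persons: pd.DataFrame
    households: pd.DataFrame
    graph: NeighborhoodGraph
    events: pd.DataFrame
    horizon: int


@dataclass
class CalibrationSpec:
    """Search-space and objective configuration for coordinate descent.

    theta is excluded from the default free set: literature-recommended
    values exist for memory decay, so it is held fixed unless requested.
    """

    free_parameters: Sequence[str] = ("v", "Q")
    bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"v": (0.05, 5.0), "Q": (10.0, 5000.0)}
    )
    grid_points: int = 9
    replicates: int = 3
    max_cycles: int = 4
    tolerance: float = 1e-3
    objective: str = "rmse"
    smoothing_window: int = 7
    n_starts: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.free_parameters:
            if p not in CALIBRATABLE:
                raise ConfigurationError(f"{p!r} is not a calibratable parameter")
            if p not in self.bounds:
                raise ConfigurationError(f"no bounds for free parameter {p!r}")
            lo, hi = self.bounds[p]
            if not lo < hi:
                raise ConfigurationError(f"bounds for {p!r} must satisfy lo < hi")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.grid_points < 2:
            raise ConfigurationError("grid_points must be >= 2")
        if self.objective not in ("rmse", "one_minus_pcc"):
            raise ConfigurationError("objective must be 'rmse' or 'one_minus_pcc'")
        if self.n_starts < 1:
            raise ConfigurationError("n_starts must be >= 1")


def replicate_seeds(seed: int, replicates: int) -> np.ndarray:
    """Deterministic replicate seed stream (common random numbers)."""
    return np.random.SeedSequence(seed).generate_state(replicates) % (2**31)


def simulate_average_series(
    params: ModelParameters,
    inputs: SimulationInputs,
    replicates: int,
    seed: int,
    migration_type: str | None = "refugee",
) -> np.ndarray:
    """Replicate-averaged daily (crossing-day) migrant-person series."""
    seeds = replicate_seeds(seed, replicates)
    total = np.zeros(inputs.horizon + 1)
    for s in seeds:
        traj = run_simulation(
            inputs.persons, inputs.households, inputs.graph, inputs.events,
            params, inputs.horizon, int(s),
        )
        total += daily_series(traj, migration_type=migration_type).to_numpy()
    return total / replicates


def series_loss(simulated, observed, objective: str = "rmse", smoothing_window: int = 7) -> float:
    """Loss between two equal-length daily series after moving-average smoothing."""
    simulated = np.asarray(simulated, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if simulated.shape != observed.shape:
        raise ValueError("day-range mismatch between simulated and observed series")
    sim = moving_average(pd.Series(simulated), smoothing_window).to_numpy()
    obs = moving_average(pd.Series(observed), smoothing_window).to_numpy()
    if objective == "rmse":
        return float(np.sqrt(np.mean((sim - obs) ** 2)))
    if objective == "one_minus_pcc":
        return float(1.0 - pcc(sim, obs))
    raise ConfigurationError(f"unknown objective {objective!r}")


def objective(
    params: ModelParameters,
    observed_series,
    inputs: SimulationInputs,
    spec: CalibrationSpec,
) -> float:
    """Calibration loss of ``params`` against the observed daily series."""
    observed = np.asarray(observed_series, dtype=float)
    if observed.size != inputs.horizon + 1:
        raise ValueError(
            f"observed series has {observed.size} days, simulation covers {inputs.horizon + 1}"
        )
    sim = simulate_average_series(params, inputs, spec.replicates, spec.seed)
    return series_loss(sim, observed, spec.objective, spec.smoothing_window)


@dataclass
class CalibrationResult:
    params: ModelParameters
    loss: float
    loss_trace: list[float]
    converged: bool
    evaluations: int
    final_pcc: float | None = None

    def to_json(self) -> str:
        d = {
            "params": asdict(self.params),
            "loss": self.loss,
            "loss_trace": self.loss_trace,
            "converged": self.converged,
            "evaluations": self.evaluations,
            "final_pcc": self.final_pcc,
        }
        return json.dumps(d, indent=2)


def _latin_hypercube_starts(
    spec: CalibrationSpec, initial_params: ModelParameters
) -> list[ModelParameters]:
    """Initial points: the given start plus Latin-hypercube samples in bounds."""
    starts = [initial_params]
    n_extra = spec.n_starts - 1
    if n_extra <= 0:
        return starts
    rng = np.random.default_rng(spec.seed)
    columns = {}
    for name in spec.free_parameters:
        lo, hi = spec.bounds[name]
        strata = (np.arange(n_extra) + rng.random(n_extra)) / n_extra
        values = lo + strata * (hi - lo)
        rng.shuffle(values)
        columns[name] = values
    for i in range(n_extra):
        values = {
            name: int(round(columns[name][i])) if name in INTEGER_PARAMETERS
            else float(columns[name][i])
            for name in spec.free_parameters
        }
        try:
            starts.append(initial_params.with_values(**values))
        except ConfigurationError:
            continue  # jointly infeasible sample (e.g. i_lo > i_hi)
    return starts


def coordinate_descent(
    loss_fn: Callable[[ModelParameters], float],
    spec: CalibrationSpec,
    initial_params: ModelParameters,
) -> CalibrationResult:
    """Multi-start cyclic bounded grid line searches; accepts only improvements.

    For each free parameter a grid of ``grid_points`` values spanning its
    bounds (integers for the peer thresholds, deduplicated) is evaluated with
    the other parameters held at their current values; ties prefer the
    smallest value. A start stops when a full cycle improves the loss by less
    than ``tolerance`` or after ``max_cycles`` cycles. With ``n_starts`` > 1
    the descent is repeated from Latin-hypercube points in the bounds box
    (single-coordinate moves cannot follow a diagonal loss valley, so extra
    starts guard against ridge traps) and the best final fit is returned.
    """
    best_result: CalibrationResult | None = None
    total_evaluations = 0
    for start in _latin_hypercube_starts(spec, initial_params):
        result = _descend_from(loss_fn, spec, start)
        total_evaluations += result.evaluations
        if best_result is None or result.loss < best_result.loss:
            best_result = result
    best_result.evaluations = total_evaluations
    return best_result


def _descend_from(
    loss_fn: Callable[[ModelParameters], float],
    spec: CalibrationSpec,
    initial_params: ModelParameters,
) -> CalibrationResult:
    current = initial_params
    evaluations = 0

    def evaluate(p: ModelParameters) -> float:
        nonlocal evaluations
        evaluations += 1
        return loss_fn(p)

    best_loss = evaluate(current)
    trace = [best_loss]
    converged = False

    for _ in range(spec.max_cycles):
        cycle_start = best_loss
        for name in spec.free_parameters:
            lo, hi = spec.bounds[name]
            grid = np.linspace(lo, hi, spec.grid_points)
            if name in INTEGER_PARAMETERS:
                grid = np.unique(np.round(grid).astype(int))
            # line search: argmin over the grid, ties to the smallest value
            line_best_loss, line_best = best_loss, None
            for value in grid:
                value = int(value) if name in INTEGER_PARAMETERS else float(value)
                if value == getattr(current, name):
                    loss = best_loss
                else:
                    try:
                        candidate = current.with_values(**{name: value})
                    except ConfigurationError:
                        continue  # e.g. i_lo grid value above current i_hi
                    loss = evaluate(candidate)
                if loss < line_best_loss or (loss == line_best_loss and line_best is None
                                             and value < getattr(current, name)):
                    line_best_loss, line_best = loss, value
            if line_best is not None:
                current = current.with_values(**{name: line_best})
                best_loss = line_best_loss
                trace.append(best_loss)
        if cycle_start - best_loss < spec.tolerance:
            converged = True
            break

    return CalibrationResult(
        params=current,
        loss=best_loss,
        loss_trace=trace,
        converged=converged,
        evaluations=evaluations,
    )


def calibrate(
    observed_series,
    inputs: SimulationInputs,
    spec: CalibrationSpec,
    initial_params: ModelParameters,
) -> CalibrationResult:
    """Fit the free parameters to an observed daily refugee series."""
    result = coordinate_descent(
        lambda p: objective(p, observed_series, inputs, spec), spec, initial_params
    )
    sim = simulate_average_series(result.params, inputs, spec.replicates, spec.seed)
    obs = np.asarray(observed_series, dtype=float)
    try:
        result.final_pcc = pcc(
            moving_average(pd.Series(sim), spec.smoothing_window),
            moving_average(pd.Series(obs), spec.smoothing_window),
        )
    except UndefinedCorrelationError:
        result.final_pcc = None
    return result


def read_observed_series(csv, date_origin, horizon: int) -> np.ndarray:
    """Read a date,count CSV into a day-indexed array of length horizon+1."""
    df = pd.read_csv(csv)
    if "date" not in df.columns or "count" not in df.columns:
        raise ValueError("observed series CSV must have 'date' and 'count' columns")
    days = (pd.to_datetime(df["date"]) - pd.Timestamp(date_origin)).dt.days
    out = np.zeros(horizon + 1)
    for d, c in zip(days, df["count"]):
        if 0 <= d <= horizon:
            out[int(d)] = float(c)
    return out
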