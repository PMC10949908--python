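"""Aggregation of trajectories into daily, demographic, and spatial reports,
plus the policy-analysis arithmetic (scenario accounting, household depletion,
and the at-risk-flow x prevalence sexual-violence calculator).

All operations are pure: the same trajectory yields the same tables.
"""

from __future__ import annotations

import json
from typing import Iterable

import numpy as np
import pandas as pd

from ._geo import haversine_km
from .dynamics import Trajectory
from .population import DEFAULT_AGE_BINS, ConfigurationError, age_bin_labels

GROUP_KEYS = ("age", "gender", "age_gender", "admin1", "admin2")


def daily_series(
    trajectory: Trajectory,
    migration_type: str | None = None,
    horizon: int | None = None,
    use_crossing_day: bool = True,
) -> pd.Series:
    """Daily migrated-person counts indexed by day 0..horizon.

    Counts by crossing day (decision day + lag) by default. Disjoint
    ``migration_type`` filters partition the all-type series.
    """
    if horizon is None:
        horizon = trajectory.horizon + (trajectory.params.decision_lag if use_crossing_day else 0)
    r = trajectory.records
    if migration_type is not None:
        r = r[r["migration_type"] == migration_type]
    day_col = "crossing_day" if use_crossing_day else "day"
    counts = np.zeros(horizon + 1, dtype=np.int64)
    if len(r):
        binned = np.bincount(r[day_col].to_numpy(), minlength=horizon + 1)
        counts[: len(binned)] = binned[: horizon + 1]
    return pd.Series(counts, index=pd.RangeIndex(horizon + 1, name="day"), name="count")


def moving_average(series: pd.Series, window: int = 7) -> pd.Series:
    """Centered moving average with truncated edges; window=1 is the identity."""
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    return series.rolling(window, center=True, min_periods=1).mean()


def disaggregate(
    trajectory: Trajectory,
    by: str,
    age_bins=DEFAULT_AGE_BINS,
    migration_type: str | None = None,
    per_day: bool = False,
) -> pd.DataFrame:
    """Migrated-person counts grouped by a demographic or spatial key.

    ``by`` is one of 'age', 'gender', 'age_gender', 'admin1', 'admin2'.
    Group totals always sum to the trajectory total under the same filter.
    """
    if by not in GROUP_KEYS:
        raise ConfigurationError(f"unknown grouping key {by!r}; use one of {GROUP_KEYS}")
    r = trajectory.records.copy()
    if migration_type is not None:
        r = r[r["migration_type"] == migration_type].copy()
    if by in ("age", "age_gender") and len(r):
        r["age_bin"] = age_bin_labels(r["age"].to_numpy(), age_bins)
    key_map = {"age": ["age_bin"], "gender": ["gender"], "age_gender": ["age_bin", "gender"],
               "admin1": ["admin1"], "admin2": ["admin2"]}
    keys = key_map[by] + (["day"] if per_day else [])
    if not len(r):
        return pd.DataFrame(columns=keys + ["count"])
    out = r.groupby(keys, observed=True).size().rename("count").reset_index()
    return out


def scenario_average(values: Iterable[float]) -> float:
    """Arithmetic mean of per-scenario totals (e.g. refugee estimates)."""
    vals = list(values)
    if not vals:
        raise ValueError("scenario_average of an empty list")
    return float(np.mean(vals))


def percent_difference(estimate: float, reference: float) -> float:
    """Signed percent over/under-estimation: 100*(estimate - reference)/reference."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (estimate - reference) / reference


def remaining_fraction(total_households: float, migrated_households: float) -> float:
    """Percent of households not yet migrated (household depletion complement)."""
    if total_households <= 0 or not 0 <= migrated_households <= total_households:
        raise ValueError("need 0 <= migrated <= total and total > 0")
    return 100.0 * (total_households - migrated_households) / total_households


def displaced_fraction(total: float, migrated: float) -> float:
    """Percent displaced: complement of :func:`remaining_fraction`."""
    return 100.0 - remaining_fraction(total, migrated)


def at_risk_female_flow(
    trajectory: Trajectory,
    events: pd.DataFrame,
    households: pd.DataFrame,
    window_days: int = 7,
    radius_km: float = 30.0,
    age_range: tuple[int, int] = (17, 50),
    migration_type: str | None = "refugee",
) -> int:
    """Count migrated women of ``age_range`` who fled an active conflict zone.

    A migrant is at risk when her origin household lay within ``radius_km``
    of at least one conflict event in the ``window_days`` days strictly
    before her migration (decision) day. This proxies active military
    presence near the origin at the time of flight.
    """
    r = trajectory.records
    r = r[(r["gender"] == "female") & (r["age"] >= age_range[0]) & (r["age"] <= age_range[1])]
    if migration_type is not None:
        r = r[r["migration_type"] == migration_type]
    if not len(r) or not len(events):
        return 0
    h = households.set_index("household_id")
    count = 0
    for _, row in r.iterrows():
        day = int(row["day"])
        lat = h.at[row["household_id"], "latitude"]
        lon = h.at[row["household_id"], "longitude"]
        window = events[(events["day"] >= day - window_days) & (events["day"] < day)]
        if not len(window):
            continue
        d = haversine_km(lat, lon, window["latitude"].to_numpy(), window["longitude"].to_numpy())
        if np.any(d <= radius_km):
            count += 1
    return count


def sexual_violence_estimate(
    at_risk_flow: float,
    prevalence: float,
    bounds: tuple[float, float] | None = None,
) -> tuple[float, tuple[float, float] | None]:
    """Potential wartime sexual-violence victims among an at-risk flow.

    Central estimate = flow x prevalence; the optional ``bounds`` are lower
    and upper prevalence rates producing an interval. Prevalences are
    fractions in [0, 1].
    """
    rates = [prevalence] + (list(bounds) if bounds is not None else [])
    for r in rates:
        if not 0.0 <= r <= 1.0:
            raise ValueError("prevalence rates must be in [0, 1]")
    central = at_risk_flow * prevalence
    interval = (at_risk_flow * bounds[0], at_risk_flow * bounds[1]) if bounds is not None else None
    return central, interval


def scenario_difference_table(
    scenario_traj: Trajectory,
    baseline_traj: Trajectory,
    by: str = "admin2",
    migration_type: str | None = "refugee",
) -> pd.DataFrame:
    """Per-region scenario-minus-baseline outflow differences.

    Joins the two disaggregations on the region key; the difference column
    totals to the difference of the overall totals.
    """
    a = disaggregate(scenario_traj, by, migration_type=migration_type).set_index(by)["count"]
    b = disaggregate(baseline_traj, by, migration_type=migration_type).set_index(by)["count"]
    idx = sorted(set(a.index) | set(b.index))
    out = pd.DataFrame(
        {
            by: idx,
            "scenario": [int(a.get(k, 0)) for k in idx],
            "baseline": [int(b.get(k, 0)) for k in idx],
        }
    )
    out["difference"] = out["scenario"] - out["baseline"]
    return out


def regions_geojson(households: pd.DataFrame, table: pd.DataFrame, by: str = "admin2") -> str:
    """GeoJSON point FeatureCollection of region centroids joined with counts."""
    centroids = households.groupby(by)[["latitude", "longitude"]].mean()
    counts = table.set_index(by)["count"] if "count" in table.columns else table.set_index(by).iloc[:, -1]
    features = []
    for region, row in centroids.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["longitude"], row["latitude"]]},
                "properties": {by: region, "count": int(counts.get(region, 0))},
            }
        )
    return json.dumps({"type": "FeatureCollection", "features": features})
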