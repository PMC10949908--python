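"""Conflict-event ingestion, filtering, intensity scoring, and scenario sampling.

Events follow an ACLED-like tabular schema (date, location, event type,
fatalities). Only event classes that damage people or infrastructure —
battles, explosions/remote violence, and violence against civilians — are
retained by default; protests, riots and strategic developments are dropped.
Each retained event carries a positive intensity used by the impact kernel of
the migration engine.

Counterfactual event streams are drawn from an inhomogeneous Poisson sampler:
each scenario component emits events at a constant daily rate, placed with
Gaussian spatial scatter around a center. This consumes user-specified
intensity surfaces rather than fitting a point-process model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import ConfigurationError

EVENT_COLUMNS = ["event_id", "day", "latitude", "longitude", "event_type", "fatalities", "intensity"]

#: Event classes retained by default (prefix-matched, case-insensitive).
DEFAULT_TYPE_FILTER: tuple[str, ...] = (
    "battle",
    "explosion",
    "violence against civilians",
)

_COLUMN_ALIASES = {
    "date": ("event_date", "date"),
    "latitude": ("latitude", "lat"),
    "longitude": ("longitude", "lon", "lng"),
    "event_type": ("event_type", "type"),
    "fatalities": ("fatalities",),
}


class InputError(ValueError):
    """Malformed event input that cannot be recovered row-by-row."""


def normalize_event_type(event_type: str) -> str:
    return str(event_type).strip().lower()


def matches_filter(event_type: str, type_filter: Sequence[str] = DEFAULT_TYPE_FILTER) -> bool:
    """True if the (normalized) type starts with any retained class prefix."""
    t = normalize_event_type(event_type)
    return any(t.startswith(normalize_event_type(p)) for p in type_filter)


def compute_intensity(
    event_types,
    fatalities,
    type_weights: Mapping[str, float] | None = None,
    fatality_scale: float = 1.0,
    default_weight: float | None = 1.0,
) -> np.ndarray:
    """Event intensity I = w_type * (1 + fatality_scale * ln(1 + fatalities)).

    Positive for all events (a zero-fatality battle still has intensity
    ``w_type``) and monotone nondecreasing in fatalities. ``type_weights``
    maps normalized type prefixes to weights; an unmatched type falls back to
    ``default_weight`` or raises if that is None.
    """
    if fatality_scale < 0:
        raise ConfigurationError("fatality_scale must be nonnegative")
    if type_weights:
        for k, w in type_weights.items():
            if w <= 0:
                raise ConfigurationError(f"type weight for {k!r} must be positive")
    types = np.atleast_1d(np.asarray(event_types, dtype=object))
    fat = np.atleast_1d(np.asarray(fatalities, dtype=float))
    weights = np.empty(types.shape, dtype=float)
    for i, t in enumerate(types):
        w = None
        if type_weights:
            tn = normalize_event_type(t)
            for prefix, weight in type_weights.items():
                if tn.startswith(normalize_event_type(prefix)):
                    w = weight
                    break
        if w is None:
            if default_weight is None:
                raise ConfigurationError(f"no intensity weight for event type {t!r}")
            w = default_weight
        weights[i] = w
    intensity = weights * (1.0 + fatality_scale * np.log1p(fat))
    if np.isscalar(event_types) or np.ndim(event_types) == 0:
        return float(intensity[0])
    return intensity


def read_events(
    csv,
    date_origin,
    type_filter: Sequence[str] | None = DEFAULT_TYPE_FILTER,
    type_weights: Mapping[str, float] | None = None,
    fatality_scale: float = 1.0,
) -> pd.DataFrame:
    """Read an ACLED-like CSV into the canonical event table.

    Dates (ISO-8601) become integer day indices relative to ``date_origin``
    (day 0). Rows with unparseable dates or coordinates are dropped with a
    warning counting them; an event dated before ``date_origin`` is an error.
    ``type_filter=None`` retains every event type.
    """
    raw = pd.read_csv(csv)
    cols = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in raw.columns:
                cols[canonical] = alias
                break
        else:
            raise InputError(f"events CSV lacks a {canonical!r} column (tried {aliases})")

    n_total = len(raw)
    if n_total == 0:
        return pd.DataFrame({c: pd.Series(dtype=d) for c, d in zip(
            EVENT_COLUMNS, (np.int64, np.int64, float, float, object, np.int64, float))})
    dates = pd.to_datetime(raw[cols["date"]], errors="coerce")
    lat = pd.to_numeric(raw[cols["latitude"]], errors="coerce")
    lon = pd.to_numeric(raw[cols["longitude"]], errors="coerce")
    fat = pd.to_numeric(raw[cols["fatalities"]], errors="coerce")
    good = dates.notna() & lat.notna() & lon.notna() & fat.notna()
    n_bad = int(n_total - good.sum())
    if n_total > 0 and n_bad == n_total:
        raise InputError("no parseable rows in events CSV")
    if n_bad:
        warnings.warn(f"dropped {n_bad} unparseable event rows", stacklevel=2)

    df = pd.DataFrame(
        {
            "day": (dates[good] - pd.Timestamp(date_origin)).dt.days.to_numpy(),
            "latitude": lat[good].to_numpy(dtype=float),
            "longitude": lon[good].to_numpy(dtype=float),
            "event_type": raw.loc[good, cols["event_type"]].astype(str).to_numpy(),
            "fatalities": fat[good].to_numpy(dtype=int),
        }
    )
    if (df["day"] < 0).any():
        raise InputError("event dated before date_origin (negative day index)")
    if type_filter is not None:
        df = df[[matches_filter(t, type_filter) for t in df["event_type"]]]
    df = df.sort_values("day", kind="stable").reset_index(drop=True)
    df.insert(0, "event_id", np.arange(len(df), dtype=np.int64))
    df["intensity"] = compute_intensity(
        df["event_type"].to_numpy(), df["fatalities"].to_numpy(), type_weights, fatality_scale
    ) if len(df) else np.empty(0)
    return df[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, csv, date_origin=None) -> None:
    """Write an event table back to CSV (day indices, or dates if origin given)."""
    out = events.copy()
    if date_origin is not None:
        out["event_date"] = pd.Timestamp(date_origin) + pd.to_timedelta(out.pop("day"), unit="D")
    out.to_csv(csv, index=False)


# ---------------------------------------------------------------------------
# Scenario sampling


@dataclass(frozen=True)
class ScenarioComponent:
    """One spatial cluster of a counterfactual conflict scenario."""

    center_lat: float
    center_lon: float
    spread_km: float
    daily_rate: float
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"battles": 0.5, "explosions/remote violence": 0.4, "violence against civilians": 0.1}
    )
    mean_fatalities: float = 1.0


@dataclass
class ScenarioSpec:
    """Inhomogeneous-Poisson scenario: per-day Poisson counts per component."""

    start_day: int
    end_day: int  # inclusive
    components: Sequence[ScenarioComponent]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ConfigurationError("end_day must be >= start_day")
        for c in self.components:
            if c.daily_rate < 0:
                raise ConfigurationError("daily_rate must be nonnegative")
            if c.spread_km < 0:
                raise ConfigurationError("spread_km must be nonnegative")
            mix = np.asarray(list(c.type_mix.values()), dtype=float)
            if mix.size == 0 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-9:
                raise ConfigurationError("type_mix must be a probability vector summing to 1")
            if c.mean_fatalities < 0:
                raise ConfigurationError("mean_fatalities must be nonnegative")


_KM_PER_DEG_LAT = 111.32


def sample_scenario_events(
    spec: ScenarioSpec,
    type_weights: Mapping[str, float] | None = None,
    fatality_scale: float = 1.0,
) -> pd.DataFrame:
    """Draw a synthetic event stream; reproducible from ``spec.seed``.

    Per component and day, the event count is Poisson(daily_rate); locations
    are isotropic Gaussian (``spread_km``) around the center; types follow the
    component mix and fatalities are Poisson(mean_fatalities).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for comp in spec.components:
        types = list(comp.type_mix)
        probs = np.asarray([comp.type_mix[t] for t in types], dtype=float)
        for day in range(spec.start_day, spec.end_day + 1):
            n = rng.poisson(comp.daily_rate)
            if n == 0:
                continue
            dlat = rng.normal(0.0, comp.spread_km, size=n) / _KM_PER_DEG_LAT
            dlon = rng.normal(0.0, comp.spread_km, size=n) / (
                _KM_PER_DEG_LAT * np.cos(np.radians(comp.center_lat))
            )
            t_idx = rng.choice(len(types), size=n, p=probs)
            fats = rng.poisson(comp.mean_fatalities, size=n)
            for i in range(n):
                rows.append(
                    (day, comp.center_lat + dlat[i], comp.center_lon + dlon[i], types[t_idx[i]], int(fats[i]))
                )
    df = pd.DataFrame(rows, columns=["day", "latitude", "longitude", "event_type", "fatalities"])
    df = df.sort_values("day", kind="stable").reset_index(drop=True)
    df.insert(0, "event_id", np.arange(len(df), dtype=np.int64))
    df["intensity"] = (
        compute_intensity(df["event_type"].to_numpy(), df["fatalities"].to_numpy(), type_weights, fatality_scale)
        if len(df)
        else np.empty(0)
    )
    return df[EVENT_COLUMNS]
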