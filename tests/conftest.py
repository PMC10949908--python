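"""Shared fixtures: programmatically generated toy worlds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import migrasim as m

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

RISK_GROUPS = {"child": 1.2, "adult": 1.0, "elderly": 1.2}


def make_world(
    n_households: int,
    seed: int,
    center=(49.99, 36.23),
    spread_km: float = 5.0,
    radius_km: float = 3.0,
    max_neighbors: int = 5,
):
    """A random small world: located households with members and a network."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(1, 5, size=n_households)
    households = pd.DataFrame(
        {
            "household_id": np.arange(n_households),
            "latitude": center[0] + rng.normal(0, spread_km / 111.32, n_households),
            "longitude": center[1] + rng.normal(0, spread_km / 70.0, n_households),
            "admin1": np.where(np.arange(n_households) % 2 == 0, "East", "West"),
            "admin2": [f"raion-{i % 3}" for i in range(n_households)],
        }
    )
    persons = pd.DataFrame(
        {
            "person_id": np.arange(int(sizes.sum())),
            "household_id": np.repeat(np.arange(n_households), sizes),
            "age": rng.integers(0, 90, size=int(sizes.sum())),
            "gender": np.where(rng.random(int(sizes.sum())) < 0.54, "female", "male"),
        }
    )
    persons = m.assign_risk_proneness(persons, RISK_GROUPS)
    graph = m.build_neighborhood(households, radius_km=radius_km, max_neighbors=max_neighbors)
    return persons, households, graph


def make_events(n_events: int, seed: int, center=(49.99, 36.23), day_range=(0, 10), spread_km=8.0):
    rng = np.random.default_rng(seed)
    types = ["battles", "explosions/remote violence", "violence against civilians"]
    df = pd.DataFrame(
        {
            "day": rng.integers(day_range[0], day_range[1] + 1, size=n_events),
            "latitude": center[0] + rng.normal(0, spread_km / 111.32, n_events),
            "longitude": center[1] + rng.normal(0, spread_km / 70.0, n_events),
            "event_type": rng.choice(types, size=n_events),
            "fatalities": rng.poisson(2.0, size=n_events),
        }
    )
    df = df.sort_values("day", kind="stable").reset_index(drop=True)
    df.insert(0, "event_id", np.arange(n_events))
    df["intensity"] = m.compute_intensity(df["event_type"].to_numpy(), df["fatalities"].to_numpy())
    return df


@pytest.fixture
def small_world():
    return make_world(8, seed=11)


@pytest.fixture
def small_events():
    return make_events(6, seed=7, day_range=(0, 3))


@pytest.fixture
def default_params():
    return m.ModelParameters(tau=1.8, delta=2.2, theta=0.5, v=1.0, Q=50.0, i_hi=4, i_lo=0)
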