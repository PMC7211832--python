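import numpy as np
import pandas as pd
import pytest

from roostnet.records import CaptureDataset, RoostRegistry
from roostnet.simulate import SimulationConfig, simulate_dataset


def make_captures(rows):
    """Build a CaptureDataset from (bat, date, roost, pop, sex, age[, repro]) tuples."""
    recs = []
    for row in rows:
        bat, date, roost, pop, sex, age = row[:6]
        repro = row[6] if len(row) > 6 else "unknown"
        recs.append(
            dict(
                bat_id=bat, date=date, roost_id=roost, population=pop,
                sex=sex, age_class=age, repro_status=repro,
            )
        )
    return CaptureDataset(pd.DataFrame(recs))


@pytest.fixture
def toy_registry():
    return RoostRegistry(
        pd.DataFrame(
            {
                "roost_id": ["r1", "r2", "r3", "g1"],
                "population": ["P", "P", "P", "G"],
                "x": [0.0, 100.0, 400.0, 2000.0],
                "y": [0.0, 0.0, 0.0, 0.0],
            }
        ),
        coordinates="planar",
    )


@pytest.fixture
def toy_dataset(toy_registry):
    rows = [
        ("a", "2015-01-01", "r1", "P", "female", "adult", "pregnant"),
        ("b", "2015-01-01", "r1", "P", "female", "adult"),
        ("c", "2015-01-01", "r2", "P", "male", "adult", "scrotal"),
        ("a", "2015-02-01", "r2", "P", "female", "adult"),
        ("c", "2015-02-01", "r2", "P", "male", "adult", "scrotal"),
        ("d", "2015-02-01", "r2", "P", "male", "juvenile"),
        ("b", "2015-03-01", "r1", "P", "female", "adult"),
        ("e", "2015-03-05", "g1", "G", "female", "adult"),
        ("a", "2016-01-10", "r1", "P", "female", "adult"),
        ("b", "2016-01-10", "r1", "P", "female", "adult"),
        ("d", "2016-02-01", "r3", "P", "male", "adult", "scrotal"),
    ]
    ds = make_captures(rows)
    ds.registry = toy_registry
    return ds


@pytest.fixture(scope="session")
def small_bundle():
    """One small simulated study reused by read-only tests."""
    cfg = SimulationConfig(
        seed=2024, n_founders=40, n_years=3, days_per_year=30,
        capture_events_per_year=16, groups_per_day=4,
        n_roosts_per_population=8,
    )
    return simulate_dataset(cfg)


def random_small_dataset(rng, n_bats=None, n_events=None):
    """Random capture table over <= 6 bats and <= 10 events (two populations)."""
    n_bats = n_bats or int(rng.integers(3, 7))
    n_events = n_events or int(rng.integers(3, 11))
    bats = [f"b{i}" for i in range(n_bats)]
    sexes = {b: ("female" if rng.random() < 0.5 else "male") for b in bats}
    pops = {b: ("P" if i < n_bats // 2 + 1 else "G") for i, b in enumerate(bats)}
    rows = []
    dates = [f"2015-01-{d:02d}" for d in range(1, 6)]
    roosts = {"P": ["r1", "r2", "r3"], "G": ["g1", "g2"]}
    for _ in range(n_events):
        pop = "P" if rng.random() < 0.7 else "G"
        date = dates[rng.integers(len(dates))]
        roost = roosts[pop][rng.integers(len(roosts[pop]))]
        pool = [b for b in bats if pops[b] == pop]
        if not pool:
            continue
        k = int(rng.integers(1, len(pool) + 1))
        chosen = rng.choice(pool, size=k, replace=False)
        for b in chosen:
            rows.append(
                (b, date, roost, pop, sexes[b], "adult")
            )
    # drop duplicate (bat, event) rows arising from repeated (date, roost) draws
    seen = set()
    uniq = []
    for r in rows:
        key = (r[0], r[1], r[2])
        if key not in seen:
            seen.add(key)
            uniq.append(r)
    if not uniq:
        uniq = [("b0", "2015-01-01", "r1", "P", sexes["b0"], "adult")]
    return make_captures(uniq)
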