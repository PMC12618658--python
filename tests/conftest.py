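"""Shared fixtures: one small synthetic world, harmonized and fused once."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pncmap import (
    FeatureTable,
    WorldConfig,
    assemble_features,
    downscale_stack,
    gen_covariate_world,
    gen_station_records,
    gen_truth_pnc,
    harmonize_records,
)
from pncmap.fusion import FEATURE_NAMES

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def world():
    """A 60x60 synthetic world run through harmonization and fusion."""
    config = WorldConfig(
        seed=7, nx=60, ny=60, n_stations=30, n_clusters=5, years=(2013, 2014, 2015)
    )
    stack = gen_covariate_world(config)
    fused = downscale_stack(stack)
    truth = gen_truth_pnc(fused, config.truth_params)
    records, registry, size_grid = gen_station_records(truth, stack, config)
    observations, rejected, fractions = harmonize_records(records, registry, size_grid)
    table = assemble_features(observations, fused)
    return SimpleNamespace(
        config=config,
        stack=stack,
        fused=fused,
        truth=truth,
        records=records,
        registry=registry,
        size_grid=size_grid,
        observations=observations,
        rejected=rejected,
        fractions=fractions,
        table=table,
    )


def random_feature_table(n: int, seed: int = 0) -> FeatureTable:
    """A schema-valid feature table with random contents (no world needed)."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "station_id": [f"S{i % max(n // 3, 1):03d}" for i in range(n)],
            "year": [2010 + i // max(n // 3, 1) for i in range(n)],
            "lat": rng.uniform(40, 41, n),
            "lon": rng.uniform(10, 11, n),
            "pnc_annual": rng.lognormal(8.5, 0.8, n),
        }
    )
    for name in FEATURE_NAMES:
        frame[name] = rng.uniform(0, 100, n)
    frame["station_id"] = [f"S{i:03d}" for i in range(n)]  # unique (station, year)
    return FeatureTable(frame=frame)
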