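"""Shared fixtures; the session-scoped standard benchmark is computed once."""

import numpy as np
import pytest

import scmarkers as sm
from scmarkers.ranking import McfsParams, MrmrParams

BENCHMARK_SEED = 7


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The standard synthetic benchmark: 25 classes, 5 markers/class,
    effect 2.0, 2000 genes, ~3000 cells with the colon-immune imbalance."""
    spec = sm.SyntheticSpec(seed=BENCHMARK_SEED)
    ds = sm.generate_dataset(spec)
    markers = {g for gs in sm.planted_markers(spec).values() for g in gs}
    return ds, markers


@pytest.fixture(scope="session")
def benchmark_lists(benchmark_dataset):
    """All five feature lists on the benchmark (the expensive session step)."""
    ds, _ = benchmark_dataset
    return {
        method: sm.rank_features(
            ds, method, seed=BENCHMARK_SEED,
            mcfs_params=McfsParams(seed=BENCHMARK_SEED),
            mrmr_params=MrmrParams(),
        )
        for method in sm.ranking.RANKERS
    }
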