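"""Shared fixtures: synthetic cohorts at the standing benchmark conditions.

The benchmark cohort (n=400 samples, 28 cell types x 30 signature genes,
delta=3, beta_sig=2, theta=1, seed 7) and its full pipeline run are session
fixtures so the expensive stages run once for all tests that probe them.
"""

from __future__ import annotations

import logging

import pytest

import immunoscore as im

logging.getLogger("immunoscore").setLevel(logging.ERROR)

BENCHMARK_SEED = 7
VALIDATION_SEED = 1007


@pytest.fixture(scope="session")
def benchmark_params() -> im.SimulationParams:
    return im.SimulationParams(n_samples=400, seed=BENCHMARK_SEED)


@pytest.fixture(scope="session")
def benchmark_cohort(benchmark_params):
    """(expr, gmt, clinical, truth) at the standing benchmark conditions."""
    return im.generate_cohort(benchmark_params)


@pytest.fixture(scope="session")
def benchmark_result(benchmark_cohort):
    """Full pipeline run on the benchmark cohort (shared, ~20 s)."""
    expr, gmt, clin, _ = benchmark_cohort
    cfg = im.RunConfig(seed=BENCHMARK_SEED)
    return im.run_pipeline(expr, gmt, clin, cfg)


@pytest.fixture(scope="session")
def validation_cohort():
    """Independently generated cohort for the train/validate design."""
    params = im.SimulationParams(n_samples=400, seed=VALIDATION_SEED)
    return im.generate_cohort(params)


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for direction checks that do not need the benchmark."""
    params = im.SimulationParams(n_samples=60, seed=11)
    return im.generate_cohort(params)
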