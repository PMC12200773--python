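import numpy as np
import pytest

from droughtlink.config import PipelineConfig, SamplerSettings
from droughtlink.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Small end-to-end input bundle written once per session."""
    from droughtlink.simulate import make_fixture_suite

    out = tmp_path_factory.mktemp("bundle")
    paths = make_fixture_suite(seed=202, out_dir=out)
    return paths


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default-configuration pipeline run shared across tests."""
    out = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(seed=31)
    report = run_pipeline(config, out)
    return {"report": report, "out": out, "config": config}


@pytest.fixture(scope="session")
def small_cohort():
    """Simulated cohort small enough for quick model fits."""
    from droughtlink.simulate import CohortSimParams, simulate_cohort

    params = CohortSimParams(
        n_respondents=4000, n_countries=6, districts_per_country=6,
        beta={"very_dry": 0.3}, sigma=0.3, seed=5,
    )
    cohort, truth = simulate_cohort(params)
    return cohort, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    from droughtlink.model import build_model_input, fit_model

    cohort, _ = small_cohort
    mi = build_model_input(cohort, "very_dry")
    draws = fit_model(mi, SamplerSettings(chains=2, draws=500, warmup=400), seed=9)
    return mi, draws


def rng(seed=0):
    return np.random.default_rng(seed)
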