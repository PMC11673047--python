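import numpy as np
import pytest

from ctharmony.phantom import GeometryConfig, make_cohort
from ctharmony.pipeline import ExperimentConfig, run_experiment


@pytest.fixture(scope="session")
def small_cohort():
    """Three-subject four-protocol cohort for unit-level tests."""
    return make_cohort(3, seed=42)


@pytest.fixture(scope="session")
def e2e_bundle(tmp_path_factory):
    """Full desk-scale experiment: train/external cohorts of 8, 64x64
    patches, 500 generator steps, fixed seed.  Shared by the end-to-end
    directional tests; takes a few minutes of CPU."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = ExperimentConfig(n_train=8, n_external=8, seed=1)
    return run_experiment(cfg, out)


@pytest.fixture(scope="session")
def identity_bundle(tmp_path_factory):
    """Identity-harmonizer ablation at reduced cohort size."""
    out = tmp_path_factory.mktemp("identity")
    cfg = ExperimentConfig(n_train=3, n_external=4, seed=5, identity_harmonizer=True)
    return run_experiment(cfg, out)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
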