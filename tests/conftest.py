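import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from netsig.pipeline import run_pipeline  # noqa: E402
from netsig.synthetic_data import SimulationConfig, simulate_all  # noqa: E402
from netsig.upregulation import McmcSettings, fit_null_model  # noqa: E402


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study conditions shared across module tests."""
    return SimulationConfig(
        n_normal=20, n_tumor=24, n_genes=80, n_tfs=8, targets_per_tf=(4, 6),
        n_subgroups=3, active_tfs_per_group=2, planted_fold=4.0, noise_sd=0.5,
        n_drugs=12, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def null_model_88():
    """Null model fitted on 88 seeded Normal(5, 1) controls (the control
    sample size of the intended study design)."""
    rng = np.random.default_rng(88)
    controls = rng.normal(5.0, 1.0, size=88)
    model = fit_null_model(controls, settings=McmcSettings(seed=88), gene="demo")
    return controls, model


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline on noiseless synthetic data (constant controls handled
    by the documented jitter fallback)."""
    outdir = tmp_path_factory.mktemp("noiseless_run")
    config = {
        "seed": 5,
        "zero_variance": "jitter",
        "mcmc": {"n_draws": 500, "n_tune": 300, "n_chains": 2, "predictive_draws": 2000},
        "simulate": {
            "n_normal": 20, "n_tumor": 24, "n_genes": 80, "n_tfs": 8,
            "active_tfs_per_group": 2, "n_subgroups": 3, "targets_per_tf": [4, 6],
            "noise_sd": 0.0, "n_drugs": 12,
        },
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config, outdir)
    return result
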