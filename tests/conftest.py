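import warnings

import numpy as np
import pytest

from marindown import dqm
from marindown.grids import coarsen
from marindown.synthetic import SyntheticConfig, make_member, make_reference

warnings.filterwarnings("ignore", category=RuntimeWarning, message="Mean of empty slice")

TRAINING_WINDOW = (1993, 2020)
PROJECTION_WINDOW = (2021, 2100)


@pytest.fixture(scope="session")
def synth_config() -> SyntheticConfig:
    """Default desk-scale study conditions (24x24 fine grid, factor 6)."""
    return SyntheticConfig()


@pytest.fixture(scope="session")
def reference(synth_config):
    field, truth = make_reference(synth_config)
    return field, truth


@pytest.fixture(scope="session")
def member_245(synth_config):
    field, truth = make_member(synth_config, "model1_r1", "ssp245")
    return field, truth


@pytest.fixture(scope="session")
def ref_coarse(reference, synth_config):
    return coarsen(reference[0], synth_config.coarsen_factor)


@pytest.fixture(scope="session")
def bias_corrected(member_245, ref_coarse):
    return dqm.bias_correct(member_245[0], ref_coarse, training_window=TRAINING_WINDOW)


@pytest.fixture(scope="session")
def downscaled(bias_corrected, reference):
    return dqm.downscale(bias_corrected, reference[0], training_window=TRAINING_WINDOW)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """Full end-to-end synthetic pipeline (2 models x 2 realizations x 3
    scenarios on the desk-scale grid), shared across tests.

    Returns (config, output directory, wall-clock seconds)."""
    import time

    from marindown.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        synthetic={"n_models": 2, "realizations_per_model": 2},
        out_dir=str(out),
        seed=0,
    )
    t0 = time.monotonic()
    run_pipeline(cfg)
    elapsed = time.monotonic() - t0
    return cfg, out, elapsed


def ols_slope(values: np.ndarray, frac_years: np.ndarray) -> float:
    """Independent OLS slope used as the oracle for trend checks."""
    ok = np.isfinite(values)
    t, v = frac_years[ok], values[ok]
    A = np.vstack([t, np.ones_like(t)]).T
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    return float(coef[0])
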