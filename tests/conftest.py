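import numpy as np
import pytest

from faupa import (
    NoiseParams,
    RunConfig,
    block_region,
    build_all_ideal_responses,
    hrf_kernel,
    make_default_paradigm,
    simulate_subject,
)
from faupa.preprocess import preprocess


@pytest.fixture(scope="session")
def paradigm():
    return make_default_paradigm()


@pytest.fixture(scope="session")
def kernel(paradigm):
    return hrf_kernel(paradigm.tr_s)


@pytest.fixture(scope="session")
def ideals(paradigm, kernel):
    return build_all_ideal_responses(paradigm, kernel)


@pytest.fixture(scope="session")
def synth_config():
    """Analysis configuration for simulated data: no spatial smoothing
    (smoothing would blur the planted ground truth itself)."""
    cfg = RunConfig()
    cfg.preprocess.fwhm_mm = 0.0
    return cfg


@pytest.fixture(scope="session")
def three_region_noiseless(paradigm):
    """Three disjoint planted regions (6, 8, 10 voxels) with zero noise."""
    specs = [
        block_region((2, 2, 2), (3, 2, 1), category=("FT",), amplitude_pct=1.2),
        block_region((8, 8, 2), (2, 2, 2), category=("WR",), amplitude_pct=1.2),
        block_region((2, 9, 5), (5, 2, 1), category=("PV",), amplitude_pct=1.2),
    ]
    subj = simulate_subject(
        specs, paradigm=paradigm, noise=NoiseParams(sigma_pct=0.0),
        grid_shape=(16, 16, 8), seed=11,
    )
    return subj


@pytest.fixture(scope="session")
def three_region_pct(three_region_noiseless):
    return preprocess(three_region_noiseless.data, tr_s=2.5, fwhm_mm=0.0)
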