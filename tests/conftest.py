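import numpy as np
import pytest

from countcorr.core_model import LatentParams, build_its_design, simulate_series
from countcorr.glm_core import fit_poisson_glm


@pytest.fixture(scope="session")
def its_fit():
    """One fitted replicate from the study design (n=340, moderate autocorrelation)."""
    design = build_its_design(340, 170, time_scale=340)
    data = simulate_series(design, (1.0, 1.0, 0.0, 0.0), LatentParams(0.5, 0.8), seed=7)
    return fit_poisson_glm(data)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
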