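import numpy as np
import pytest

from bayestics.preprocess import extract_roi, truncate_series
from bayestics.simulate import SceneSpec, render_analytic

# Study-condition constants shared across the suite (matching the generator
# defaults): D = 0.5 px²/frame, sigma_psf = 1.3 px, gain*C0 = 160, ROI 31x31.
D_TRUE = 0.5
SIGMA_PSF = 1.3
GAIN_C0 = 160.0
A_TRUE = 2.0 * np.pi * GAIN_C0**2 * SIGMA_PSF**4


@pytest.fixture(scope="session")
def base_scene() -> SceneSpec:
    return SceneSpec()


@pytest.fixture(scope="session")
def noise_free_stack(base_scene):
    seq, truth = render_analytic(base_scene)
    return seq, truth


@pytest.fixture(scope="session")
def noise_free_roi(noise_free_stack):
    """Centered 31x31 ROI of the noise-free isolated-spot scene, full length."""
    seq, _ = noise_free_stack
    return truncate_series(extract_roi(seq, (30, 30), (31, 31)), 0, seq.n_frames)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
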