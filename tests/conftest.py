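import numpy as np
import pytest

from limbusvd.roi_geometry import LimbusAnnotation
from limbusvd.synthetic_limbus import InjurySpec, SceneParams, generate_scene

SPACING = 9.0 / 256.0


@pytest.fixture(scope="session")
def annotation():
    return LimbusAnnotation(cx=127.5, cy=127.5, r_in_mm=2.5, r_out_mm=3.5)


@pytest.fixture(scope="session")
def default_scene():
    """One uninjured noisy scene at the default study conditions."""
    return generate_scene(SceneParams(seed=42), InjurySpec())


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free uninjured scene (speckle and additive noise disabled)."""
    params = SceneParams(seed=42, speckle_shape=None, additive_sigma=0.0)
    return generate_scene(params, InjurySpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
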