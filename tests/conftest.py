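import numpy as np
import pytest

from wormquant import AFFieldSpec, HyperSceneParams, RatioFieldSpec, make_hyper_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """One noiseless biosensor scene (constant true ratio 1.8) with controls."""
    params = HyperSceneParams(
        shape=(7, 64, 64),
        noise="none",
        ratio_field_spec=RatioFieldSpec("constant", 1.8),
        n_control_subjects=2,
        seed=123,
    )
    return make_hyper_scene(params)


@pytest.fixture(scope="session")
def noisy_controls():
    """Eight Poisson-noise control scenes for bleed-ratio fitting."""
    params = HyperSceneParams(
        shape=(7, 64, 64),
        af_field_spec=AFFieldSpec(amp_range=(50.0, 150.0)),
        noise="poisson",
        n_control_subjects=8,
        seed=42,
    )
    _, controls = make_hyper_scene(params)
    return controls


def control_pairs(controls, channel="405"):
    return [(c.raw_stacks[channel], c.raw_stacks["af"]) for c in controls]


@pytest.fixture
def rng():
    return np.random.default_rng(7)
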