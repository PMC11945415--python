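import numpy as np
import pytest

from headcirc.synthetic import SceneSpec, render_scene


def _base_spec(**overrides) -> SceneSpec:
    defaults = dict(
        head_semi_axes_mm=(60.0, 50.0, 48.0),
        body_semi_axes_mm=(105.0, 48.0, 38.0),
        noise_sigma_mm=0.0,
        seed=1,
        scene_id="fixture",
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def clean_scene():
    """A rendered noiseless, undulation-free scene with oracle truth."""
    return render_scene(_base_spec())


@pytest.fixture(scope="session")
def noisy_scene():
    """Study-condition scene: 1 mm noise, 2% outliers, undulating mat."""
    return render_scene(_base_spec(
        noise_sigma_mm=1.0, outlier_fraction=0.02,
        undulation_amplitude_mm=(3.0, 2.5),
        head_tilt_deg=(6.0, -4.0, 8.0), yaw_deg=25.0, seed=7,
        scene_id="noisy_fixture"))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
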