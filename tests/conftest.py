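import numpy as np
import pytest

from sonosex import synthdata as sd


@pytest.fixture(scope="session")
def clean_spec():
    """One deterministic female phantom with no defects."""
    return sd.sample_individual("F", "large", seed=1, index=0)


@pytest.fixture(scope="session")
def clean_frame(clean_spec):
    return sd.render_frame(clean_spec, frame_index=0, seed=1)


@pytest.fixture(scope="session")
def small_clean_dataset():
    """Defect-free, overlay-free mini dataset (frames, manifest)."""
    cfg = sd.DatasetConfig(
        n_per_sex=4,
        frames_min=3,
        frames_max=5,
        canvas=(64, 64),
        ghost_rate=0.0,
        suppress_rate=0.0,
        truncate_rate=0.0,
        overlay_border_px=0,
        overlay_text_px=0,
    )
    return sd.generate_frames(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
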