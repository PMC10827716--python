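import numpy as np
import pytest

from strokequant.imaging import SectionImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_section(pixels, channel="iba1", ap_mm=0.0, um_per_px=10.0,
                 midline_col=None, lesion_side="right", animal_id="T"):
    pixels = np.asarray(pixels, dtype=float)
    if midline_col is None:
        midline_col = pixels.shape[1] // 2
    return SectionImage(pixels=pixels, ap_mm=ap_mm, um_per_px=um_per_px,
                        midline_col=midline_col, lesion_side=lesion_side,
                        channel=channel, animal_id=animal_id)


@pytest.fixture
def section_factory():
    return make_section
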