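import numpy as np
import pytest

from spinalign.types import RadiographFrame, View


@pytest.fixture
def rng():
    return np.random.default_rng(20250930)


@pytest.fixture
def unit_frames():
    """Frontal/lateral frames with unit spacing and origin at zero."""
    kwargs = dict(pixel_spacing=(1.0, 1.0), origin_mm=(0.0, 0.0, 0.0), image_size_px=(100, 100))
    return (
        RadiographFrame(view=View.FRONTAL, frame_id="f", **kwargs),
        RadiographFrame(view=View.LATERAL, frame_id="l", **kwargs),
    )


def make_frame(view=View.FRONTAL, spacing=(1.0, 1.0), origin=(0.0, 0.0, 0.0), size=(100, 100)):
    return RadiographFrame(view=view, pixel_spacing=spacing, origin_mm=origin, image_size_px=size)
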