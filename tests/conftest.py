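import numpy as np
import pytest

from slicevol import CARROT, Silhouette, extract_silhouette
from slicevol.synthetic import RenderSpec, make_shape, render_top_view


@pytest.fixture(scope="session")
def rect_silhouette() -> Silhouette:
    """Axis-aligned 200 x 50 px rectangle at 20 px/cm (10 cm x 2.5 cm)."""
    mask = np.zeros((300, 400), dtype=bool)
    mask[100:150, 50:250] = True
    return Silhouette(mask=mask, px_per_cm=20.0)


def render_silhouette(shape, px_per_cm=70.0, rotation_deg=0.0, seed=0, **kwargs):
    spec = RenderSpec(px_per_cm=px_per_cm, rotation_deg=rotation_deg, **kwargs)
    image, truth = render_top_view(shape, spec, seed=seed)
    return extract_silhouette(image), truth


@pytest.fixture(scope="session")
def spindle_shape():
    return make_shape("spindle", length=16.0, max_width=4.0, aspect_ratio=CARROT.aspect_ratio)


@pytest.fixture(scope="session")
def spindle_silhouette(spindle_shape):
    sil, truth = render_silhouette(spindle_shape, rotation_deg=30.0)
    return sil, truth
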