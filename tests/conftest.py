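import numpy as np
import pytest

from mps_scope import (
    BraidSceneParams,
    Polyline,
    SceneParams,
    make_braid_image,
    make_mps_localizations,
    reconstruct,
)


def render_scene(params: SceneParams, pixel_size: float = 16.0):
    """Simulate + render with bounds covering the nominal axon footprint."""
    table, gt = make_mps_localizations(params)
    pad = 8 * params.localization_precision_sd + 40
    bounds = (
        (-pad, params.axon_length + pad),
        (-params.axon_width / 2 - pad, params.axon_width / 2 + pad),
    )
    image = reconstruct(table, pixel_size=pixel_size, bounds=bounds)
    return table, gt, image


def axis_trace(params: SceneParams, band_width: float = 160.0) -> Polyline:
    """Straight tracing along the (angle-0) axon axis from ground truth."""
    return Polyline(
        np.array([[0.0, 0.0], [params.axon_length, 0.0]]), band_width=band_width
    )


@pytest.fixture(scope="session")
def mps_scene():
    """A default periodic scaffold scene: (params, table, gt, image)."""
    params = SceneParams(seed=7)
    table, gt, image = render_scene(params)
    return params, table, gt, image


@pytest.fixture(scope="session")
def braid_scene():
    """A default noiseless braid image: (params, image, gt)."""
    params = BraidSceneParams(seed=3)
    image, gt = make_braid_image(params)
    return params, image, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
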