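import numpy as np
import pytest

from histotile.slide import SlidePyramid
from histotile.synth import PenMark, SlideSpec, TissueBlob, synth_pyramid


@pytest.fixture(scope="session")
def basic_spec():
    """Small slide: two tissue blobs on clean background, 3-level pyramid."""
    return SlideSpec(
        width_um=4096,
        height_um=4096,
        level_mpps=(1.0, 4.0, 16.0),
        tissue_blobs=(
            TissueBlob((1400, 1500), 900),
            TissueBlob((2900, 2800), 700),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def basic_slide(basic_spec):
    return synth_pyramid(basic_spec, slide_id="basic")


@pytest.fixture(scope="session")
def pen_spec():
    """Slide with a centimeter-scale pen mark next to textured tissue."""
    return SlideSpec(
        width_um=12000,
        height_um=10000,
        level_mpps=(4.0, 16.0),
        tissue_blobs=(
            TissueBlob((3200, 3200), 2400),
            TissueBlob((8200, 6800), 2000),
        ),
        pen_marks=(
            PenMark(((5600, 400), (11600, 400), (11600, 4900), (5600, 4900))),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def pen_slide(pen_spec):
    return synth_pyramid(pen_spec, slide_id="penmark")


def checkerboard_pyramid(square_um=512.0, n=8, mpps=(1.0, 4.0), dark=40, light=215):
    """Pyramid whose level 0 is an n x n checkerboard of uniform squares."""
    mpp0 = mpps[0]
    sq_px = int(square_um / mpp0)
    size = sq_px * n
    tile_idx = (np.arange(size) // sq_px)
    board = (tile_idx[:, None] + tile_idx[None, :]) % 2
    level0 = np.where(board[..., None] == 0, dark, light).astype(np.uint8)
    level0 = np.repeat(level0, 3, axis=2)
    arrays = [level0]
    for mpp in mpps[1:]:
        step = int(mpp / mpp0)
        arrays.append(level0[::step, ::step])
    return SlidePyramid.from_arrays("checker", arrays, list(mpps))


@pytest.fixture
def checker():
    return checkerboard_pyramid()
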