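import numpy as np
import pytest

from mosquitrack.detection import Frame


@pytest.fixture
def white_frame():
    """Uniform light background, nothing to detect."""
    return Frame(index=0, pixels=np.full((64, 64), 230, dtype=np.uint8))


def paint_disk(pixels: np.ndarray, cx: float, cy: float, radius: float, intensity: float) -> None:
    ys, xs = np.mgrid[0 : pixels.shape[0], 0 : pixels.shape[1]]
    mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    pixels[mask] = intensity


@pytest.fixture
def disk_frame():
    """64x64 white frame with one dark disk centered at (20, 30)."""
    px = np.full((64, 64), 230, dtype=np.uint8)
    paint_disk(px, 20, 30, 4, 40)
    return Frame(index=0, pixels=px)


@pytest.fixture
def two_disk_frame():
    """Two well-separated dark disks."""
    px = np.full((64, 64), 230, dtype=np.uint8)
    paint_disk(px, 15, 15, 4, 40)
    paint_disk(px, 45, 45, 4, 40)
    return Frame(index=0, pixels=px)
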