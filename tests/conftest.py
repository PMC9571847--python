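import numpy as np
import pytest
from PIL import Image


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def write_png(tmp_path):
    """Write a uint8 H×W×3 array as PNG and return the path."""

    def _write(arr, name="img.png"):
        path = tmp_path / name
        Image.fromarray(np.asarray(arr, dtype=np.uint8)).save(path)
        return path

    return _write


@pytest.fixture
def constant_image():
    """Build an in-memory ImageRecord of a constant colour."""
    from cvchroma.imaging import ImageRecord

    def _make(rgb, shape=(10, 10)):
        arr = np.empty((*shape, 3), dtype=np.uint8)
        arr[:] = rgb
        return ImageRecord(pixels=arr)

    return _make
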