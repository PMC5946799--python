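import numpy as np
import pytest

from spimpiv.scenes import SceneConfig


@pytest.fixture
def small_scene() -> SceneConfig:
    """A small, fast scene used across unit tests (noise-free by default)."""
    return SceneConfig(image_shape=(64, 96), seeding_density=0.5,
                       tracer_diameter=2.0, pixel_size=0.5, dt=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def brute_force_sad(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Independent double-loop SAD oracle (raw, un-negated)."""
    h, w = a.shape
    H, W = b.shape
    out = np.zeros((H - h + 1, W - w + 1))
    for i in range(H - h + 1):
        for j in range(W - w + 1):
            s = 0.0
            for r in range(h):
                for c in range(w):
                    s += abs(a[r, c] - b[i + r, j + c])
            out[i, j] = s
    return out
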