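import numpy as np
import pytest

from cervitex.synthetic import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cfg():
    """Small but non-trivial synthetic dataset configuration."""
    return SyntheticConfig(n_images_per_class=3, seed=11)


def brute_force_glcm(qband, levels, distance=1, angles=(0, 45, 90, 135),
                     symmetric=True):
    """Independent pair-enumeration GLCM oracle (loops, no vectorization)."""
    offsets = {0: (0, distance), 45: (distance, distance),
               90: (distance, 0), 135: (distance, -distance)}
    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = qband.shape
    for ang in angles:
        dr, dc = offsets[ang]
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    counts[qband[r, c], qband[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()
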