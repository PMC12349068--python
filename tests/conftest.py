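import numpy as np
import pytest


@pytest.fixture
def ring_field():
    """3x3 plateau with a bright center: one hole born at 1, dying at 9."""
    return np.array([[1, 1, 1], [1, 9, 1], [1, 1, 1]], dtype=float)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def count_local_extrema(z: np.ndarray) -> tuple[int, int, int]:
    """(n_minima, n_maxima, n_interior_maxima) of a distinct-valued field
    under the 6-neighborhood of the Freudenthal triangulation: axis
    neighbors plus the (+1,+1) and (-1,-1) diagonals.  "Interior" means
    not on the image border."""
    h, w = z.shape
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1), (1, 1), (-1, -1)]
    n_min = n_max = n_max_int = 0
    for i in range(h):
        for j in range(w):
            vals = [
                z[i + di, j + dj]
                for di, dj in offsets
                if 0 <= i + di < h and 0 <= j + dj < w
            ]
            if all(z[i, j] < v for v in vals):
                n_min += 1
            if all(z[i, j] > v for v in vals):
                n_max += 1
                if 0 < i < h - 1 and 0 < j < w - 1:
                    n_max_int += 1
    return n_min, n_max, n_max_int
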