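import numpy as np
import pytest

from fmshift import ABFeatures, build_grid, compute_integrals


def feats_from_points(pts: np.ndarray) -> ABFeatures:
    """Wrap an (n, 2) point set as a degenerate n x 1 feature image."""
    pts = np.asarray(pts, dtype=float)
    return ABFeatures(a=pts[:, 0].reshape(-1, 1), b=pts[:, 1].reshape(-1, 1))


def grid_and_tables(pts: np.ndarray, e: float):
    grid = build_grid(feats_from_points(pts), e)
    return grid, compute_integrals(grid)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
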