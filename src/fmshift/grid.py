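"""Grid density estimation and summed-area tables for the feature space.

The (a*, b*) feature points of an image all lie inside a bounded rectangle R.
R is tiled with tiny squares of side 2e; each cell (i, j) stores the number of
points that fall in it, w(i, j), and its geometric centre c(i, j).  The pair
(w, c) is a histogram-style density estimate: a window sum over w approximates
the number of points in that window, and a window sum over w*c approximates
their coordinate sum.  Cumulative (summed-area) tables

    W(k, l) = sum_{i<=k, j<=l} w(i, j)
    M(k, l) = sum_{i<=k, j<=l} w(i, j) * c(i, j)

turn any axis-aligned box sum into four table lookups, which is what makes the
mean-shift vector O(1) per evaluation regardless of image size.

Conventions (fixed, and relied on by every downstream module):

* cells are half-open ``[lo, lo + 2e)`` along each axis, with the top cell
  closed, so each point lands in exactly one cell and interior boundary ties
  go to the higher-index cell;
* box sums use the exclusive lower-corner convention — the sum over cells
  ``m-h_c..m+h_c`` x ``n-h_c..n+h_c`` is
  ``T[i1,j1] - T[i0-1,j1] - T[i1,j0-1] + T[i0-1,j0-1]`` with the table treated
  as zero at index -1 — making the four-lookup result EXACTLY the inclusive
  double sum;
* windows are clipped at the grid edges (frequency outside the grid is zero).

Indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color import ABFeatures

__all__ = [
    "DensityGrid",
    "IntegralTables",
    "build_grid",
    "default_e",
    "compute_integrals",
    "box_sum",
    "locate_cell",
]


@dataclass(frozen=True)
class DensityGrid:
    """Frequency matrix ``w`` and centre matrix ``c`` over the occupied region.

    Attributes
    ----------
    e
        Half side length of a tiny square (cell side is 2e), in feature units.
    bounds
        ``(a_min, a_max, b_min, b_max)`` of the observed points; the grid
        starts at (a_min, b_min) and extends to a whole number of cells.
    w
        (G_a, G_b) integer frequency matrix.
    c
        (G_a, G_b, 2) cell-centre coordinates.
    n_points
        Total number of binned feature points; equals ``w.sum()``.
    """

    e: float
    bounds: tuple[float, float, float, float]
    w: np.ndarray
    c: np.ndarray
    n_points: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.w.shape

    def occupied_cells(self) -> np.ndarray:
        """Indices (row-major order) of cells with at least one point."""
        return np.argwhere(self.w > 0)

    def save(self, path) -> None:
        """Archive cell size, bounds and matrices (numpy .npz)."""
        np.savez(path, e=self.e, bounds=np.asarray(self.bounds), w=self.w,
                 c=self.c, n_points=self.n_points)

    @classmethod
    def load(cls, path) -> "DensityGrid":
        d = np.load(path)
        return cls(e=float(d["e"]), bounds=tuple(d["bounds"]), w=d["w"],
                   c=d["c"], n_points=int(d["n_points"]))


@dataclass(frozen=True)
class IntegralTables:
    """Summed-area tables of the frequency and weighted-centre matrices."""

    W: np.ndarray  #: (G_a, G_b) cumulative frequency
    M: np.ndarray  #: (G_a, G_b, 2) cumulative frequency-weighted centres

    def save(self, path) -> None:
        np.savez(path, W=self.W, M=self.M)

    @classmethod
    def load(cls, path) -> "IntegralTables":
        d = np.load(path)
        return cls(W=d["W"], M=d["M"])


def default_e(feats: ABFeatures) -> float:
    """Cell half-width rule: one thousandth of the larger channel range.

    ``e = max(range(a*), range(b*)) / 1000``.  Raises for a constant image,
    whose feature space has zero extent on both axes.
    """
    ra = float(feats.a.max() - feats.a.min())
    rb = float(feats.b.max() - feats.b.min())
    r = max(ra, rb)
    if r <= 0.0:
        raise ValueError("degenerate feature space: zero range on both a* and b*")
    return r / 1000.0


def build_grid(feats: ABFeatures, e: float) -> DensityGrid:
    """Bin feature points into cells of side 2e and record counts and centres."""
    if not e > 0.0:
        raise ValueError(f"cell half-width e must be positive, got {e}")
    pts = feats.points()
    if pts.size == 0:
        raise ValueError("empty feature set")

    side = 2.0 * e
    a_min, b_min = pts.min(axis=0)
    a_max, b_max = pts.max(axis=0)
    g_a = max(1, int(np.ceil((a_max - a_min) / side))) if a_max > a_min else 1
    g_b = max(1, int(np.ceil((b_max - b_min) / side))) if b_max > b_min else 1

    ia = np.clip(np.floor((pts[:, 0] - a_min) / side).astype(np.int64), 0, g_a - 1)
    ib = np.clip(np.floor((pts[:, 1] - b_min) / side).astype(np.int64), 0, g_b - 1)
    w = np.bincount(ia * g_b + ib, minlength=g_a * g_b).reshape(g_a, g_b)

    ca = a_min + (np.arange(g_a) + 0.5) * side
    cb = b_min + (np.arange(g_b) + 0.5) * side
    c = np.stack(np.meshgrid(ca, cb, indexing="ij"), axis=-1)

    return DensityGrid(
        e=float(e),
        bounds=(float(a_min), float(a_max), float(b_min), float(b_max)),
        w=w,
        c=c,
        n_points=int(pts.shape[0]),
    )


def compute_integrals(grid: DensityGrid) -> IntegralTables:
    """Cumulative tables of w and w*c (single pass along each axis)."""
    W = grid.w.astype(np.float64).cumsum(axis=0).cumsum(axis=1)
    wc = grid.w[..., None].astype(np.float64) * grid.c
    M = wc.cumsum(axis=0).cumsum(axis=1)
    return IntegralTables(W=W, M=M)


def _box_sum_clipped(T: np.ndarray, m, n, h_c) -> np.ndarray:
    """Four-lookup window sum, vectorised over (m, n); window clipped to grid.

    Works for 2-D tables (W) and 3-D per-coordinate tables (M); in the latter
    case the trailing axis is carried through.
    """
    g_a, g_b = T.shape[:2]
    m = np.asarray(m)
    n = np.asarray(n)
    i0 = np.maximum(m - h_c, 0)
    j0 = np.maximum(n - h_c, 0)
    i1 = np.minimum(m + h_c, g_a - 1)
    j1 = np.minimum(n + h_c, g_b - 1)

    def at(i, j):
        # exclusive lower corner: index -1 contributes zero
        valid = (i >= 0) & (j >= 0)
        v = T[np.maximum(i, 0), np.maximum(j, 0)]
        if T.ndim == 3:
            return np.where(valid[..., None], v, 0.0)
        return np.where(valid, v, 0.0)

    return at(i1, j1) - at(i0 - 1, j1) - at(i1, j0 - 1) + at(i0 - 1, j0 - 1)


def box_sum(T: np.ndarray, m: int, n: int, h_c: int):
    """Sum of ``w`` (or ``w*c``) over cells within ``h_c`` of cell (m, n).

    ``T`` is a cumulative table from :func:`compute_integrals`.  The window
    ``m-h_c..m+h_c`` x ``n-h_c..n+h_c`` is clipped to the grid.  Returns a
    scalar for a 2-D table and a length-2 vector for the 3-D centre table.
    """
    g_a, g_b = T.shape[:2]
    if not (0 <= m < g_a and 0 <= n < g_b):
        raise IndexError(f"cell ({m}, {n}) outside {g_a} x {g_b} grid")
    if h_c < 0:
        raise ValueError("window half-width must be non-negative")
    out = _box_sum_clipped(T, m, n, h_c)
    return out if T.ndim == 3 else float(out)


def locate_cell(x: np.ndarray, grid: DensityGrid):
    """Cell index (m, n) of a feature point; outside points clamp to the edge.

    Vectorised: ``x`` may be a single (2,) point or an (N, 2) array.  Clamping
    (rather than erroring) absorbs the small numerical drift that mean-shift
    iterates can accumulate at the boundary of the occupied region.
    """
    x = np.asarray(x, dtype=np.float64)
    side = 2.0 * grid.e
    a_min, _, b_min, _ = grid.bounds
    g_a, g_b = grid.shape
    m = np.clip(np.floor((x[..., 0] - a_min) / side).astype(np.int64), 0, g_a - 1)
    n = np.clip(np.floor((x[..., 1] - b_min) / side).astype(np.int64), 0, g_b - 1)
    if x.ndim == 1:
        return int(m), int(n)
    return m, n
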