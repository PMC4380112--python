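"""Mean-shift vectors, mode seeking and mode-region partitioning.

The mean-shift vector (MSV) with a uniform kernel at a point x is the
displacement from x to the mean of the observations inside a window around x:

    m_h(x) = (1/K) * sum_{x_i in window(x)} (x_i - x)

Iterating ``x <- x + m_h(x)`` climbs the estimated density; its stationary
points are the density modes, and points converging to the same mode form one
cluster.

Three window variants appear here, forming an oracle chain:

* :func:`exact_msv` — sphere of radius h (the textbook definition);
* :func:`exact_square_msv` — the circumscribing square (Chebyshev ball of
  half-width h), the intermediate approximation;
* :func:`fast_msv` — the square window evaluated on the grid density
  estimate via four summed-area-table lookups, replacing each point by its
  cell centre.  Cost is O(1) per evaluation, independent of image size.

Mode seeking starts from the centre of every occupied grid cell (not from raw
pixels), which is what decouples the clustering cost from the pixel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .grid import DensityGrid, IntegralTables, _box_sum_clipped, locate_cell

__all__ = [
    "MsvParams",
    "ModeSet",
    "ModeSeekResult",
    "exact_msv",
    "exact_square_msv",
    "fast_msv",
    "seek_mode",
    "find_modes",
]


@dataclass(frozen=True)
class MsvParams:
    """Window size and iteration controls for mode seeking.

    Parameters
    ----------
    h
        Window size in feature units: sphere radius / square half-width.
    e
        Cell half-width of the grid the fast path runs on; used to derive the
        integer window half-width in cells, ``h_c = round(h / (2e))``.
    tol
        Convergence threshold on the Euclidean norm of the MSV.  Default
        ``max(e, 1e-3 * h)`` — tolerances below the cell resolution carry no
        information.
    max_iter
        Iteration cap per seed (non-convergence is flagged, never raised).
    merge_radius
        Converged points closer than this to an existing mode are merged into
        it.  Default ``h``: at bandwidth h the density estimate cannot resolve
        peaks closer than one window, and uniform-kernel iterates stall on
        plateaus scattered across a basin, so anything nearer than h is the
        same mode.
    """

    h: float
    e: float
    tol: float = field(default=None)  # type: ignore[assignment]
    max_iter: int = 100
    merge_radius: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (self.h > 0 and self.e > 0):
            raise ValueError("h and e must be positive")
        if self.h < 10.0 * self.e:
            warnings.warn(
                f"window size h={self.h:g} is not much larger than cell size "
                f"e={self.e:g}; the grid approximation degrades for h < 10 e",
                stacklevel=2,
            )
        if self.tol is None:
            object.__setattr__(self, "tol", max(self.e, 1e-3 * self.h))
        if self.merge_radius is None:
            object.__setattr__(self, "merge_radius", self.h)
        if not (self.tol > 0 and self.tol < self.h):
            raise ValueError("tol must satisfy 0 < tol < h")
        if not self.merge_radius > 0:
            raise ValueError("merge_radius must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")

    @property
    def h_c(self) -> int:
        """Window half-width in whole cells: h feature units span h/(2e) cells."""
        return max(1, int(round(self.h / (2.0 * self.e))))


@dataclass(frozen=True)
class ModeSet:
    """Density modes plus the mode assignment of every occupied grid cell.

    ``modes`` are sorted by ``mode_mass`` descending (ties: row-major order of
    the first contributing cell); ``cell_mode`` maps each grid cell to a mode
    index, -1 for empty cells.
    """

    modes: np.ndarray  #: (M, 2) mode points in (a*, b*) space
    cell_mode: np.ndarray  #: (G_a, G_b) int mode index per cell, -1 if empty
    mode_mass: np.ndarray  #: (M,) total point frequency per mode
    seed_iters: np.ndarray | None = None  #: iterations per seed (row-major occupied order)

    @property
    def n_modes(self) -> int:
        return len(self.modes)

    def to_csv(self, path) -> None:
        """Export modes as CSV (index, a*, b*, mass) for inspection."""
        arr = np.column_stack([np.arange(self.n_modes), self.modes, self.mode_mass])
        np.savetxt(path, arr, delimiter=",", header="mode,a,b,mass",
                   comments="", fmt=["%d", "%.10g", "%.10g", "%d"])


class ModeSeekResult(NamedTuple):
    point: np.ndarray
    n_iter: int
    converged: bool
    vacuum: bool = False


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=np.float64)
    if pts.size == 0:
        raise ValueError("empty point set")
    return pts.reshape(-1, 2)


def exact_msv(points, x, h: float) -> np.ndarray:
    """Uniform-kernel MSV over the sphere of radius h centred at x.

    Returns the zero vector when no point lies in the window (vacuum).
    """
    if not h > 0:
        raise ValueError("h must be positive")
    pts = _as_points(points)
    x = np.asarray(x, dtype=np.float64)
    inside = ((pts - x) ** 2).sum(axis=1) <= h * h
    if not inside.any():
        return np.zeros(2)
    return pts[inside].mean(axis=0) - x


def exact_square_msv(points, x, h: float) -> np.ndarray:
    """MSV over the circumscribing square: membership ``||x_i - x||_inf <= h``."""
    if not h > 0:
        raise ValueError("h must be positive")
    pts = _as_points(points)
    x = np.asarray(x, dtype=np.float64)
    inside = np.abs(pts - x).max(axis=1) <= h
    if not inside.any():
        return np.zeros(2)
    return pts[inside].mean(axis=0) - x


def _fast_msv_batch(tables: IntegralTables, grid: DensityGrid, X: np.ndarray,
                    h_c: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised fast MSV for an (N, 2) array of points.

    Returns (vectors, window masses); zero vector where the window is empty.
    """
    m, n = locate_cell(X, grid)
    K = _box_sum_clipped(tables.W, m, n, h_c)
    S = _box_sum_clipped(tables.M, m, n, h_c)
    K = np.atleast_1d(K)
    S = S.reshape(-1, 2)
    v = np.zeros_like(S)
    occupied = K > 0
    v[occupied] = S[occupied] / K[occupied, None] - X.reshape(-1, 2)[occupied]
    return v, K


def fast_msv(tables: IntegralTables, grid: DensityGrid, x, p: MsvParams,
             *, return_mass: bool = False):
    """Grid-approximated square-window MSV from four table lookups.

    Locates the cell of x, divides the weighted-centre box sum (table M) by
    the frequency box sum (table W) and subtracts x.  An empty window
    ("vacuum") yields the zero vector; pass ``return_mass=True`` to detect it
    from the window mass.
    """
    x = np.asarray(x, dtype=np.float64)
    v, K = _fast_msv_batch(tables, grid, x.reshape(1, 2), p.h_c)
    vec, mass = v[0], float(K[0])
    return (vec, mass) if return_mass else vec


def seek_mode(start, tables: IntegralTables, grid: DensityGrid,
              p: MsvParams) -> ModeSeekResult:
    """Iterate ``x <- x + fast_msv(x)`` until ||MSV|| < tol or max_iter.

    A vacuum window (no mass within the square) terminates immediately at the
    current point — the uniform-kernel MSV is undefined there.
    """
    x = np.asarray(start, dtype=np.float64).copy()
    for it in range(p.max_iter):
        v, mass = fast_msv(tables, grid, x, p, return_mass=True)
        if mass == 0:
            return ModeSeekResult(x, it, converged=False, vacuum=True)
        if float(np.hypot(v[0], v[1])) < p.tol:
            return ModeSeekResult(x, it, converged=True)
        x = x + v
    return ModeSeekResult(x, p.max_iter, converged=False)


def _merge_converged(converged: np.ndarray, merge_radius: float) -> tuple[np.ndarray, np.ndarray]:
    """First-come mode merging.

    Walks converged points in order; a point within ``merge_radius`` of an
    existing mode joins the nearest such mode, otherwise it becomes the
    canonical representative of a new mode.  Returns (modes (M,2),
    assignment (N,)).
    """
    modes: list[np.ndarray] = []
    assign = np.empty(len(converged), dtype=np.int64)
    mode_arr = np.empty((0, 2))
    for i, pt in enumerate(converged):
        if len(modes):
            d = np.sqrt(((mode_arr - pt) ** 2).sum(axis=1))
            j = int(np.argmin(d))
            if d[j] < merge_radius:
                assign[i] = j
                continue
        modes.append(pt)
        mode_arr = np.asarray(modes)
        assign[i] = len(modes) - 1
    return mode_arr, assign


def find_modes(tables: IntegralTables, grid: DensityGrid, p: MsvParams) -> ModeSet:
    """Seek a mode from every occupied cell centre and partition the grid.

    All seeds are iterated in lockstep (each freezes once its own MSV drops
    below tol), converged points are merged within ``merge_radius``
    (candidate order = row-major cell order), and each occupied cell inherits
    the mode of its seed.  Modes are sorted by total mass descending, ties
    broken by the row-major order of the first contributing cell.
    """
    occ = grid.occupied_cells()  # row-major
    seeds = grid.c[occ[:, 0], occ[:, 1]].astype(np.float64)
    X = seeds.copy()
    active = np.ones(len(X), dtype=bool)
    iters = np.full(len(X), p.max_iter, dtype=np.int64)
    for it in range(p.max_iter):
        if not active.any():
            break
        v, K = _fast_msv_batch(tables, grid, X[active], p.h_c)
        norms = np.sqrt((v ** 2).sum(axis=1))
        done = (norms < p.tol) | (K == 0)
        idx = np.flatnonzero(active)
        X[idx[~done]] += v[~done]
        active[idx[done]] = False
        iters[idx[done]] = it

    modes, assign = _merge_converged(X, p.merge_radius)

    masses = np.bincount(assign, weights=grid.w[occ[:, 0], occ[:, 1]],
                         minlength=len(modes))
    # stable sort: creation order already matches row-major first-cell order
    order = np.argsort(-masses, kind="stable")
    rank = np.empty(len(modes), dtype=np.int64)
    rank[order] = np.arange(len(modes))

    cell_mode = np.full(grid.shape, -1, dtype=np.int64)
    cell_mode[occ[:, 0], occ[:, 1]] = rank[assign]
    return ModeSet(modes=modes[order], cell_mode=cell_mode,
                   mode_mass=masses[order], seed_iters=iters)
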