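"""End-to-end colour segmentation pipelines.

The fast pipeline runs the three stages in sequence:

1. convert the RGB image to CIE L*a*b* and keep the (a*, b*) channels;
2. bin the feature points into a grid of tiny squares, build the summed-area
   tables, and find the density modes by mean shift seeded at occupied cell
   centres;
3. label every pixel through its grid cell's mode assignment (a constant-time
   lookup), prune to the k most massive clusters and reassign the rest to the
   nearest kept mode.

No spatial information is used anywhere — labels depend on pixel colour only.

A standard mean-shift segmenter operating directly on the raw per-pixel
feature points (spherical window, exact MSV) is provided as the reference the
fast path is validated against; its per-sweep cost is quadratic in the pixel
count, so it is guarded to small images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .color import ABFeatures, extract_ab, rgb_to_lab
from .grid import build_grid, compute_integrals, default_e, locate_cell
from .meanshift import ModeSet, MsvParams, _merge_converged, find_modes

__all__ = [
    "LabelMap",
    "PipelineConfig",
    "fmshift_segment",
    "prune_to_top_k",
    "standard_ms_segment",
]

#: standard_ms_segment refuses images larger than this (pixels) unless forced.
STANDARD_MS_MAX_PIXELS = 200 * 200


@dataclass(frozen=True)
class LabelMap:
    """Per-pixel integer cluster labels.

    Labels are 0-based and contiguous, sorted by cluster size so that label 0
    is always the largest cluster; ``provenance`` records the parameters that
    produced the map.
    """

    labels: np.ndarray  #: H x W int array, values in [0, k)
    k: int
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.labels.ravel(), minlength=self.k)


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the fast segmentation pipeline.

    ``e="auto"`` applies the default rule (max channel range / 1000);
    ``h = h_mult * e`` with the default multiplier 40.  ``k`` is the number of
    clusters kept after pruning.
    """

    k: int = 3
    e: object = "auto"  # "auto" | positive float
    h_mult: float = 40.0
    tol: Optional[float] = None
    max_iter: int = 100
    merge_radius: Optional[float] = None
    illuminant: str = "D65"
    seed: Optional[int] = None  # synthetic generation only; pipeline is deterministic

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        if self.e != "auto" and not (isinstance(self.e, (int, float)) and self.e > 0):
            raise ValueError('e must be "auto" or a positive number')
        if not self.h_mult > 0:
            raise ValueError("h_mult must be positive")


def _sort_labels_by_size(labels: np.ndarray, n_labels: int) -> tuple[np.ndarray, np.ndarray]:
    """Remap labels so that 0 is the largest cluster; stable in ties."""
    sizes = np.bincount(labels.ravel(), minlength=n_labels)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty(n_labels, dtype=np.int64)
    rank[order] = np.arange(n_labels)
    return rank[labels], sizes[order]


def prune_to_top_k(modes: ModeSet, k: int) -> ModeSet:
    """Keep the k most massive modes; reassign the cells of dropped modes.

    Each dropped mode's cells move as a block to the kept mode whose mode
    point is nearest in Euclidean (a*, b*) distance (ties to the larger-mass,
    i.e. lower-index, mode).  The result is re-sorted by aggregated mass.
    Fewer than k modes is not an error: they are returned unchanged with a
    warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    m = modes.n_modes
    if m <= k:
        if m < k:
            warnings.warn(f"only {m} modes available, fewer than requested k={k}",
                          stacklevel=2)
        return modes

    kept = modes.modes[:k]
    # map: old mode index -> kept mode index
    remap = np.arange(m)
    for j in range(k, m):
        d = np.sqrt(((kept - modes.modes[j]) ** 2).sum(axis=1))
        remap[j] = int(np.argmin(d))  # argmin ties -> lower index = larger mass

    mass = np.bincount(remap, weights=modes.mode_mass, minlength=k)[:k]
    order = np.argsort(-mass, kind="stable")
    rank = np.empty(k, dtype=np.int64)
    rank[order] = np.arange(k)

    cell_mode = modes.cell_mode.copy()
    occ = cell_mode >= 0
    cell_mode[occ] = rank[remap[cell_mode[occ]]]
    return ModeSet(modes=kept[order], cell_mode=cell_mode, mode_mass=mass[order])


def fmshift_segment(img: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> LabelMap:
    """Fast mean-shift segmentation of a colour image.

    Returns a :class:`LabelMap` with at most ``cfg.k`` labels sorted by
    cluster size descending.  A constant-colour image cannot support more
    than one cluster and degrades to a single-label result with a warning.
    """
    lab = rgb_to_lab(img, illuminant=cfg.illuminant, drop_alpha=True)
    feats = extract_ab(lab)

    try:
        e = default_e(feats) if cfg.e == "auto" else float(cfg.e)
    except ValueError:
        if cfg.k > 1:
            warnings.warn("constant-colour image: returning a single cluster",
                          stacklevel=2)
        return LabelMap(labels=np.zeros(feats.shape, dtype=np.int64), k=1,
                        provenance={"degenerate": True, "k_requested": cfg.k})

    h = cfg.h_mult * e
    params = MsvParams(h=h, e=e, tol=cfg.tol, max_iter=cfg.max_iter,
                       merge_radius=cfg.merge_radius)
    grid = build_grid(feats, e)
    tables = compute_integrals(grid)
    modes = find_modes(tables, grid, params)
    modes = prune_to_top_k(modes, cfg.k)

    m, n = locate_cell(feats.points(), grid)
    labels = modes.cell_mode[m, n].reshape(feats.shape)
    labels, _ = _sort_labels_by_size(labels, modes.n_modes)

    return LabelMap(
        labels=labels,
        k=modes.n_modes,
        provenance={
            "method": "fmshift",
            "e": e, "h": h, "h_c": params.h_c, "k": cfg.k,
            "tol": params.tol, "max_iter": params.max_iter,
            "merge_radius": params.merge_radius, "illuminant": cfg.illuminant,
            "n_modes_before_pruning": None,
        },
    )


def _standard_ms_modes(pts: np.ndarray, h: float, tol: float, max_iter: int,
                       chunk: int = 1024) -> np.ndarray:
    """Exact spherical-window mode seeking from every raw feature point.

    Vectorised in chunks; each point freezes once its own MSV norm drops
    below tol (or its window empties, which cannot happen for a seed sitting
    on a data point).  Returns the (n, 2) converged positions.
    """
    X = pts.copy()
    active = np.ones(len(X), dtype=bool)
    h2 = h * h
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        for s in range(0, idx.size, chunk):
            sel = idx[s:s + chunk]
            d2 = ((X[sel, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
            inside = d2 <= h2
            K = inside.sum(axis=1)
            K = np.maximum(K, 1)
            means = (inside[:, :, None] * pts[None, :, :]).sum(axis=1) / K[:, None]
            v = means - X[sel]
            done = np.sqrt((v ** 2).sum(axis=1)) < tol
            X[sel[~done]] += v[~done]
            active[sel[done]] = False
    return X


def standard_ms_segment(img: np.ndarray, h: Optional[float] = None, k: int = 3,
                        tol: Optional[float] = None, max_iter: int = 100,
                        merge_radius: Optional[float] = None,
                        force: bool = False) -> LabelMap:
    """Reference segmenter: exact mean shift on the raw (a*, b*) points.

    Every pixel's feature point is iterated with the spherical-window MSV
    over all n points, so one sweep costs O(n^2); images larger than
    200 x 200 pixels are refused unless ``force=True``.  Merging and top-k
    pruning follow the same rules as the fast path.
    """
    lab = rgb_to_lab(img, drop_alpha=True)
    feats = extract_ab(lab)
    if feats.n > STANDARD_MS_MAX_PIXELS and not force:
        raise ValueError(
            f"image has {feats.n} pixels; standard mean shift is O(n^2) per "
            f"sweep and is limited to {STANDARD_MS_MAX_PIXELS} (use force=True)")
    if k < 1:
        raise ValueError("k must be at least 1")

    pts = feats.points()
    try:
        e = default_e(feats)
    except ValueError:
        if k > 1:
            warnings.warn("constant-colour image: returning a single cluster",
                          stacklevel=2)
        return LabelMap(labels=np.zeros(feats.shape, dtype=np.int64), k=1,
                        provenance={"degenerate": True, "method": "standard-ms"})
    if h is None:
        h = 40.0 * e
    if tol is None:
        tol = max(e, 1e-3 * h)
    if merge_radius is None:
        merge_radius = h

    converged = _standard_ms_modes(pts, h, tol, max_iter)
    modes, assign = _merge_converged(converged, merge_radius)
    mass = np.bincount(assign, minlength=len(modes)).astype(float)

    order = np.argsort(-mass, kind="stable")
    rank = np.empty(len(modes), dtype=np.int64)
    rank[order] = np.arange(len(modes))
    labels = rank[assign]
    modes, mass = modes[order], mass[order]

    # top-k pruning by mode distance, mirroring the fast path
    if len(modes) > k:
        kept = modes[:k]
        remap = np.arange(len(modes))
        for j in range(k, len(modes)):
            d = np.sqrt(((kept - modes[j]) ** 2).sum(axis=1))
            remap[j] = int(np.argmin(d))
        labels = remap[labels]
        n_labels = k
    else:
        if len(modes) < k:
            warnings.warn(f"only {len(modes)} modes available, fewer than k={k}",
                          stacklevel=2)
        n_labels = len(modes)

    labels, _ = _sort_labels_by_size(labels, n_labels)
    return LabelMap(
        labels=labels.reshape(feats.shape),
        k=n_labels,
        provenance={"method": "standard-ms", "h": h, "k": k, "tol": tol,
                    "max_iter": max_iter, "merge_radius": merge_radius},
    )
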