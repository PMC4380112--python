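"""Ground-truth-labelled synthetic fixtures.

Real trichrome-stained liver sections show three dominant colour classes:
thin, elongated light-blue ribbons of fibrotic collagen, roughly elliptical
white vessel/sinusoid lumina, and a lavender background of other tissue.
The generator reproduces that statistical structure — class geometry, mean
stain colours in L*a*b*, and per-class Gaussian colour noise — so that every
pipeline stage can be exercised against a known pixel-level ground truth.

Geometry is drawn directly on the label image: elliptical blobs for vessels
and smooth random-walk ribbons 2–6 px wide for fibrosis, each class painted
until its requested area fraction is met.  Colours are synthesised in Lab
space (where the clustering operates, making class separability directly
controllable) and converted to 8-bit sRGB.

All randomness flows from a single integer seed through
``numpy.random.default_rng`` (PCG64); fixed seed ⇒ bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color as _skcolor
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse

from .segment import LabelMap

__all__ = [
    "TissueClass",
    "TissueSpec",
    "MixtureSpec",
    "default_tissue_spec",
    "make_label_image",
    "render_histology",
    "make_histology_image",
    "make_point_cloud",
]

#: Default 3-class stain palette (fixture constants chosen for a plausible
#: trichrome rendering): fibrosis light blue, vessels near-white, background
#: lavender.  Pairwise (a*, b*) distances all exceed 25 Lab units.
FIBROSIS_LAB = (70.0, -10.0, -25.0)
VESSEL_LAB = (95.0, 0.0, 0.0)
BACKGROUND_LAB = (60.0, 25.0, -15.0)


@dataclass(frozen=True)
class TissueClass:
    name: str
    mean_lab: tuple[float, float, float]
    sigma: float  #: colour noise s.d. per Lab channel
    geometry: str  #: "ribbon" | "blob" | "background"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.geometry not in ("ribbon", "blob", "background"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass(frozen=True)
class TissueSpec:
    """Recipe for a synthetic stained-tissue image.

    ``fractions`` are target area fractions per class (must sum to 1); the
    achieved fractions are within ±20 % relative of the targets.  ``seed``
    fixes all randomness.
    """

    classes: tuple[TissueClass, ...]
    size: tuple[int, int] = (256, 256)
    fractions: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("at least one tissue class required")
        fr = self.fractions or tuple([1.0 / len(self.classes)] * len(self.classes))
        object.__setattr__(self, "fractions", fr)
        if len(self.fractions) != len(self.classes):
            raise ValueError("one area fraction per class required")
        if any(f < 0 for f in self.fractions) or abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("area fractions must be non-negative and sum to 1")
        n_bg = sum(c.geometry == "background" for c in self.classes)
        if len(self.classes) > 1 and n_bg != 1:
            raise ValueError("exactly one background class required")


@dataclass(frozen=True)
class MixtureSpec:
    """Isotropic 2-D Gaussian mixture: direct feature-space fixtures."""

    means: tuple[tuple[float, float], ...]
    sigmas: tuple[float, ...]
    weights: tuple[float, ...]
    n: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.means)
        if len(self.sigmas) != k or len(self.weights) != k:
            raise ValueError("means, sigmas, weights must have equal length")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def default_tissue_spec(size=(256, 256), sigma: float = 2.0, seed: int = 0,
                        fractions=(0.10, 0.15, 0.75)) -> TissueSpec:
    """Three-class trichrome-like spec: fibrosis ribbons, vessel blobs, background."""
    return TissueSpec(
        classes=(
            TissueClass("fibrosis", FIBROSIS_LAB, sigma, "ribbon"),
            TissueClass("vessels", VESSEL_LAB, sigma, "blob"),
            TissueClass("background", BACKGROUND_LAB, sigma, "background"),
        ),
        size=tuple(size),
        fractions=tuple(fractions),
        seed=seed,
    )


def _paint_blobs(lbl: np.ndarray, value: int, target: int, rng) -> None:
    """Stamp random ellipses until ~target pixels carry ``value``."""
    H, W = lbl.shape
    max_r = max(3.0, min(H, W) / 14.0)
    count = int((lbl == value).sum())
    for _ in range(10000):
        if count >= target:
            break
        remaining = target - count
        cap = max(2.0, min(max_r, 1.1 * np.sqrt(remaining / np.pi)))
        r0, c0 = rng.uniform(0, H), rng.uniform(0, W)
        ry = rng.uniform(2.0, cap)
        rx = rng.uniform(2.0, cap)
        rot = rng.uniform(0, np.pi)
        rr, cc = _draw_ellipse(r0, c0, ry, rx, shape=lbl.shape, rotation=rot)
        count += int((lbl[rr, cc] != value).sum())
        lbl[rr, cc] = value


def _paint_ribbons(lbl: np.ndarray, value: int, target: int, rng) -> None:
    """Draw smooth random-walk ribbons (width 2–6 px) until ~target pixels."""
    H, W = lbl.shape
    count = int((lbl == value).sum())
    for _ in range(10000):
        if count >= target:
            break
        width = rng.integers(2, 7)  # ribbon width 2..6 px
        radius = max(1.0, width / 2.0)
        r, c = rng.uniform(0, H), rng.uniform(0, W)
        heading = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(40, 4 * max(H, W)))
        for _step in range(n_steps):
            rr, cc = _draw_disk((r, c), radius, shape=lbl.shape)
            count += int((lbl[rr, cc] != value).sum())
            lbl[rr, cc] = value
            if count >= target:
                break
            heading += rng.normal(0.0, 0.25)
            r += np.sin(heading)
            c += np.cos(heading)
            if not (0 <= r < H and 0 <= c < W):
                break


def make_label_image(spec: TissueSpec) -> LabelMap:
    """Deterministic ground-truth label image for a tissue spec.

    Labels are class indices into ``spec.classes``.  Blobs are painted before
    ribbons (ribbons overlie vessels, as collagen sheathes vessel walls), with
    the blob target inflated to compensate for the expected overlap; achieved
    class areas are within ±20 % relative of the requested fractions.
    """
    H, W = spec.size
    rng = np.random.default_rng([int(spec.seed), 0])
    bg = next((i for i, c in enumerate(spec.classes) if c.geometry == "background"),
              0 if len(spec.classes) == 1 else None)
    lbl = np.full((H, W), bg, dtype=np.int64)

    total = H * W
    ribbon_frac = sum(f for c, f in zip(spec.classes, spec.fractions)
                      if c.geometry == "ribbon")
    for i, (cls, frac) in enumerate(zip(spec.classes, spec.fractions)):
        if cls.geometry == "blob" and frac > 0:
            # inflate: ribbons drawn later overwrite ~ribbon_frac of the blobs
            _paint_blobs(lbl, i, int(round(frac * total / max(1e-9, 1.0 - ribbon_frac))), rng)
    for i, (cls, frac) in enumerate(zip(spec.classes, spec.fractions)):
        if cls.geometry == "ribbon" and frac > 0:
            _paint_ribbons(lbl, i, int(round(frac * total)), rng)

    return LabelMap(labels=lbl, k=len(spec.classes),
                    provenance={"source": "synthetic", "seed": spec.seed,
                                "fractions": tuple(spec.fractions)})


def render_histology(gt: LabelMap, spec: TissueSpec) -> np.ndarray:
    """Render a ground-truth label image as an 8-bit sRGB stained image.

    Per pixel: class mean Lab + N(0, sigma^2) per channel, converted to sRGB
    and clipped to gamut.  With sigma = 0 the image is piecewise constant
    with exactly one colour per class.
    """
    lbl = gt.labels
    if lbl.max() >= len(spec.classes) or lbl.min() < 0:
        raise ValueError("label image contains labels not covered by the spec")
    rng = np.random.default_rng([int(spec.seed), 1])
    means = np.asarray([c.mean_lab for c in spec.classes], dtype=np.float64)
    sigmas = np.asarray([c.sigma for c in spec.classes], dtype=np.float64)
    lab = means[lbl]
    noise = rng.normal(0.0, 1.0, size=lab.shape) * sigmas[lbl][..., None]
    rgb = _skcolor.lab2rgb(lab + noise)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def make_histology_image(spec: TissueSpec) -> tuple[np.ndarray, LabelMap]:
    """Convenience: (rendered RGB image, ground-truth LabelMap)."""
    gt = make_label_image(spec)
    return render_histology(gt, spec), gt


def make_point_cloud(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded Gaussian-mixture sample: (points (n, 2), component labels (n,))."""
    rng = np.random.default_rng([int(spec.seed), 2])
    counts = rng.multinomial(spec.n, spec.weights)
    pts, lbls = [], []
    for k, (mu, s, m) in enumerate(zip(spec.means, spec.sigmas, counts)):
        pts.append(rng.normal(0.0, 1.0, size=(m, 2)) * s + np.asarray(mu))
        lbls.append(np.full(m, k, dtype=np.int64))
    return np.concatenate(pts, axis=0), np.concatenate(lbls)
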