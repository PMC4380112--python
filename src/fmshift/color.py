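"""Colour feature extraction in CIE L*a*b* space.

Stained tissue classes differ chiefly in chromaticity, while illumination and
section thickness modulate brightness.  Working in CIE L*a*b* and keeping only
the chromatic (a*, b*) channels therefore turns colour segmentation into a 2-D
clustering problem that is insensitive to lightness variation.

The sRGB working space with the D65 white point (2 degree observer) is assumed
throughout; the white point can be overridden where a scanner is calibrated
differently.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

__all__ = [
    "ABFeatures",
    "rgb_to_lab",
    "lab_to_rgb",
    "extract_ab",
    "load_image",
]

#: Default reference white for the sRGB -> XYZ -> L*a*b* transform.
DEFAULT_ILLUMINANT = "D65"
DEFAULT_OBSERVER = "2"


@dataclass(frozen=True)
class ABFeatures:
    """The 2-D chromatic feature space: per-pixel (a*, b*) values.

    Flattening the two planes row-major yields the point set
    ``{x_1, ..., x_n}`` (n = H*W) that the clustering operates on.
    """

    a: np.ndarray  #: H x W a* channel (green-red axis)
    b: np.ndarray  #: H x W b* channel (blue-yellow axis)

    def __post_init__(self) -> None:
        if self.a.shape != self.b.shape or self.a.ndim != 2:
            raise ValueError("a* and b* must be 2-D arrays of the same shape")
        if not (np.isfinite(self.a).all() and np.isfinite(self.b).all()):
            raise ValueError("feature values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.a.shape

    @property
    def n(self) -> int:
        return self.a.size

    def points(self) -> np.ndarray:
        """Row-major (n, 2) array of (a*, b*) feature points."""
        return np.column_stack([self.a.ravel(), self.b.ravel()]).astype(float)


def _validate_rgb(img: np.ndarray, drop_alpha: bool) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3:
        raise ValueError(f"expected an H x W x 3 colour image, got shape {img.shape}")
    if img.shape[2] == 4:
        if not drop_alpha:
            raise ValueError("image has an alpha channel; pass drop_alpha=True to discard it")
        img = img[..., :3]
    if img.shape[2] != 3:
        raise ValueError(f"expected 3 colour channels, got {img.shape[2]}")
    if np.issubdtype(img.dtype, np.integer):
        if img.min() < 0 or img.max() > 255:
            raise ValueError("integer RGB values must lie in [0, 255]")
    return img


def rgb_to_lab(
    img: np.ndarray,
    *,
    illuminant: str = DEFAULT_ILLUMINANT,
    observer: str = DEFAULT_OBSERVER,
    drop_alpha: bool = False,
) -> np.ndarray:
    """Convert an 8-bit sRGB image to CIE L*a*b*.

    Parameters
    ----------
    img
        H x W x 3 (or x4 with ``drop_alpha``) array; integer arrays are
        interpreted as 8-bit intensities in [0, 255].
    illuminant, observer
        Reference white of the Lab transform.  Defaults: D65, 2 degrees.

    Returns
    -------
    H x W x 3 float array with channels (L*, a*, b*); L* in [0, 100].
    """
    img = _validate_rgb(img, drop_alpha=drop_alpha)
    if np.issubdtype(img.dtype, np.integer):
        rgb = img.astype(np.float64) / 255.0
    else:
        rgb = np.clip(img.astype(np.float64), 0.0, 1.0)
    return _skcolor.rgb2lab(rgb, illuminant=illuminant, observer=observer)


def lab_to_rgb(
    lab: np.ndarray,
    *,
    illuminant: str = DEFAULT_ILLUMINANT,
    observer: str = DEFAULT_OBSERVER,
) -> np.ndarray:
    """Inverse transform back to 8-bit sRGB (out-of-gamut values clipped)."""
    rgb = _skcolor.lab2rgb(np.asarray(lab, dtype=np.float64), illuminant=illuminant, observer=observer)
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def extract_ab(lab: np.ndarray) -> ABFeatures:
    """Keep the chromatic a*, b* channels and discard lightness L*."""
    lab = np.asarray(lab)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 Lab image, got shape {lab.shape}")
    return ABFeatures(a=lab[..., 1].astype(np.float64), b=lab[..., 2].astype(np.float64))


def load_image(path, *, drop_alpha: bool = True) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an H x W x 3 uint8 array."""
    img = iio.imread(path)
    if img.ndim == 2:  # greyscale: replicate to three channels
        img = np.stack([img] * 3, axis=-1)
    return _validate_rgb(img, drop_alpha=drop_alpha)
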