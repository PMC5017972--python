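"""Intensity normalization and plane extraction.

Contrast stretching maps an input intensity range [x_low, x_hi] linearly onto
[y_low, y_hi] (gamma fixed at 1), clipping outside the input range:

    y = (x - x_low) * (y_hi - y_low) / (x_hi - x_low) + y_low

The negative transform of an L-bit plane is y = (2**L - 1) - x.  Both
segmentation branches consume single planes: the green channel for the cup,
the HSV value channel for the disc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .image import FundusImage


class DegenerateRangeError(ValueError):
    """Constant plane: stretch bounds cannot be auto-estimated."""


@dataclass
class ContrastStretchParams:
    x_low: float
    x_hi: float
    y_low: float = 0.0
    y_hi: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not self.x_hi > self.x_low:
            raise ValueError("x_hi must exceed x_low")
        if self.y_hi < self.y_low:
            raise ValueError("y_hi must be >= y_low")


def auto_stretch_params(plane: np.ndarray, lo_pct: float = 1.0,
                        hi_pct: float = 99.0, y_low: float = 0.0,
                        y_hi: float = 1.0) -> ContrastStretchParams:
    """Robust bounds: input range from intensity percentiles (default 1/99)."""
    x_low = float(np.percentile(plane, lo_pct))
    x_hi = float(np.percentile(plane, hi_pct))
    if x_hi <= x_low:
        raise DegenerateRangeError("plane has no intensity spread")
    return ContrastStretchParams(x_low, x_hi, y_low, y_hi)


def contrast_stretch(plane: np.ndarray, p: ContrastStretchParams) -> np.ndarray:
    """Piecewise-linear stretch of a single plane; clips outside [x_low, x_hi]."""
    x = np.asarray(plane, dtype=np.float64)
    y = (x - p.x_low) * (p.y_hi - p.y_low) / (p.x_hi - p.x_low) + p.y_low
    return np.clip(y, p.y_low, p.y_hi)


def negative_transform(plane: np.ndarray, L: int = 8) -> np.ndarray:
    """y = (2**L - 1) - x; an involution on the L-bit grid."""
    hi = 2 ** L - 1
    x = np.asarray(plane)
    if x.dtype.kind in "ui" and (x.min() < 0 or x.max() > hi):
        raise ValueError(f"intensities outside [0, {hi}]")
    return hi - x


def negative_unit(plane: np.ndarray) -> np.ndarray:
    """Unit-scale negative, y = 1 - x, for planes already on [0, 1]."""
    return 1.0 - np.asarray(plane, dtype=np.float64)


def _stretch_planes(arr: np.ndarray, lo_pct: float, hi_pct: float,
                    skip: tuple[int, ...] = ()) -> np.ndarray:
    out = np.empty_like(arr, dtype=np.float64)
    for c in range(arr.shape[2]):
        if c in skip:
            out[:, :, c] = arr[:, :, c]
        else:
            p = auto_stretch_params(arr[:, :, c], lo_pct, hi_pct)
            out[:, :, c] = contrast_stretch(arr[:, :, c], p)
    return out


def stretch_rgb(img: FundusImage, lo_pct: float = 1.0,
                hi_pct: float = 99.0) -> np.ndarray:
    """Stretch each RGB channel independently; returns a unit-scale H×W×3 array."""
    if img.colorspace != "RGB":
        raise ValueError("stretch_rgb expects an RGB image")
    return _stretch_planes(img.as_float(), lo_pct, hi_pct)


def stretch_hsv(img: FundusImage, lo_pct: float = 1.0, hi_pct: float = 99.0,
                stretch_hue: bool = True) -> np.ndarray:
    """Convert RGB→HSV and stretch each plane; returns unit-scale H×W×3 (HSV).

    Hue is circular, so stretching it is geometrically dubious; the default
    follows the per-plane prescription literally, ``stretch_hue=False`` exempts
    the hue plane.
    """
    if img.colorspace != "RGB":
        raise ValueError("stretch_hsv expects an RGB image")
    hsv = skcolor.rgb2hsv(img.as_float())
    skip = () if stretch_hue else (0,)
    return _stretch_planes(hsv, lo_pct, hi_pct, skip=skip)


_PLANES = {"R": 0, "G": 1, "B": 2, "H": 0, "S": 1, "V": 2}


def extract_plane(arr: np.ndarray | FundusImage, which: str) -> np.ndarray:
    """Return one channel of an RGB or HSV array unmodified.

    ``which`` ∈ {R,G,B} for RGB data, {H,S,V} for HSV data.  When given a
    :class:`FundusImage` the colorspace tag is checked against the request.
    """
    which = which.upper()
    if which not in _PLANES:
        raise ValueError(f"unknown plane {which!r}")
    family = "RGB" if which in "RGB" else "HSV"
    if isinstance(arr, FundusImage):
        if arr.colorspace != family:
            raise ValueError(f"plane {which} requires {family}, "
                             f"image is {arr.colorspace}")
        data = arr.as_float()
    else:
        data = np.asarray(arr)
    if data.ndim != 3 or data.shape[2] != 3:
        raise ValueError("expected an H×W×3 array")
    return data[:, :, _PLANES[which]]
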