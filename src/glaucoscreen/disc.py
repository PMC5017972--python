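"""Optic-disc segmentation inside the ROI.

Branch pipeline: HSV contrast stretch -> value plane -> mean-of-image
threshold (pixels strictly above the arithmetic mean; ties go to background)
-> morphological cleaning (three passes of small-object removal + binary
opening with a flat disk, radius 15 at the large profile) -> convex-hull
fill -> boundary trace -> direct least-squares ellipse fit.

Mean thresholding is invariant under any strictly increasing affine
rescaling of the plane, so the preceding stretch only matters through its
clipping tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

from .config import RunConfig
from .cup import (SegmentationError, SegmentationResult, StructuringElement,
                  boundary_points, convex_hull_mask)
from .geometry import fit_ellipse_lsq
from .localize import RoiPatch
from .preprocess import extract_plane, stretch_hsv


@dataclass
class MorphCleanConfig:
    se: StructuringElement = field(
        default_factory=lambda: StructuringElement("disk_flat", 15, 0.0))
    repetitions: int = 3
    min_object_area: int = 50      # px^2

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def mean_threshold(plane: np.ndarray) -> np.ndarray:
    """Binary mask of pixels strictly above the plane's arithmetic mean.

    Pixels exactly equal to the mean map to background (the defining
    inequalities are strict; the gap is closed downward).
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError("mean_threshold expects a single-channel plane")
    return plane > plane.mean()


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop connected components with area < min_area px^2."""
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def clean_binary(mask: np.ndarray, cfg: MorphCleanConfig | None = None
                 ) -> np.ndarray:
    """Three passes of [small-object removal, binary opening], then hull.

    Vessels crossing the disc cut the above-mean mask into fragments; the
    small-object removal drops speckle while the final convex-hull fill
    welds the surviving disc fragments back into a single convex region
    (holes and unconnected parts included).  Raises if cleaning erases the
    mask entirely.
    """
    cfg = cfg or MorphCleanConfig()
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    footprint = skmorph.disk(cfg.se.radius)
    for _ in range(cfg.repetitions):
        m = _remove_small(m, cfg.min_object_area)
        m = ndimage.binary_opening(m, structure=footprint)
        if not m.any():
            raise SegmentationError("clean_binary",
                                    "mask vanished during cleaning")
    # The ROI is centred on the localized disc, so genuine disc fragments
    # cluster around the frame centre; bright background blobs near the ROI
    # rim are unwanted objects and must not be welded in by the hull.
    labels, n = ndimage.label(m)
    if n > 1:
        H, W = m.shape
        keep = []
        for idx in range(1, n + 1):
            r, c = ndimage.center_of_mass(labels == idx)
            if abs(r - H / 2) <= H / 4 and abs(c - W / 2) <= W / 4:
                keep.append(idx)
        if keep:
            m = np.isin(labels, keep)
        else:   # nothing central: fall back to the largest fragment
            sizes = ndimage.sum_labels(m, labels, index=range(1, n + 1))
            m = labels == (1 + int(np.argmax(sizes)))
    # iterate hull/opening till no change: raster hulls of an opened disk
    # can gain a few boundary pixels on a second pass, and the fixed point
    # makes the cleaning idempotent
    h = convex_hull_mask(m)
    for _ in range(5):
        h2 = convex_hull_mask(ndimage.binary_opening(h, structure=footprint))
        if np.array_equal(h2, h):
            break
        h = h2
    return h


def segment_disc(roi: RoiPatch, cfg: RunConfig | None = None
                 ) -> SegmentationResult:
    """Run the full disc branch on a disc ROI."""
    cfg = cfg or RunConfig()
    stage = "stretch_hsv"
    try:
        hsv = stretch_hsv(roi.image, cfg.stretch_lo_percentile,
                          cfg.stretch_hi_percentile,
                          stretch_hue=cfg.stretch_hue)
        value = extract_plane(hsv, "V")
        stage = "mean_threshold"
        binary = mean_threshold(value)
        if not binary.any():
            raise ValueError("no pixel above the image mean")
        stage = "clean_binary"
        clean = clean_binary(binary, MorphCleanConfig(
            StructuringElement("disk_flat", cfg.disc_open_radius, 0.0),
            cfg.disc_open_repetitions, cfg.min_object_area))
        stage = "boundary"
        pts = boundary_points(clean)
        stage = "ellipse_fit"
        ellipse = fit_ellipse_lsq(pts)
    except SegmentationError:
        raise
    except Exception as e:
        raise SegmentationError(stage, str(e)) from e
    return SegmentationResult(clean, pts, ellipse, structure="disc")
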