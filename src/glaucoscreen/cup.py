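"""Optic-cup segmentation inside the disc ROI.

Branch pipeline: per-channel contrast stretch -> green plane -> negative ->
gray-level opening with a non-flat ball (radius/height 40 at the large
profile; vessels are bright in the negative, so erosion-first opening erases
them) -> negative back -> seeded region growing from the brightest pixel
(homogeneity threshold 0.025 on the unit scale) -> morphological convex-hull
fill -> boundary trace -> direct least-squares ellipse fit.

Everything here is deterministic: ties in the seed choice break to the
smallest (row, col), the region-growing frontier is scanned in row-major
order, and the boundary comes from contour tracing rather than Canny by
default (Canny on a binary mask gives the same curve up to a pixel; it is
kept as an option).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .config import RunConfig
from .geometry import EllipseParams, fit_ellipse_lsq
from .localize import RoiPatch
from .preprocess import extract_plane, negative_unit, stretch_rgb

log = logging.getLogger("glaucoscreen")

_CROSS = ndimage.generate_binary_structure(2, 1)   # 4-connectivity


class SegmentationError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class StructuringElement:
    """Flat disk or non-flat ball; the ball's height profile is spherical."""

    shape: str = "ball_nonflat"          # or "disk_flat"
    radius: int = 40
    height: float = 40.0 / 255.0         # unit-scale intensity units

    def __post_init__(self) -> None:
        if self.radius < 1 or self.height < 0:
            raise ValueError("radius >= 1 and height >= 0 required")
        if self.shape not in ("ball_nonflat", "disk_flat"):
            raise ValueError(f"unknown SE shape {self.shape!r}")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(footprint bool, height structure float) on a (2r+1)^2 grid."""
        r = self.radius
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        d2 = (xx ** 2 + yy ** 2) / float(r * r)
        footprint = d2 <= 1.0
        if self.shape == "disk_flat":
            struct = np.zeros_like(d2)
        else:
            struct = self.height * np.sqrt(np.clip(1.0 - d2, 0.0, None))
        struct = np.where(footprint, struct, 0.0)
        return footprint, struct


@dataclass
class RegionGrowConfig:
    intensity_threshold: float = 0.025   # unit scale
    connectivity: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity_threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.connectivity != 4:
            raise ValueError("only 4-connectivity is supported")


@dataclass
class SegmentationResult:
    mask: np.ndarray                     # bool, ROI shape
    boundary: np.ndarray                 # N×2 (x, y) points, ROI frame
    ellipse: EllipseParams
    structure: str = "cup"


# ----------------------------------------------------------------------


def gray_open(plane: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Gray-level opening (erosion then dilation) with a possibly non-flat SE."""
    plane = np.asarray(plane, dtype=np.float64)
    if min(plane.shape) < 2 * se.radius + 1:
        raise ValueError(f"SE radius {se.radius} too large for plane "
                         f"{plane.shape}")
    footprint, struct = se.arrays()
    eroded = ndimage.grey_erosion(plane, footprint=footprint,
                                  structure=struct)
    return ndimage.grey_dilation(eroded, footprint=footprint,
                                 structure=struct)


def region_grow(plane: np.ndarray, cfg: RegionGrowConfig | None = None,
                seed: tuple[int, int] | None = None) -> np.ndarray:
    """Seeded region growing on a unit-scale plane.

    The seed is the global maximum (first in row-major order on ties).  Each
    iteration scans the current 4-connected frontier in row-major order; a
    pixel joins iff its intensity is within the threshold of (a) the region's
    running mean and (b) at least one 4-neighbour already in the region.  The
    mean is updated after every admission.  Worst case the region is the seed
    alone.
    """
    cfg = cfg or RegionGrowConfig()
    plane = np.asarray(plane, dtype=np.float64)
    H, W = plane.shape
    if seed is None:
        flat = int(np.argmax(plane))
        seed = (flat // W, flat % W)
    thr = cfg.intensity_threshold
    region = np.zeros((H, W), dtype=bool)
    region[seed] = True
    mean = float(plane[seed])
    count = 1
    while True:
        frontier = ndimage.binary_dilation(region, structure=_CROSS) & ~region
        admitted = 0
        for r, c in np.argwhere(frontier):
            p = plane[r, c]
            if abs(p - mean) > thr:
                continue
            for dr, dc in ((-1, 0), (0, -1), (0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if (0 <= rr < H and 0 <= cc < W and region[rr, cc]
                        and abs(p - plane[rr, cc]) <= thr):
                    break
            else:
                continue
            region[r, c] = True
            count += 1
            mean += (p - mean) / count
            admitted += 1
        if admitted == 0:
            return region


def convex_hull_mask(mask: np.ndarray) -> np.ndarray:
    """Smallest discrete convex region containing the mask.

    The classical formulation iterates four hit-or-miss thickenings to a
    fixed point; here the geometric hull fill is itself iterated to a fixed
    point, because the discrete rasterisation of the hull boundary can add
    a stray pixel on a second pass — the fixed point makes the operation
    idempotent by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no hull")
    for _ in range(8):
        hull = skmorph.convex_hull_image(mask)
        if np.array_equal(hull, mask):
            return hull
        mask = hull
    return mask


def boundary_points(mask: np.ndarray, use_canny: bool = False) -> np.ndarray:
    """Ordered closed boundary of a mask as N×2 (x, y) points.

    Multiple components: the largest is used (with a log warning).  Fewer
    than 5 boundary points cannot support an ellipse fit and raise.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    labels, n = ndimage.label(mask)
    if n > 1:
        log.warning("mask has %d components; using the largest", n)
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if use_canny:
        from skimage import feature as skfeature
        edges = skfeature.canny(mask.astype(float), sigma=1.0)
        pts = np.argwhere(edges)[:, ::-1].astype(np.float64)   # (x, y)
    else:
        contours = skmeasure.find_contours(mask.astype(float), 0.5)
        if not contours:
            raise ValueError("no contour found")
        contour = max(contours, key=len)
        if len(contour) > 1 and np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]                 # drop the closing point
        pts = contour[:, ::-1]                                 # (row,col)->(x,y)
    if len(pts) < 5:
        raise ValueError(f"degenerate boundary: only {len(pts)} points")
    return pts


# ----------------------------------------------------------------------


def segment_cup(roi: RoiPatch, cfg: RunConfig | None = None
                ) -> SegmentationResult:
    """Run the full cup branch on a disc ROI."""
    cfg = cfg or RunConfig()
    stage = "stretch"
    try:
        rgb = stretch_rgb(roi.image, cfg.stretch_lo_percentile,
                          cfg.stretch_hi_percentile)
        green = extract_plane(rgb, "G")
        stage = "vessel_removal"
        se = StructuringElement("ball_nonflat", cfg.ball_radius,
                                cfg.ball_height)
        opened = negative_unit(gray_open(negative_unit(green), se))
        stage = "region_grow"
        mask = region_grow(opened,
                           RegionGrowConfig(cfg.region_grow_threshold))
        stage = "convex_hull"
        hull = convex_hull_mask(mask)
        stage = "boundary"
        pts = boundary_points(hull, use_canny=cfg.cup_use_canny)
        stage = "ellipse_fit"
        ellipse = fit_ellipse_lsq(pts)
    except Exception as e:
        raise SegmentationError(stage, str(e)) from e
    return SegmentationResult(hull, pts, ellipse, structure="cup")
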