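"""Ground-truthed synthetic fundus images.

Real fundus photographs show a bright yellowish elliptical optic disc with a
still brighter central cup, dark vessels converging on the disc, a textured
reddish background, a smooth illumination gradient and sensor noise.  The
generator reproduces exactly those cues — nothing else — so every pipeline
stage can be tested against known geometry.

Brightness ordering on the structure (green) plane: background ~0.35 of full
scale, disc ~0.75, cup ~0.9, vessels dark.  The true CDR is *defined* as the
cup/disc ellipse area ratio of the stored ground truth; the class label is
glaucoma iff that ratio exceeds 0.5.

Two frame profiles mirror the published datasets: ``large`` 1000x1504 and
``small`` 452x415 (rows x cols).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import EllipseParams
from .image import FundusImage

PROFILE_SIZES = {"large": (1000, 1504), "small": (452, 415)}

#: structure-plane mean levels (unit scale)
BACKGROUND_LEVEL = 0.35
DISC_LEVEL = 0.75
CUP_LEVEL = 0.90

#: structure value -> RGB; keeps green == structure plane and R = max channel
_RGB_MIX = (0.25, 0.75)   # R = 0.25 + 0.75*v


@dataclass
class VesselSpec:
    count: int = 8
    width: int = 5          # stroke width in px (large profile scale)
    contrast: float = 0.6   # vessel value = (1 - contrast) * underlying


@dataclass
class SyntheticGroundTruth:
    disc_ellipse: EllipseParams
    cup_ellipse: EllipseParams
    true_cdr: float
    vessel_spec: VesselSpec
    illumination_gradient: float
    noise_sd: float
    label: str
    seed: int
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        ratio = self.cup_ellipse.area / self.disc_ellipse.area
        if not math.isclose(ratio, self.true_cdr, rel_tol=1e-6):
            raise ValueError("true_cdr must equal cup area / disc area")
        if not _ellipse_inside(self.cup_ellipse, self.disc_ellipse):
            raise ValueError("cup ellipse must lie strictly inside the disc")
        expect = "glaucoma" if self.true_cdr > 0.5 else "healthy"
        if self.label != expect:
            raise ValueError(f"label {self.label!r} inconsistent with "
                             f"true_cdr {self.true_cdr}")


def _ellipse_inside(inner: EllipseParams, outer: EllipseParams) -> bool:
    pts = inner.sample(72)
    B, C, D, E, F = outer.conic
    x, y = pts[:, 0], pts[:, 1]
    val = x * x + B * x * y + C * y * y + D * x + E * y + F
    return bool(np.all(val < 0))


def _ellipse_mask(e: EllipseParams, shape) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    B, C, D, E, F = e.conic
    return (xx * xx + B * xx * yy + C * yy * yy + D * xx + E * yy + F) <= 0


class GeometryError(ValueError):
    """Ground-truth ellipse does not fit in the requested frame."""


def make_ground_truth(seed: int, size: tuple[int, int] = PROFILE_SIZES["small"],
                      cdr: float | None = None,
                      cdr_range: tuple[float, float] = (0.2, 0.45),
                      vessel_spec: VesselSpec | None = None,
                      illumination_gradient: float = 0.10,
                      noise_sd: float = 0.005,
                      blur_sigma: float = 0.0) -> SyntheticGroundTruth:
    """Draw one random ground truth: disc near the frame centre, cup inside.

    Disc semi-axes are ~17% of the frame's short side (clinically plausible);
    cup axes are scaled so the area ratio equals the requested CDR exactly.
    """
    rng = np.random.default_rng(seed)
    H, W = size
    if cdr is None:
        cdr = float(rng.uniform(*cdr_range))
    if not 0.0 < cdr < 1.0:
        raise ValueError("cdr must be in (0, 1)")
    short = min(H, W)
    a_d = float(rng.uniform(0.155, 0.19) * short) / 2.0  # semi-major axis
    ecc = float(rng.uniform(0.88, 1.0))
    b_d = a_d * ecc
    cx = W / 2.0 + float(rng.uniform(-0.10, 0.10) * W)
    cy = H / 2.0 + float(rng.uniform(-0.10, 0.10) * H)
    th_d = float(rng.uniform(0.0, np.pi))
    disc = EllipseParams.from_geometric((cx, cy), (a_d, b_d), th_d)

    # cup: same centre (small jitter), axes scaled to hit the area ratio
    s = math.sqrt(cdr)
    ecc_c = float(rng.uniform(0.9, 1.0))
    a_c = a_d * s / math.sqrt(ecc_c)
    b_c = b_d * s * math.sqrt(ecc_c)
    jit = (1.0 - s) * 0.15 * b_d
    ccx = cx + float(rng.uniform(-jit, jit))
    ccy = cy + float(rng.uniform(-jit, jit))
    cup = EllipseParams.from_geometric((ccx, ccy), (a_c, b_c), th_d)
    true_cdr = cup.area / disc.area

    vs = vessel_spec or VesselSpec(width=max(2, round(5 * short / 1000)))
    return SyntheticGroundTruth(
        disc_ellipse=disc, cup_ellipse=cup, true_cdr=true_cdr,
        vessel_spec=vs, illumination_gradient=illumination_gradient,
        noise_sd=noise_sd, label="glaucoma" if true_cdr > 0.5 else "healthy",
        seed=int(seed), blur_sigma=blur_sigma)


def _draw_vessels(value: np.ndarray, truth: SyntheticGroundTruth,
                  rng: np.random.Generator) -> None:
    """Quadratic Bezier strokes from the border towards the disc centre."""
    H, W = value.shape
    cx, cy = truth.disc_ellipse.center
    vs = truth.vessel_spec
    r = max(1, vs.width // 2)
    for _ in range(vs.count):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        # start on the frame border along direction ang from the disc centre
        tmax = min(
            (W - 1 - cx) / math.cos(ang) if math.cos(ang) > 0 else (-cx) / math.cos(ang) if math.cos(ang) < 0 else np.inf,
            (H - 1 - cy) / math.sin(ang) if math.sin(ang) > 0 else (-cy) / math.sin(ang) if math.sin(ang) < 0 else np.inf,
        )
        x0 = cx + tmax * math.cos(ang)
        y0 = cy + tmax * math.sin(ang)
        # control point: midpoint pushed sideways for curvature
        mx, my = (x0 + cx) / 2.0, (y0 + cy) / 2.0
        nx, ny = -(y0 - cy), (x0 - cx)
        nn = math.hypot(nx, ny) or 1.0
        bend = rng.uniform(-0.18, 0.18) * nn
        px, py = mx + bend * nx / nn, my + bend * ny / nn
        t = np.linspace(0.0, 1.0, 400)
        bx = (1 - t) ** 2 * x0 + 2 * (1 - t) * t * px + t ** 2 * cx
        by = (1 - t) ** 2 * y0 + 2 * (1 - t) * t * py + t ** 2 * cy
        cols = np.clip(np.round(bx).astype(int), 0, W - 1)
        rows = np.clip(np.round(by).astype(int), 0, H - 1)
        # vessel caliber tapers away from the disc: thickest at the disc end
        # (t=1), thinnest at the periphery — the density cue the disc
        # localizer depends on
        stroke = np.zeros_like(value, dtype=bool)
        for t_lo, t_hi, rad in ((0.0, 0.55, max(1, r - 1)),
                                (0.55, 0.85, r),
                                (0.85, 1.01, r + 1)):
            seg = (t >= t_lo) & (t < t_hi)
            part = np.zeros_like(value, dtype=bool)
            part[rows[seg], cols[seg]] = True
            stroke |= ndimage.binary_dilation(part, iterations=rad)
        value[stroke] *= (1.0 - vs.contrast)


def render_vessel_mask(truth: SyntheticGroundTruth,
                       size: tuple[int, int]) -> np.ndarray:
    """The exact vessel-pixel mask a render with this truth produces."""
    base = np.full(size, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 7]))
    _draw_vessels(base, truth, rng)
    return base < 1.0


def generate_fundus(truth: SyntheticGroundTruth,
                    size: tuple[int, int] = PROFILE_SIZES["small"],
                    ) -> FundusImage:
    """Render one synthetic fundus frame; deterministic for a fixed truth."""
    H, W = size
    for e in (truth.disc_ellipse, truth.cup_ellipse):
        pts = e.sample(72)
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > W - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > H - 1):
            raise GeometryError("ground-truth ellipse outside the frame")

    ss = np.random.SeedSequence([truth.seed, 7])
    rng = np.random.default_rng(ss)          # vessels drawn first (shared
    noise_rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 11]))

    # background: low-frequency smoothed noise around the background level
    tex = noise_rng.standard_normal((H, W))
    tex = ndimage.gaussian_filter(tex, sigma=0.06 * min(H, W))
    tex_sd = tex.std() or 1.0
    v = BACKGROUND_LEVEL + 0.015 * tex / tex_sd

    v[_ellipse_mask(truth.disc_ellipse, size)] = DISC_LEVEL
    v[_ellipse_mask(truth.cup_ellipse, size)] = CUP_LEVEL
    if truth.vessel_spec.count > 0:
        _draw_vessels(v, truth, rng)
    if truth.blur_sigma > 0:
        v = ndimage.gaussian_filter(v, sigma=truth.blur_sigma)
    # smooth multiplicative illumination gradient (corner-to-corner)
    if truth.illumination_gradient:
        gx = np.linspace(-0.5, 0.5, W)[None, :]
        gy = np.linspace(-0.5, 0.5, H)[:, None]
        v = v * (1.0 + truth.illumination_gradient * (0.7 * gx + 0.3 * gy))
    if truth.noise_sd > 0:
        v = v + noise_rng.normal(0.0, truth.noise_sd, size=(H, W))
    v = np.clip(v, 0.0, 1.0)

    rgb = np.empty((H, W, 3))
    rgb[:, :, 0] = np.clip(_RGB_MIX[0] + _RGB_MIX[1] * v, 0, 1)  # reddish cast
    rgb[:, :, 1] = v                                             # structure
    rgb[:, :, 2] = 0.30 * v
    return FundusImage.from_float(rgb, colorspace="RGB")


DEFAULT_CDR_RANGES = {"healthy": (0.2, 0.45), "glaucoma": (0.55, 0.85)}


def generate_cohort(n: int, glaucoma_fraction: float = 0.26,
                    cdr_ranges: dict | None = None,
                    seed: int = 0,
                    size: tuple[int, int] = PROFILE_SIZES["small"],
                    noise_sd: float = 0.005,
                    illumination_gradient: float = 0.10,
                    vessel_spec: VesselSpec | None = None,
                    ) -> list[tuple[FundusImage, SyntheticGroundTruth]]:
    """Labelled cohort: exactly round(n * glaucoma_fraction) glaucoma cases.

    True CDRs are uniform on the class interval; default intervals span the
    clinically reported ranges on either side of the 0.5 decision boundary
    (healthy 0.20-0.45, glaucomatous 0.55-0.85).
    """
    if not 0.0 <= glaucoma_fraction <= 1.0:
        raise ValueError("glaucoma_fraction must be in [0, 1]")
    ranges = dict(DEFAULT_CDR_RANGES)
    if cdr_ranges:
        ranges.update(cdr_ranges)
    lo_h, hi_h = ranges["healthy"]
    lo_g, hi_g = ranges["glaucoma"]
    if hi_h > 0.5 or lo_g <= 0.5:
        raise ValueError("CDR intervals must sit on the correct sides of 0.5")

    n_g = round(n * glaucoma_fraction)
    labels = ["glaucoma"] * n_g + ["healthy"] * (n - n_g)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
    out = []
    for lab, cseed in zip(labels, child_seeds):
        rng = np.random.default_rng(cseed)
        interval = ranges[lab]
        cdr = float(rng.uniform(*interval))
        truth = make_ground_truth(
            seed=cseed, size=size, cdr=cdr, vessel_spec=vessel_spec,
            illumination_gradient=illumination_gradient, noise_sd=noise_sd)
        out.append((generate_fundus(truth, size), truth))
    return out


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write images, disc/cup masks and a ground-truth CSV for a cohort."""
    from .image import write_image
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth) in enumerate(cohort):
        iid = f"syn{i + 1:03d}"
        write_image(img, out_dir / f"{iid}.png")
        size = img.shape
        write_image(_ellipse_mask(truth.disc_ellipse, size),
                    out_dir / f"{iid}_disc_mask.png")
        write_image(_ellipse_mask(truth.cup_ellipse, size),
                    out_dir / f"{iid}_cup_mask.png")
        rows.append(f"{iid},{truth.true_cdr:.4f},{truth.label}")
    csv = out_dir / "ground_truth.csv"
    csv.write_text("image_id,clinical_cdr,label\n" + "\n".join(rows) + "\n")
    return csv
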