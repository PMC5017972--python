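"""Texture and intensity feature bank.

Glaucoma enlarges the bright cup, which shifts the image's brightness
statistics and spatial texture; the non-structural branch quantifies this
with five descriptor families computed on the disc ROI:

* Gabor wavelet energies (mean and sd of the response magnitude per
  scale x orientation),
* rotation-invariant uniform local binary patterns (LBP riu2, P=8
  neighbours sampled at radius 12, histogram over the P+2 codes),
* Haralick statistics of a direction-fused gray-level co-occurrence matrix
  (four displacement vectors [0,d], [-d,d], [-d,0], [-d,-d], summed,
  averaged and normalised),
* per-channel colour moments (mean, sd, signed cube-root skewness),
* intensity auto-correlograms (probability that a pixel at Chebyshev
  distance exactly d of a colour-c pixel is also colour c).

"Multi-wavelets" are a second Gabor bank at half the base frequencies; the
term appears in the source feature list without a definition, so this is an
explicit interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .config import RunConfig
from .image import FundusImage
from .localize import RoiPatch

_EPS = 1e-12

BLOCK_ORDER = ("wavelets", "multiwavelets", "lbp", "haralick",
               "color_moments", "correlogram")


@dataclass
class FeatureVector:
    blocks: dict[str, np.ndarray]

    @property
    def values(self) -> np.ndarray:
        return np.concatenate([self.blocks[b] for b in BLOCK_ORDER
                               if b in self.blocks])

    def __len__(self) -> int:
        return int(sum(len(v) for v in self.blocks.values()))


# ----------------------------------------------------------------------
# Gabor wavelets


def gabor_kernel(f: float, theta: float, gamma: float, eta: float,
                 half_size: int | None = None) -> np.ndarray:
    """Complex 2-D Gabor kernel.

    phi(x, y) = f^2/(pi*gamma*eta) * exp(-(f^2/gamma^2 x_r^2
                + f^2/eta^2 y_r^2)) * exp(i 2 pi f x_r)
    with (x_r, y_r) the coordinates rotated by theta.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    if half_size is None:
        sd = max(gamma, eta) / (f * np.sqrt(2.0))
        half_size = max(3, int(np.ceil(3.0 * sd)))
    y, x = np.mgrid[-half_size:half_size + 1, -half_size:half_size + 1]
    xr = x * np.cos(theta) + y * np.sin(theta)
    yr = -x * np.sin(theta) + y * np.cos(theta)
    envelope = np.exp(-((f / gamma) ** 2 * xr ** 2 + (f / eta) ** 2 * yr ** 2))
    carrier = np.exp(2j * np.pi * f * xr)
    return (f ** 2 / (np.pi * gamma * eta)) * envelope * carrier


def gabor_features(plane: np.ndarray, frequencies, n_orientations: int = 8,
                   gamma: float = np.sqrt(2.0), eta: float = np.sqrt(2.0)
                   ) -> np.ndarray:
    """Mean and sd of |response| per (frequency, orientation); length 2*S*O."""
    plane = np.asarray(plane, dtype=np.float64)
    thetas = [np.pi * k / n_orientations for k in range(n_orientations)]
    out = []
    for f in frequencies:
        for theta in thetas:
            k = gabor_kernel(f, theta, gamma, eta)
            if k.shape[0] > plane.shape[0] or k.shape[1] > plane.shape[1]:
                raise ValueError(f"Gabor kernel {k.shape} larger than plane "
                                 f"{plane.shape}")
            resp = signal.fftconvolve(plane, k, mode="same")
            mag = np.abs(resp)
            out.extend([mag.mean(), mag.std()])
    return np.asarray(out)


# ----------------------------------------------------------------------
# LBP riu2


def lbp_sign(x: np.ndarray, printed_threshold: bool = False) -> np.ndarray:
    """Threshold step s(.): 1 iff x >= 0 (standard); >= 1 in printed mode."""
    return (x >= (1.0 if printed_threshold else 0.0)).astype(np.uint8)


def riu2_code(bits: np.ndarray) -> np.ndarray:
    """Map P binary neighbour samples to the riu2 code.

    Uniformity U counts circular 0/1 transitions; uniform patterns (U <= 2)
    code as their number of ones, everything else as P+1.  ``bits`` is
    (P, n) or (P,).
    """
    bits = np.atleast_2d(np.asarray(bits, dtype=np.int64).T).T
    P = bits.shape[0]
    rolled = np.roll(bits, 1, axis=0)
    U = np.abs(bits - rolled).sum(axis=0)
    ones = bits.sum(axis=0)
    return np.where(U <= 2, ones, P + 1)


def lbp_riu2_histogram(plane: np.ndarray, P: int = 8, R: float = 12,
                       printed_threshold: bool = False) -> np.ndarray:
    """Normalised histogram of riu2 codes over all interior pixels; P+2 bins.

    Neighbours are sampled at radius R by bilinear interpolation; pixels
    within R of the border are skipped.
    """
    plane = np.asarray(plane, dtype=np.float64)
    H, W = plane.shape
    m = int(np.ceil(R))
    if H <= 2 * m or W <= 2 * m:
        raise ValueError(f"plane {plane.shape} too small for radius {R}")
    rows, cols = np.mgrid[m:H - m, m:W - m]
    rows, cols = rows.ravel(), cols.ravel()
    center = plane[rows, cols]
    bits = np.empty((P, rows.size), dtype=np.uint8)
    for p in range(P):
        ang = 2.0 * np.pi * p / P
        # (x, y) = (col + R cos, row + R sin)
        sample = ndimage.map_coordinates(
            plane, [rows + R * np.sin(ang), cols + R * np.cos(ang)],
            order=1, mode="nearest")
        bits[p] = lbp_sign(sample - center, printed_threshold)
    codes = riu2_code(bits)
    hist = np.bincount(codes, minlength=P + 2).astype(np.float64)
    return hist / hist.sum()


# ----------------------------------------------------------------------
# GLCM + Haralick

#: displacement vectors (drow, dcol) for 0, 45, 90, 135 degrees
GLCM_DISPLACEMENTS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def quantize(plane: np.ndarray, levels: int) -> np.ndarray:
    """Uniform quantization of a unit-scale plane to integer levels."""
    plane = np.asarray(plane, dtype=np.float64)
    q = np.floor(np.clip(plane, 0.0, 1.0) * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def glcm_fused(plane_q: np.ndarray, levels: int, delta: int = 1) -> np.ndarray:
    """Direction-fused co-occurrence matrix: sum of the four directional
    matrices, divided by 4, then normalised to unit mass."""
    q = np.asarray(plane_q)
    if q.dtype.kind not in "ui" or q.min() < 0 or q.max() >= levels:
        raise ValueError("plane must be integer-quantized to [0, levels)")
    total = np.zeros((levels, levels), dtype=np.float64)
    H, W = q.shape
    for dr, dc in GLCM_DISPLACEMENTS:
        dr, dc = dr * delta, dc * delta
        r0, r1 = max(0, -dr), min(H, H - dr)
        c0, c1 = max(0, -dc), min(W, W - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.bincount(a * levels + b, minlength=levels * levels)
        total += counts.reshape(levels, levels)
    total /= 4.0
    s = total.sum()
    if s > 0:
        total /= s
    return total


HARALICK_NAMES = (
    "asm", "contrast", "correlation", "sum_of_squares_variance",
    "inverse_difference_moment", "sum_average", "sum_variance",
    "sum_entropy", "entropy", "difference_variance", "difference_entropy",
    "info_measure_correlation_1", "info_measure_correlation_2",
    "maximal_correlation_coefficient",
)


def haralick_features(glcm: np.ndarray) -> np.ndarray:
    """The 14 classical co-occurrence statistics; entropies in bits."""
    P = np.asarray(glcm, dtype=np.float64)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(P.sum() - 1.0) > 1e-6:
        raise ValueError("GLCM must be normalised to unit mass")
    n = P.shape[0]
    i = np.arange(n)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float(i @ px)
    muy = float(i @ py)
    sx = float(np.sqrt(((i - mux) ** 2) @ px))
    sy = float(np.sqrt(((i - muy) ** 2) @ py))

    k_sum = np.arange(2 * n - 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    k_diff = np.arange(n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())

    def ent(p):
        p = p[p > _EPS]
        return float(-(p * np.log2(p)).sum())

    asm = float((P ** 2).sum())
    contrast = float((k_diff ** 2) @ p_diff)
    corr = (float((ii * jj * P).sum()) - mux * muy) / (sx * sy) \
        if sx > _EPS and sy > _EPS else 0.0
    ssq = float((((ii - mux) ** 2) * P).sum())
    idm = float((P / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float(k_sum @ p_sum)
    sum_var = float(((k_sum - sum_avg) ** 2) @ p_sum)
    sum_ent = ent(p_sum)
    entropy = ent(P.ravel())
    diff_avg = float(k_diff @ p_diff)
    diff_var = float(((k_diff - diff_avg) ** 2) @ p_diff)
    diff_ent = ent(p_diff)

    hx, hy = ent(px), ent(py)
    outer = np.outer(px, py)
    mask = (P > _EPS)
    hxy1 = float(-(P[mask] * np.log2(np.maximum(outer[mask], _EPS))).sum())
    m2 = outer > _EPS
    hxy2 = float(-(outer[m2] * np.log2(outer[m2])).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > _EPS else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    # maximal correlation coefficient: sqrt of 2nd-largest eigenvalue of Q
    sup_x = px > _EPS
    sup_y = py > _EPS
    if sup_x.sum() >= 2 and sup_y.sum() >= 2:
        Psub = P[np.ix_(sup_x, sup_y)]
        Q = (Psub / px[sup_x, None]) @ (Psub / py[sup_y]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1]))) if len(ev) >= 2 else 0.0
    else:
        mcc = 0.0

    return np.array([asm, contrast, corr, ssq, idm, sum_avg, sum_var,
                     sum_ent, entropy, diff_var, diff_ent, imc1, imc2, mcc])


# ----------------------------------------------------------------------
# intensity features


def color_moments(img: FundusImage | np.ndarray) -> np.ndarray:
    """Per-channel mean, sd, and signed cube-root skewness; length 3*C.

    Moments are population moments of the raw channel values; the third
    moment keeps its sign through the cube root.
    """
    arr = img.as_float() if isinstance(img, FundusImage) else np.asarray(
        img, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    out = []
    for c in range(arr.shape[2]):
        ch = arr[:, :, c]
        mu = ch.mean()
        sd = np.sqrt(((ch - mu) ** 2).mean())
        s3 = np.cbrt(((ch - mu) ** 3).mean())
        out.extend([mu, sd, s3])
    return np.asarray(out)


def autocorrelogram(plane: np.ndarray, n_colors: int = 64,
                    distances=(1, 3, 5, 7)) -> np.ndarray:
    """Intensity auto-correlogram over exact Chebyshev distances.

    Entry (c, d): probability that a pixel at L-inf distance exactly d from
    a colour-c pixel is also colour c; zero-support entries are 0.  Length
    n_colors * len(distances).
    """
    q = np.asarray(plane)
    if q.dtype.kind == "f" or (q.ndim == 3):
        if q.ndim == 3:                       # RGB -> intensity
            q = q.mean(axis=2)
        q = quantize(q / max(1.0, float(q.max())) if q.max() > 1 else q,
                     n_colors)
    if q.min() < 0 or q.max() >= n_colors:
        raise ValueError("plane must quantize to [0, n_colors)")
    H, W = q.shape
    out = np.zeros((len(distances), n_colors))
    for di, d in enumerate(distances):
        num = np.zeros(n_colors)
        den = np.zeros(n_colors)
        offsets = [(dr, dc) for dr in range(-d, d + 1)
                   for dc in range(-d, d + 1)
                   if max(abs(dr), abs(dc)) == d]
        for dr, dc in offsets:
            r0, r1 = max(0, -dr), min(H, H - dr)
            c0, c1 = max(0, -dc), min(W, W - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            a = q[r0:r1, c0:c1].ravel()
            b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
            den += np.bincount(a, minlength=n_colors)
            num += np.bincount(a[a == b], minlength=n_colors)
        nz = den > 0
        out[di, nz] = num[nz] / den[nz]
    return out.ravel(order="F")  # grouped by colour, then distance


# ----------------------------------------------------------------------
# feature-vector assembly


def build_feature_vector(img: RoiPatch | FundusImage,
                         selection=("lbp", "color_moments"),
                         cfg: RunConfig | None = None) -> FeatureVector:
    """Compute the requested blocks in canonical order.

    Texture blocks use the mean-of-channels intensity plane; colour moments
    use the RGB planes.  Default selection is the best-performing hybrid
    (LBP + colour moments).
    """
    cfg = cfg or RunConfig()
    if isinstance(img, RoiPatch):
        img = img.image
    selection = set(selection)
    unknown = selection - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
    if not selection:
        raise ValueError("empty feature selection")
    rgb = img.as_float()
    gray = rgb.mean(axis=2)
    blocks: dict[str, np.ndarray] = {}
    if "wavelets" in selection:
        blocks["wavelets"] = gabor_features(
            gray, cfg.gabor_frequencies, cfg.gabor_n_orientations,
            cfg.gabor_gamma, cfg.gabor_eta)
    if "multiwavelets" in selection:
        blocks["multiwavelets"] = gabor_features(
            gray, tuple(f / 2.0 for f in cfg.gabor_frequencies),
            cfg.gabor_n_orientations, cfg.gabor_gamma, cfg.gabor_eta)
    if "lbp" in selection:
        blocks["lbp"] = lbp_riu2_histogram(
            gray, cfg.lbp_points, cfg.lbp_radius, cfg.lbp_printed_threshold)
    if "haralick" in selection:
        q = quantize(gray, cfg.glcm_levels)
        blocks["haralick"] = haralick_features(
            glcm_fused(q, cfg.glcm_levels, cfg.glcm_delta))
    if "color_moments" in selection:
        blocks["color_moments"] = color_moments(rgb)
    if "correlogram" in selection:
        blocks["correlogram"] = autocorrelogram(
            quantize(gray, cfg.correlogram_colors), cfg.correlogram_colors,
            cfg.correlogram_distances)
    return FeatureVector(blocks)


def feature_names(selection, cfg: RunConfig | None = None) -> list[str]:
    """Column names matching :func:`build_feature_vector` order."""
    cfg = cfg or RunConfig()
    names: list[str] = []
    for block in BLOCK_ORDER:
        if block not in set(selection):
            continue
        if block in ("wavelets", "multiwavelets"):
            freqs = cfg.gabor_frequencies if block == "wavelets" else tuple(
                f / 2.0 for f in cfg.gabor_frequencies)
            for f in freqs:
                for o in range(cfg.gabor_n_orientations):
                    names += [f"{block}_f{f:g}_o{o}_mean",
                              f"{block}_f{f:g}_o{o}_sd"]
        elif block == "lbp":
            names += [f"lbp_riu2_{k}" for k in range(cfg.lbp_points + 2)]
        elif block == "haralick":
            names += [f"haralick_{n}" for n in HARALICK_NAMES]
        elif block == "color_moments":
            for ch in "rgb":
                names += [f"cm_{ch}_mean", f"cm_{ch}_sd", f"cm_{ch}_skew"]
        elif block == "correlogram":
            for c in range(cfg.correlogram_colors):
                names += [f"corr_c{c}_d{d}"
                          for d in cfg.correlogram_distances]
    return names
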