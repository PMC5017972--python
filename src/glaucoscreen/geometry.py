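"""Ellipse geometry: direct least-squares fitting, conic forms, CDR.

The cup and disc boundaries are smoothed by fitting the conic

    x^2 + B*x*y + C*y^2 + D*x + E*y + F = 0

to the boundary pixels.  The fit is the direct ellipse-specific least-squares
method (Fitzgibbon's 4AC - B^2 = 1 constraint in the numerically stable
Halir–Flusser block form), which minimises the algebraic residual subject to
a normalization that guarantees the solution is an ellipse — unconstrained
conic fits can return hyperbolas on noisy arcs.

The cup-to-disc ratio (CDR) is the ratio of cup to disc extent: the area
ratio by default (pi*a*b for each ellipse), or the ratio of vertical
diameters in ``vertical_diameter`` mode.  CDR > 0.5 flags glaucoma; the
boundary value 0.5 is labelled healthy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EllipseFitError(ValueError):
    """Too few points or a degenerate configuration."""


class NotAnEllipseError(ValueError):
    """Conic coefficients do not satisfy B^2 - 4C < 0."""


@dataclass(frozen=True)
class EllipseParams:
    """Conic (leading x^2 coefficient fixed at 1) plus derived geometry."""

    conic: tuple[float, float, float, float, float]  # (B, C, D, E, F)
    center: tuple[float, float]                      # (cx, cy)
    semi_axes: tuple[float, float]                   # (a, b), a >= b
    theta: float                                     # major-axis angle, [0, pi)
    area: float = field(default=0.0)

    def __post_init__(self) -> None:
        B, C, *_ = self.conic
        if B * B - 4.0 * C >= 0:
            raise NotAnEllipseError("conic is not an ellipse (B^2 - 4C >= 0)")
        a, b = self.semi_axes
        object.__setattr__(self, "area", float(np.pi * a * b))

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_conic(cls, conic) -> "EllipseParams":
        center, axes, theta = conic_to_geometric(conic)
        return cls(tuple(float(c) for c in conic), center, axes, theta)

    @classmethod
    def from_geometric(cls, center, semi_axes, theta) -> "EllipseParams":
        conic = geometric_to_conic(center, semi_axes, theta)
        a, b = max(semi_axes), min(semi_axes)
        theta = float(theta) % np.pi
        if semi_axes[0] < semi_axes[1]:
            theta = (theta + np.pi / 2.0) % np.pi
        return cls(conic, (float(center[0]), float(center[1])),
                   (float(a), float(b)), theta)

    # -- derived --------------------------------------------------------
    @property
    def vertical_diameter(self) -> float:
        a, b = self.semi_axes
        return 2.0 * float(np.hypot(a * np.sin(self.theta),
                                    b * np.cos(self.theta)))

    def sample(self, n: int = 360) -> np.ndarray:
        """n boundary points (x, y) for drawing/testing."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a, b = self.semi_axes
        ct, st = np.cos(self.theta), np.sin(self.theta)
        x = self.center[0] + a * np.cos(t) * ct - b * np.sin(t) * st
        y = self.center[1] + a * np.cos(t) * st + b * np.sin(t) * ct
        return np.column_stack([x, y])


# ----------------------------------------------------------------------
# conic <-> geometric


def conic_to_geometric(conic):
    """Reduce (B, C, D, E, F) with unit x^2 coefficient to center/axes/angle."""
    B, C, D, E, F = (float(v) for v in conic)
    disc = B * B - 4.0 * C
    if disc >= 0:
        raise NotAnEllipseError("B^2 - 4C >= 0: not an ellipse")
    # center solves 2*M*[cx, cy] = -[D, E], M = [[1, B/2], [B/2, C]]
    cx = (B * E - 2.0 * C * D) / (4.0 * C - B * B)
    cy = (B * D - 2.0 * E) / (4.0 * C - B * B)
    f0 = (cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F)
    M = np.array([[1.0, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(M)
    if f0 >= 0 or np.any(evals <= 0):
        raise NotAnEllipseError("conic has no real elliptic point set")
    # (X-c)^T M (X-c) = -f0 ; semi-axis along eigvec_i is sqrt(-f0/eval_i)
    axes = np.sqrt(-f0 / evals)            # eigh: evals ascending -> axes desc
    a, b = float(axes[0]), float(axes[1])
    major = evecs[:, 0]
    theta = float(np.arctan2(major[1], major[0])) % np.pi
    return (cx, cy), (a, b), theta


def geometric_to_conic(center, semi_axes, theta):
    """Inverse reduction; returns (B, C, D, E, F) with unit x^2 coefficient."""
    cx, cy = (float(v) for v in center)
    a, b = (float(v) for v in semi_axes)
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    ct, st = np.cos(theta), np.sin(theta)
    R = np.array([[ct, -st], [st, ct]])
    M = R @ np.diag([1.0 / a ** 2, 1.0 / b ** 2]) @ R.T
    A_ = M[0, 0]
    B_ = 2.0 * M[0, 1]
    C_ = M[1, 1]
    D_ = -2.0 * (M[0, 0] * cx + M[0, 1] * cy)
    E_ = -2.0 * (M[0, 1] * cx + M[1, 1] * cy)
    F_ = cx * cx * M[0, 0] + 2 * M[0, 1] * cx * cy + cy * cy * M[1, 1] - 1.0
    return tuple(float(v / A_) for v in (B_, C_, D_, E_, F_))


# ----------------------------------------------------------------------
# direct least-squares ellipse fit


def fit_ellipse_lsq(points) -> EllipseParams:
    """Direct ellipse-specific least-squares fit to >= 5 boundary points.

    Points are centred and isotropically scaled before the fit for numerical
    stability; the conic is mapped back to the original frame afterwards.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise EllipseFitError("need >= 5 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    mx, my = x.mean(), y.mean()
    s = np.sqrt(((x - mx) ** 2 + (y - my) ** 2).mean())
    if s <= 0:
        raise EllipseFitError("degenerate point set")
    u, v = (x - mx) / s, (y - my) / s

    D1 = np.column_stack([u * u, u * v, v * v])
    D2 = np.column_stack([u, v, np.ones_like(u)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    try:
        T = -np.linalg.solve(S3, S2.T)
    except np.linalg.LinAlgError as e:
        raise EllipseFitError("degenerate (collinear?) point set") from e
    M = S1 + S2 @ T
    # inverse of constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    M = np.array([M[2] / 2.0, -M[1], M[0] / 2.0])
    evals, evecs = np.linalg.eig(M)
    cond = np.real(4.0 * evecs[0] * evecs[2] - evecs[1] ** 2)
    good = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(good) == 0:
        raise EllipseFitError("no elliptic solution found")
    a1 = np.real(evecs[:, good[0]])
    coeffs = np.concatenate([a1, T @ a1])          # A', B', C', D', E', F'

    # undo scaling:   u = (x - mx)/s, v = (y - my)/s
    Ap, Bp, Cp, Dp, Ep, Fp = coeffs
    a_, b_, c_ = Ap / s ** 2, Bp / s ** 2, Cp / s ** 2
    d_, e_, f_ = Dp / s, Ep / s, Fp
    A = a_
    B = b_
    C = c_
    D = -2 * a_ * mx - b_ * my + d_
    E = -b_ * mx - 2 * c_ * my + e_
    F = (a_ * mx * mx + b_ * mx * my + c_ * my * my
         - d_ * mx - e_ * my + f_)
    if A == 0:
        raise EllipseFitError("degenerate conic (zero x^2 coefficient)")
    conic = tuple(float(v / A) for v in (B, C, D, E, F))
    try:
        return EllipseParams.from_conic(conic)
    except NotAnEllipseError as e:
        raise EllipseFitError(str(e)) from e


# ----------------------------------------------------------------------
# CDR


@dataclass
class CdrRecord:
    image_id: str
    cdr: float
    cdr_label: str
    clinical_cdr: float | None = None
    clamped: bool = False


def compute_cdr(cup: EllipseParams, disc: EllipseParams,
                mode: str = "area") -> float:
    """Cup-to-disc ratio; ``area`` (default) or ``vertical_diameter`` mode.

    Values above 1 (cup fit larger than disc fit) are clamped to 1.0 — use
    :func:`cdr_record` to retain the quality flag.
    """
    if mode == "area":
        if disc.area <= 0:
            raise ZeroDivisionError("disc area is zero")
        r = cup.area / disc.area
    elif mode == "vertical_diameter":
        vd = disc.vertical_diameter
        if vd <= 0:
            raise ZeroDivisionError("disc vertical diameter is zero")
        r = cup.vertical_diameter / vd
    else:
        raise ValueError(f"unknown CDR mode {mode!r}")
    return min(max(r, 0.0), 1.0)


def cdr_decide(cdr: float, threshold: float = 0.5) -> str:
    """glaucoma iff CDR strictly exceeds the threshold (<= 0.5 is healthy)."""
    if cdr < 0:
        raise ValueError("CDR must be non-negative")
    return "glaucoma" if cdr > threshold else "healthy"


def cdr_record(image_id: str, cup: EllipseParams, disc: EllipseParams,
               mode: str = "area", threshold: float = 0.5,
               clinical_cdr: float | None = None) -> CdrRecord:
    raw = (cup.area / disc.area if mode == "area"
           else cup.vertical_diameter / disc.vertical_diameter)
    cdr = compute_cdr(cup, disc, mode)
    return CdrRecord(image_id, cdr, cdr_decide(cdr, threshold),
                     clinical_cdr, clamped=raw > 1.0)
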