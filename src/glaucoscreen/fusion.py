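"""Decision fusion, screening metrics and CDR error statistics.

The two branches each emit a binary label; fusion keeps a label both agree
on and otherwise emits ``suspect`` — the referral class that sends the
patient to an ophthalmologist.  A stage failure anywhere in the per-image
pipeline also maps to ``suspect`` (fail-safe referral): the system's purpose
is screening, so an un-analysable image must not silently pass as healthy.

Metric conventions: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
accuracy = (TP+TN)/total.  Reported values are *truncated* — floored at two
decimals, accuracy at integer percent — which is the only rounding
convention consistent with the published figures (73/74 -> 0.98,
65/74 -> 0.87).  The referral variant counts suspects as positives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassifierBundle, FoldPlan, two_fold_evaluate
from .config import RunConfig
from .cup import segment_cup
from .disc import segment_disc
from .features import build_feature_vector
from .geometry import cdr_decide, compute_cdr
from .image import FundusImage
from .localize import locate_disc

log = logging.getLogger("glaucoscreen")


@dataclass
class ScreeningDecision:
    image_id: str
    cdr: float | None
    cdr_label: str | None
    ml_label: str | None
    fused: str
    provenance: dict = field(default_factory=dict)


def fuse(cdr_label: str, ml_label: str) -> str:
    """Agreement keeps the shared label; disagreement refers as suspect."""
    for lab in (cdr_label, ml_label):
        if lab not in ("glaucoma", "healthy"):
            raise ValueError(f"invalid branch label {lab!r}")
    return cdr_label if cdr_label == ml_label else "suspect"


# ----------------------------------------------------------------------
# metrics


def truncate(x: float, decimals: int = 2) -> float:
    """Floor at the given number of decimals (the reporting convention)."""
    f = 10 ** decimals
    return math.floor(x * f) / f


@dataclass
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int
    suspect_given_glaucoma: int = 0
    suspect_given_healthy: int = 0

    def __post_init__(self) -> None:
        for v in (self.tp, self.fn, self.fp, self.tn,
                  self.suspect_given_glaucoma, self.suspect_given_healthy):
            if v < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_glaucoma(self) -> int:
        return self.tp + self.fn + self.suspect_given_glaucoma

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp + self.suspect_given_healthy

    @property
    def total(self) -> int:
        return self.n_glaucoma + self.n_healthy

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionTable":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        g = truth == "glaucoma"
        h = truth == "healthy"
        return cls(
            tp=int((g & (predicted == "glaucoma")).sum()),
            fn=int((g & (predicted == "healthy")).sum()),
            fp=int((h & (predicted == "glaucoma")).sum()),
            tn=int((h & (predicted == "healthy")).sum()),
            suspect_given_glaucoma=int((g & (predicted == "suspect")).sum()),
            suspect_given_healthy=int((h & (predicted == "suspect")).sum()),
        )


def confusion_metrics(t: ConfusionTable) -> tuple[float, float, int]:
    """(sensitivity, specificity, accuracy %) from binary counts, truncated."""
    if t.tp + t.fn == 0 or t.tn + t.fp == 0 or t.total == 0:
        raise ZeroDivisionError("undefined metric: empty class")
    sens = truncate(t.tp / (t.tp + t.fn))
    spec = truncate(t.tn / (t.tn + t.fp))
    acc = int(math.floor(100.0 * (t.tp + t.tn) / t.total))
    return sens, spec, acc


def referral_metrics(t: ConfusionTable) -> tuple[float, float]:
    """(referral sensitivity, specificity) of the fused three-class output.

    Referral positives are fused glaucoma *or* suspect; specificity counts
    only fused-healthy images in the numerator but all healthy images in the
    denominator.  Both truncated at two decimals.
    """
    if t.n_glaucoma == 0 or t.n_healthy == 0:
        raise ZeroDivisionError("undefined metric: empty class")
    referred_g = t.tp + t.suspect_given_glaucoma
    sens = truncate(referred_g / t.n_glaucoma)
    spec = truncate(t.tn / t.n_healthy)
    return sens, spec


def cdr_error_stats(pairs) -> tuple[float, float, float]:
    """(mean, sd, max) of |clinical CDR - computed CDR| over image pairs."""
    arr = np.asarray(list(pairs), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no CDR pairs")
    err = np.abs(arr[:, 0] - arr[:, 1])
    return float(err.mean()), float(err.std()), float(err.max())


# ----------------------------------------------------------------------
# end-to-end screening


def structural_cdr(img: FundusImage, cfg: RunConfig | None = None):
    """Localize the disc, run both segmentation branches, return
    ``(cdr, cdr_label, roi, cup_result, disc_result)``."""
    cfg = cfg or RunConfig()
    _, roi = locate_disc(img, cfg)
    cup = segment_cup(roi, cfg)
    disc = segment_disc(roi, cfg)
    cdr = compute_cdr(cup.ellipse, disc.ellipse, cfg.cdr_mode)
    return cdr, cdr_decide(cdr, cfg.cdr_threshold), roi, cup, disc


def screen_image(img: FundusImage, cfg: RunConfig,
                 model: ClassifierBundle, image_id: str = "",
                 feature_blocks=("lbp", "color_moments", "correlogram"),
                 ) -> ScreeningDecision:
    """Full per-image screening: structural CDR + ML label + fusion.

    Any stage failure yields a ``suspect`` decision carrying the error in
    its provenance instead of raising.
    """
    prov: dict = {}
    cdr = cdr_label = ml_label = None
    try:
        cdr, cdr_label, roi, _, _ = structural_cdr(img, cfg)
        prov["cdr"] = cdr
        fv = build_feature_vector(roi, feature_blocks, cfg)
        ml_label = str(model.predict(fv.values[None, :])[0])
    except Exception as e:  # fail-safe referral
        log.warning("screening failure for %s: %s", image_id or "<image>", e)
        prov["error"] = str(e)
        return ScreeningDecision(image_id, cdr, cdr_label, ml_label,
                                 "suspect", prov)
    return ScreeningDecision(image_id, cdr, cdr_label, ml_label,
                             fuse(cdr_label, ml_label), prov)


def screen_cohort_two_fold(cohort, cfg: RunConfig | None = None,
                           feature_blocks=("lbp", "color_moments", "correlogram"),
                           seed: int = 0):
    """Evaluate a labelled cohort end to end with the two-fold protocol.

    ``cohort`` is a list of (FundusImage, truth-with-.label[/.true_cdr]).
    The structural branch runs per image; the ML branch is trained/tested
    two-fold on the true labels.  Returns ``(decisions, table)`` where the
    table is the fused three-class confusion summary.
    """
    cfg = cfg or RunConfig.profile("small")
    labels = np.array([t.label for _, t in cohort])
    cdrs: list[float | None] = []
    cdr_labels: list[str | None] = []
    feats = []
    for idx, (img, _) in enumerate(cohort):
        try:
            cdr, lab, roi, _, _ = structural_cdr(img, cfg)
        except Exception as e:
            log.warning("structural branch failed on image %d: %s", idx, e)
            cdr, lab, roi = None, None, None
            _, roi = locate_disc(img, cfg)  # features still need a crop
        cdrs.append(cdr)
        cdr_labels.append(lab)
        feats.append(build_feature_vector(roi, feature_blocks, cfg).values)
    X = np.vstack(feats)
    plan = FoldPlan.stratified(labels, seed=seed if seed else cfg.seed)
    _, ml_preds = two_fold_evaluate(X, labels, plan, k=cfg.pca_k,
                                    variance_target=cfg.pca_variance,
                                    C=cfg.svm_c)
    decisions = []
    for i, (cdr, c_lab, m_lab) in enumerate(zip(cdrs, cdr_labels, ml_preds)):
        iid = f"syn{i + 1:03d}"
        if c_lab is None:
            decisions.append(ScreeningDecision(
                iid, None, None, str(m_lab), "suspect",
                {"error": "structural branch failed"}))
        else:
            decisions.append(ScreeningDecision(
                iid, cdr, c_lab, str(m_lab), fuse(c_lab, str(m_lab)),
                {"cdr": cdr}))
    fused = np.array([d.fused for d in decisions])
    return decisions, ConfusionTable.from_predictions(labels, fused)
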