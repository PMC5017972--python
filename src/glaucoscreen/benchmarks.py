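"""Published clinical benchmark numbers used as metric-arithmetic inputs.

These are the evaluation counts and per-image CDR values reported for the
method's 100-image clinical cohort (26 glaucomatous, 74 healthy eyes).  The
images themselves are private; the printed numbers are retained so the
metric arithmetic (confusion metrics, referral metrics, CDR error
statistics) can be exercised and reproduced exactly.
"""

from __future__ import annotations

from .fusion import ConfusionTable

#: structural (CDR) branch on the 100-image cohort: TP=24, FN=2, FP=1, TN=73
CDR_MODULE_COUNTS = ConfusionTable(tp=24, fn=2, fp=1, tn=73)

#: machine-learning branch on the same cohort: TP=24, FN=2, FP=7, TN=67
ML_MODULE_COUNTS = ConfusionTable(tp=24, fn=2, fp=7, tn=67)

#: fused three-class output: glaucoma row (22 glaucoma / 0 healthy /
#: 4 suspect), healthy row (1 glaucoma / 65 healthy / 8 suspect)
FUSED_COUNTS = ConfusionTable(tp=22, fn=0, fp=1, tn=65,
                              suspect_given_glaucoma=4,
                              suspect_given_healthy=8)

#: per-image (image_id, clinical CDR, computed CDR) for the 99 images with
#: a published pair
CLINICAL_CDR_PAIRS: tuple[tuple[str, float, float], ...] = (
    ("f1", 0.3, 0.32),
    ("f2", 0.4, 0.42),
    ("f3", 0.6, 0.62),
    ("f4", 1, 1),
    ("f5", 0.4, 0.36),
    ("f6", 0.4, 0.43),
    ("f7", 0.7, 0.69),
    ("f8", 0.6, 0.67),
    ("f9", 0.3, 0.39),
    ("f10", 0.4, 0.38),
    ("f11", 0.6, 0.53),
    ("f12", 0.5, 0.49),
    ("f13", 0.3, 0.30),
    ("f14", 1, 1),
    ("f15", 0.3, 0.32),
    ("f16", 0.5, 0.44),
    ("f17", 0.5, 0.38),
    ("f18", 0.3, 0.31),
    ("f19", 0.4, 0.27),
    ("f20", 0.3, 0.32),
    ("f21", 0.5, 0.39),
    ("f22", 0.4, 0.40),
    ("f23", 0.4, 0.46),
    ("f24", 0.2, 0.35),
    ("f25", 0.6, 0.59),
    ("f26", 0.6, 0.78),
    ("f27", 0.6, 0.56),
    ("f28", 0.3, 0.29),
    ("f29", 0.5, 0.49),
    ("f30", 0.4, 0.39),
    ("f31", 0.4, 0.34),
    ("f32", 0.4, 0.46),
    ("f33", 0.6, 0.60),
    ("f34", 0.3, 0.40),
    ("f35", 0.4, 0.43),
    ("f36", 0.4, 0.42),
    ("f37", 0.4, 0.48),
    ("f38", 0.5, 0.52),
    ("f39", 0.4, 0.38),
    ("f40", 0.6, 0.55),
    ("f41", 0.5, 0.45),
    ("f42", 0.6, 0.45),
    ("f43", 0.5, 0.47),
    ("f44", 0.5, 0.40),
    ("f45", 0.6, 0.54),
    ("f46", 0.4, 0.42),
    ("f47", 0.6, 0.61),
    ("f48", 0.6, 0.62),
    ("f49", 0.4, 0.42),
    ("f50", 0.4, 0.34),
    ("f51", 0.5, 0.42),
    ("f52", 0.3, 0.35),
    ("f53", 0.6, 0.61),
    ("f54", 0.3, 0.35),
    ("f55", 0.4, 0.44),
    ("f56", 0.5, 0.42),
    ("f57", 0.4, 0.33),
    ("f58", 0.4, 0.41),
    ("f59", 0.9, 0.59),
    ("f60", 0.6, 0.65),
    ("f61", 0.5, 0.49),
    ("f62", 0.5, 0.38),
    ("f63", 0.5, 0.40),
    ("f64", 0.4, 0.41),
    ("f65", 0.4, 0.45),
    ("f66", 0.4, 0.43),
    ("f67", 0.6, 0.52),
    ("f68", 0.4, 0.35),
    ("f69", 0.7, 0.64),
    ("f70", 0.4, 0.39),
    ("f71", 0.5, 0.49),
    ("f72", 0.4, 0.35),
    ("f73", 0.4, 0.39),
    ("f74", 0.5, 0.47),
    ("f75", 0.5, 0.49),
    ("f76", 0.4, 0.47),
    ("f77", 0.7, 0.67),
    ("f78", 0.8, 0.66),
    ("f79", 0.4, 0.38),
    ("f80", 0.5, 0.46),
    ("f81", 0.4, 0.39),
    ("f82", 0.4, 0.41),
    ("f83", 0.5, 0.38),
    ("f84", 0.5, 0.38),
    ("f85", 0.5, 0.40),
    ("f86", 0.5, 0.50),
    ("f87", 0.4, 0.42),
    ("f88", 0.5, 0.36),
    ("f89", 0.5, 0.37),
    ("f90", 0.6, 0.39),
    ("f91", 0.4, 0.37),
    ("f92", 0.4, 0.40),
    ("f93", 0.6, 0.55),
    ("f94", 1, 0.88),
    ("f95", 0.4, 0.37),
    ("f96", 0.3, 0.41),
    ("f97", 0.4, 0.32),
    ("f98", 0.4, 0.36),
    ("f99", 0.6, 0.60),
)
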