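"""Run configuration for the screening pipeline.

Every tunable constant of the pipeline lives here with its default.  Defaults
follow the published operating point of the method where one is stated (ROI
size 155x175, ball structuring element radius/height 40, disc opening radius
15 repeated three times, region-growing threshold 0.025 on the unit intensity
scale, CDR decision threshold 0.5); everything the method leaves open (LoG
scale, vessel detector, percentile stretch bounds, feature-bank parameters,
PCA rule, SVM C) is an explicit, documented field.

Two resolution profiles are provided: ``large`` (1504x1000 fundus frames) and
``small`` (415x452 frames).  Structuring-element radii scale with the image
diagonal between profiles so a fixed-size ball does not swallow a small disc.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: diagonal ratio between the small (415x452) and large (1504x1000) frames
_SMALL_SCALE = math.hypot(415, 452) / math.hypot(1504, 1000)


@dataclass
class RunConfig:
    """Flat bag of pipeline constants; YAML round-trippable."""

    # --- geometry / localization ---
    roi_size: tuple[int, int] = (155, 175)  # (height, width) of the disc ROI
    log_sigma_frac: float = 0.05            # LoG scale = frac * min(H, W)
    bright_fraction: float = 0.40           # fraction of LoG response kept
    vessel_tophat_radius: int = 7           # black top-hat disk radius (px)
    vessel_window: tuple[int, int] = (101, 101)  # vessel-density window (px)

    # --- preprocessing ---
    stretch_lo_percentile: float = 1.0
    stretch_hi_percentile: float = 99.0
    stretch_hue: bool = True                # stretch H plane too (literal mode)

    # --- cup segmentation ---
    ball_radius: int = 40                   # non-flat ball SE radius (px)
    ball_height: float = 40.0 / 255.0       # ball height on the unit scale
    region_grow_threshold: float = 0.025    # homogeneity bound, unit scale
    cup_use_canny: bool = False             # contour tracing by default

    # --- disc segmentation ---
    disc_open_radius: int = 15              # flat disk SE radius (px)
    disc_open_repetitions: int = 3
    min_object_area: int = 50               # px^2, small-object removal

    # --- decision ---
    cdr_threshold: float = 0.5
    cdr_mode: str = "area"                  # "area" | "vertical_diameter"

    # --- features ---
    gabor_frequencies: tuple[float, ...] = (0.1, 0.2, 0.3)   # cycles/px
    gabor_n_orientations: int = 8
    gabor_gamma: float = math.sqrt(2.0)
    gabor_eta: float = math.sqrt(2.0)
    lbp_points: int = 8
    lbp_radius: int = 12
    lbp_printed_threshold: bool = False     # use the s(x)>=1 printed variant
    glcm_levels: int = 64
    glcm_delta: int = 1
    correlogram_colors: int = 64
    correlogram_distances: tuple[int, ...] = (1, 3, 5, 7)

    # --- classification ---
    svm_c: float = 1.0
    pca_variance: float = 0.95              # used when pca_k is None
    pca_k: int | None = None
    seed: int = 0

    # ------------------------------------------------------------------
    @classmethod
    def profile(cls, name: str) -> "RunConfig":
        """Preset for the two published frame resolutions.

        ``large``: 1504x1000 frames, the stated constants verbatim.
        ``small``: 415x452 frames; structuring elements scaled by the image
        diagonal ratio (~0.34) so morphology stays proportionate.
        """
        if name == "large":
            return cls()
        if name == "small":
            s = _SMALL_SCALE
            return cls(
                ball_radius=max(3, round(40 * s)),
                ball_height=40.0 / 255.0 * s,
                disc_open_radius=max(2, round(15 * s)),
                vessel_tophat_radius=max(3, round(7 * s)),
                vessel_window=(61, 61),
                min_object_area=max(10, round(50 * s * s)),
            )
        raise ValueError(f"unknown profile {name!r}; use 'large' or 'small'")

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for k, v in data.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)
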