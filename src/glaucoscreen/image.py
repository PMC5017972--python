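"""Image and table I/O.

The in-memory raster container is :class:`FundusImage`: an integer H×W×C grid
with an explicit bit depth ``L`` (intensities in ``[0, 2**L - 1]``) and a
colorspace tag.  All pipeline arithmetic happens on the unit scale via
:meth:`FundusImage.as_float`; integers only appear at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageOps, UnidentifiedImageError

log = logging.getLogger("glaucoscreen")

COLORSPACES = ("RGB", "HSV", "GRAY")


class FormatError(ValueError):
    """Unparseable or invalid input file."""


@dataclass
class FundusImage:
    """Raster container: integer pixels, bit depth, colorspace tag."""

    pixels: np.ndarray          # H×W×C (C=3) or H×W (GRAY), integer dtype
    bit_depth: int = 8
    colorspace: str = "RGB"

    def __post_init__(self) -> None:
        if self.colorspace not in COLORSPACES:
            raise ValueError(f"colorspace must be one of {COLORSPACES}")
        px = np.asarray(self.pixels)
        if self.colorspace == "GRAY":
            if px.ndim == 3 and px.shape[2] == 1:
                px = px[:, :, 0]
            if px.ndim != 2:
                raise ValueError("GRAY image must be H×W")
        else:
            if px.ndim != 3 or px.shape[2] != 3:
                raise ValueError(f"{self.colorspace} image must be H×W×3")
        hi = 2 ** self.bit_depth - 1
        if px.min() < 0 or px.max() > hi:
            raise ValueError(f"intensities outside [0, {hi}]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def as_float(self) -> np.ndarray:
        """Pixels on the unit scale [0, 1] as float64."""
        return self.pixels.astype(np.float64) / (2 ** self.bit_depth - 1)

    @classmethod
    def from_float(cls, arr: np.ndarray, colorspace: str = "RGB",
                   bit_depth: int = 8) -> "FundusImage":
        """Quantize a unit-scale array back to the integer grid (round-half-up)."""
        hi = 2 ** bit_depth - 1
        px = np.floor(np.clip(arr, 0.0, 1.0) * hi + 0.5).astype(
            np.uint8 if bit_depth <= 8 else np.uint16)
        return cls(px, bit_depth=bit_depth, colorspace=colorspace)


def read_image(path: str | Path) -> FundusImage:
    """Read a PNG/TIFF/JPEG file as an 8-bit RGB :class:`FundusImage`.

    Grayscale files are promoted to three equal channels; EXIF orientation
    is applied before the pixel grid is returned.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with Image.open(path) as im:
            im = ImageOps.exif_transpose(im)
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.uint8)
    except UnidentifiedImageError as e:
        raise FormatError(f"not an image file: {path}") from e
    except OSError as e:  # truncated / corrupt
        raise FormatError(f"unreadable image file: {path}: {e}") from e
    return FundusImage(arr, bit_depth=8, colorspace="RGB")


def write_image(img: FundusImage | np.ndarray, path: str | Path) -> None:
    """Write an image or a binary/float mask as PNG/TIFF."""
    if isinstance(img, FundusImage):
        arr = img.pixels
    else:
        arr = np.asarray(img)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8) * 255
        elif arr.dtype.kind == "f":
            arr = np.floor(np.clip(arr, 0, 1) * 255 + 0.5).astype(np.uint8)
    Image.fromarray(arr).save(path)


# ----------------------------------------------------------------------
# annotation tables and reports


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a clinical-CDR annotation CSV.

    Expected header: ``image_id,clinical_cdr[,label]``.  Rows with
    ``clinical_cdr`` outside [0, 1] or duplicate ids are rejected.
    """
    df = pd.read_csv(path, dtype={"image_id": str})
    required = {"image_id", "clinical_cdr"}
    if not required.issubset(df.columns):
        raise FormatError(f"annotation CSV must have columns {sorted(required)}")
    if df["image_id"].duplicated().any():
        dups = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ValueError(f"duplicate image_id values: {dups}")
    cdr = pd.to_numeric(df["clinical_cdr"], errors="raise")
    bad = (cdr < 0) | (cdr > 1) | cdr.isna()
    if bad.any():
        raise ValueError(
            f"clinical_cdr outside [0,1] for: {df.loc[bad, 'image_id'].tolist()}")
    df["clinical_cdr"] = cdr
    if "label" in df.columns:
        ok = df["label"].isin(["glaucoma", "healthy"]) | df["label"].isna()
        if not ok.all():
            raise ValueError("label must be 'glaucoma' or 'healthy'")
    return df


def write_report(decisions, path: str | Path) -> None:
    """Write per-image screening decisions as a deterministic CSV.

    Columns: image_id, cdr, cdr_label, ml_label, fused_label; rows sorted by
    image_id so reruns are byte-identical.
    """
    decisions = list(decisions)
    if not decisions:
        raise ValueError("no decisions to report")
    rows = [
        {
            "image_id": d.image_id,
            "cdr": "" if d.cdr is None else f"{d.cdr:.4f}",
            "cdr_label": d.cdr_label or "",
            "ml_label": d.ml_label or "",
            "fused_label": d.fused,
        }
        for d in decisions
    ]
    df = pd.DataFrame(rows).sort_values("image_id", kind="mergesort")
    df.to_csv(path, index=False, lineterminator="\n")
    log.info("wrote report with %d rows to %s", len(df), path)
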