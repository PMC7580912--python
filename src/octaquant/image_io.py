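"""Reading and writing en-face angiogram rasters and per-eye tables.

An en-face slab is a square, single-channel, 8- or 16-bit raster (PNG or
TIFF) covering a fovea-centred square field of view.  Anything with a
palette, alpha channel, or colour is rejected rather than flattened, since
flattening would distort the decorrelation intensities that downstream
metrics average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import NamedTuple, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, RecordError, SchemaError

__all__ = [
    "Plexus",
    "EnFaceImage",
    "EyeRecord",
    "QcOutcome",
    "load_enface",
    "write_enface",
    "load_mask",
    "write_mask",
    "normalize_intensity",
    "qc_eligible",
    "load_parameter_table",
    "write_parameter_table",
]

#: Central macular thickness cutoffs (um) above which an eye is excluded
#: for macular edema; strict "greater than" by sex.
CMT_EDEMA_CUTOFF_UM = {"M": 320.0, "F": 305.0}

MIN_Q_SCORE = 6.0
MIN_SSI = 50.0


class Plexus(str, Enum):
    """Capillary layer of an en-face slab."""

    SCP = "SCP"
    MCP = "MCP"
    DCP = "DCP"
    RETINA = "RETINA"


_DTYPE_TO_DEPTH = {np.dtype(np.uint8): 8, np.dtype(np.uint16): 16}


@dataclass
class EnFaceImage:
    """One plexus slab: an integer intensity grid plus physical metadata.

    Parameters
    ----------
    pixels
        Square 2D array of non-negative integers (uint8 or uint16).
    plexus
        Which capillary layer the slab was exported from.
    fov_mm
        Physical side length of the square field of view in mm.
    bit_depth
        8 or 16; bounds the admissible intensity range.
    """

    pixels: np.ndarray
    plexus: Plexus
    fov_mm: float = 3.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected a 2D grid, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise DimensionError(f"grid must be square, got {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError(f"intensities must be integer, got {self.pixels.dtype}")
        if self.fov_mm <= 0:
            raise ValueError(f"fov_mm must be positive, got {self.fov_mm}")
        lo, hi = self.pixels.min(initial=0), self.pixels.max(initial=0)
        if lo < 0 or hi > self.intensity_max:
            raise FormatError(
                f"intensities [{lo}, {hi}] outside [0, {self.intensity_max}]"
            )
        self.plexus = Plexus(self.plexus)

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def intensity_max(self) -> int:
        return (1 << self.bit_depth) - 1


def load_enface(path: str | Path, plexus: Plexus | str, fov_mm: float = 3.0) -> EnFaceImage:
    """Read a single-channel PNG/TIFF slab; bit depth inferred from dtype."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel raster, got shape {arr.shape}"
        )
    depth = _DTYPE_TO_DEPTH.get(arr.dtype)
    if depth is None:
        raise FormatError(f"{path}: unsupported dtype {arr.dtype}; need uint8/uint16")
    if arr.shape[0] != arr.shape[1]:
        raise DimensionError(f"{path}: non-square grid {arr.shape}")
    return EnFaceImage(pixels=arr, plexus=Plexus(plexus), fov_mm=fov_mm, bit_depth=depth)


def write_enface(img: EnFaceImage, path: str | Path) -> None:
    """Write the slab losslessly (PNG or TIFF chosen by extension)."""
    iio.imwrite(path, img.pixels)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster: 0 = background, anything else = foreground."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel, got {arr.shape}")
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def normalize_intensity(img: EnFaceImage) -> np.ndarray:
    """Map raw intensities onto [0, 1] by dividing by the dtype maximum.

    The decorrelation scale of exported slabs is device-defined; this
    order-preserving rescale puts flow-index averages on a [0, 1] scale.
    """
    return img.pixels.astype(np.float64) / img.intensity_max


@dataclass
class EyeRecord:
    """Demographics, QC indices, severity stage, and computed parameters.

    ``stage`` is the ordered severity code: 0 healthy, 1 diabetic without
    retinopathy, 2 mild, 3 moderate, 4 severe NPDR.
    """

    eye_id: str
    stage: int
    age: float
    sex: Optional[str] = None
    q_score: Optional[float] = None
    ssi: Optional[float] = None
    cmt_um: Optional[float] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = int(self.stage)
        if self.stage not in (0, 1, 2, 3, 4):
            raise RecordError(f"{self.eye_id}: stage must be in 0..4, got {self.stage}")
        if self.age is not None and not math.isnan(self.age) and self.age <= 0:
            raise RecordError(f"{self.eye_id}: age must be positive, got {self.age}")
        if self.q_score is not None and self.q_score < 0:
            raise RecordError(f"{self.eye_id}: q_score must be >= 0")
        if self.sex is not None and self.sex not in ("M", "F"):
            raise RecordError(f"{self.eye_id}: sex must be 'M' or 'F', got {self.sex!r}")


class QcOutcome(NamedTuple):
    eligible: bool
    failed: list
    skipped: list


def qc_eligible(rec: EyeRecord) -> QcOutcome:
    """Apply the scan-quality and macular-edema eligibility gates.

    Eligible iff q_score >= 6, ssi >= 50, and central macular thickness is
    not strictly above the sex-specific edema cutoff (320 um for men,
    305 um for women).  Missing q_score/ssi/cmt fields are reported as
    skipped criteria, never as failures.
    """
    failed: list[str] = []
    skipped: list[str] = []

    if rec.q_score is None:
        skipped.append("q_score")
    elif rec.q_score < MIN_Q_SCORE:
        failed.append("q_score")

    if rec.ssi is None:
        skipped.append("ssi")
    elif rec.ssi < MIN_SSI:
        failed.append("ssi")

    if rec.cmt_um is None:
        skipped.append("macular_edema")
    elif rec.sex is None:
        skipped.append("macular_edema")
    elif rec.cmt_um > CMT_EDEMA_CUTOFF_UM[rec.sex]:
        failed.append("macular_edema")

    return QcOutcome(eligible=not failed, failed=failed, skipped=skipped)


_CORE_COLUMNS = {"eye_id", "stage", "age", "sex", "q_score", "ssi", "cmt_um"}


def load_parameter_table(path: str | Path) -> list[EyeRecord]:
    """Read a per-eye CSV into validated records.

    Required columns: ``eye_id``, ``stage``, ``age``.  ``sex``, ``q_score``,
    ``ssi`` and ``cmt_um`` are picked up when present; every other numeric
    column is preserved in ``params``.
    """
    df = pd.read_csv(path)
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> list[EyeRecord]:
    for col in ("eye_id", "stage", "age"):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    param_cols = [c for c in df.columns if c not in _CORE_COLUMNS]
    records = []
    for _, row in df.iterrows():
        def _opt(col):
            if col not in df.columns:
                return None
            v = row[col]
            return None if pd.isna(v) else v

        params = {c: row[c] for c in param_cols if not pd.isna(row[c])}
        records.append(
            EyeRecord(
                eye_id=str(row["eye_id"]),
                stage=int(row["stage"]),
                age=float(row["age"]),
                sex=_opt("sex"),
                q_score=_opt("q_score"),
                ssi=_opt("ssi"),
                cmt_um=_opt("cmt_um"),
                params=params,
            )
        )
    return records


def write_parameter_table(records: list[EyeRecord], path: str | Path) -> None:
    """Write records to CSV so that a round trip reproduces them."""
    frame = records_to_frame(records)
    frame.to_csv(path, index=False)


def records_to_frame(records: list[EyeRecord]) -> pd.DataFrame:
    param_cols: list[str] = []
    for rec in records:
        for k in rec.params:
            if k not in param_cols:
                param_cols.append(k)
    rows = []
    for rec in records:
        row = {
            "eye_id": rec.eye_id,
            "stage": rec.stage,
            "age": rec.age,
            "sex": rec.sex,
            "q_score": rec.q_score,
            "ssi": rec.ssi,
            "cmt_um": rec.cmt_um,
        }
        for k in param_cols:
            row[k] = rec.params.get(k, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
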