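"""Per-eye and per-study orchestration with structured logging.

``run_eye`` chains threshold derivation and metric computation for one
eye; ``run_study`` maps it over a cohort (or consumes a precomputed
parameter table) and hands the per-eye rows to the statistics layer.
Per-eye failures never abort a study: they become first-class rows in the
failure log and the report covers every eye that completed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .binarize import (
    DEFAULT_FIT_UPPER_FRAC,
    DEFAULT_MIN_SEGMENT,
    ThresholdResult,
    compute_vld_threshold,
)
from .errors import InputError, OctaQuantError
from .geometry import AnnulusSpec
from .image_io import EnFaceImage, EyeRecord, Plexus, records_from_frame
from .metrics import MetricSet, compute_metricset
from .stats import run_cohort_report

__all__ = ["RunConfig", "run_eye", "run_study"]

DEFAULT_PARAMS = ("SCP_VD", "MCP_VD", "DCP_VD", "SCP_VLD", "SCP_AFI", "MCP_AFI", "DCP_AFI", "FAZ")
DEFAULT_ROC_PARAMS = ("SCP_VD", "SCP_VLD", "MCP_VD")


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; serializable so outputs are traceable."""

    fov_mm: float = 3.0
    t_min: int = 1
    t_max: Optional[int] = None
    min_segment: int = DEFAULT_MIN_SEGMENT
    fit_upper_frac: float = DEFAULT_FIT_UPPER_FRAC
    outer_diameter_mm: float = 3.0
    inner_diameter_mm: float = 1.0
    fdr: float = 0.05
    rng_seed: int = 0
    params: Tuple[str, ...] = DEFAULT_PARAMS
    roc_params: Tuple[str, ...] = DEFAULT_ROC_PARAMS

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("params", "roc_params"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def annulus(self) -> AnnulusSpec:
        return AnnulusSpec(
            outer_diameter_mm=self.outer_diameter_mm,
            inner_diameter_mm=self.inner_diameter_mm,
        )


def run_eye(
    images: Dict[Plexus, EnFaceImage],
    config: RunConfig,
    faz_mask: Optional[np.ndarray] = None,
    faz_seed: Optional[Tuple[int, int]] = None,
) -> Tuple[MetricSet, dict]:
    """Threshold from the DCP slab, then all metrics at that threshold.

    Returns the metric set and a diagnostics record (config hash,
    threshold, fit coefficients) suitable for line-delimited audit logs.
    """
    if Plexus.DCP not in images:
        raise InputError("missing required plexus slab: DCP")
    result: ThresholdResult = compute_vld_threshold(
        images[Plexus.DCP],
        t_min=config.t_min,
        t_max=config.t_max,
        min_segment=config.min_segment,
        fit_upper_frac=config.fit_upper_frac,
    )
    metrics = compute_metricset(
        images,
        result,
        annulus=config.annulus(),
        faz_mask=faz_mask,
        faz_seed=faz_seed,
    )
    diagnostics = {
        "config_digest": config.digest(),
        "threshold": result.threshold,
        "fit_breakpoint": result.fit.breakpoint,
        "fit_intersection_x": result.fit.intersection_x,
        "fit_noise_line": list(result.fit.noise_line),
        "fit_signal_line": list(result.fit.signal_line),
        "fit_sse": result.fit.total_sse,
        "fit_range": list(result.fit.fit_range),
    }
    return metrics, diagnostics


def run_study(
    config: RunConfig,
    eyes: Optional[Dict[str, Dict[Plexus, EnFaceImage]]] = None,
    records: Optional[List[EyeRecord]] = None,
    parameter_table: Optional[pd.DataFrame] = None,
    out_dir: Optional[str | Path] = None,
) -> Dict[str, pd.DataFrame]:
    """Full pipeline (images per eye) or statistics-only (parameter table).

    Exactly one of ``eyes`` (with optional ``records`` carrying stage and
    covariates keyed by eye_id) or ``parameter_table``/``records`` must be
    given.  Returns the per-eye table plus the cohort report tables; when
    ``out_dir`` is set, each table and the config are also written as
    CSV/JSON.
    """
    failures: List[dict] = []
    diag_log: List[dict] = []

    if eyes is not None:
        rec_by_id = {r.eye_id: r for r in (records or [])}
        out_records: List[EyeRecord] = []
        for eye_id, images in eyes.items():
            try:
                metrics, diag = run_eye(images, config)
            except OctaQuantError as exc:
                failures.append({"eye_id": eye_id, "error": str(exc)})
                continue
            diag.update({"eye_id": eye_id})
            diag_log.append(diag)
            base = rec_by_id.get(eye_id)
            if base is None:
                failures.append({"eye_id": eye_id, "error": "no cohort record"})
                continue
            merged = dict(base.params)
            merged.update(metrics.as_row())
            out_records.append(dataclasses.replace(base, params=merged))
        use_records = out_records
    elif parameter_table is not None:
        use_records = records_from_frame(parameter_table)
    elif records is not None:
        use_records = list(records)
    else:
        raise InputError("provide images per eye, records, or a parameter table")

    from .image_io import records_to_frame

    per_eye = records_to_frame(use_records)
    params = [p for p in config.params if p in per_eye.columns and per_eye[p].notna().any()]
    report = run_cohort_report(
        use_records,
        params=params,
        roc_params=[p for p in config.roc_params if p in params],
        fdr=config.fdr,
    )
    report["per_eye"] = per_eye
    report["failures"] = pd.DataFrame(failures)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_json(out / "config.json")
        for name, frame in report.items():
            frame.to_csv(out / f"{name}.csv", index=False)
        with open(out / "eye_log.jsonl", "w") as fh:
            for rec in diag_log:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return report
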