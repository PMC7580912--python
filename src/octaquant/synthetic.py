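"""Seeded synthetic angiograms and cohort tables with ground truth.

Angiograms are built from branched biased-random-walk capillary networks
that avoid a central avascular disk, dilated to sampled vessel calibers,
with vessel and background intensities drawn from two configurable
(nominally separated) uniform ranges.  The generator records the true
vessel mask, centerline skeleton, noise/signal boundary intensity, and
true density metrics before intensity sampling, so recovery of each
quantity by the measurement pipeline can be tested exactly.

Cohort tables draw per-eye parameters from per-stage normal distributions
with optional linear age and quality-score confounding, mirroring the
group-plus-covariate structure the statistics layer assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from skimage.morphology import dilation, disk

from .errors import ParameterError
from .geometry import AnnulusSpec, PixelScale, make_parafoveal_mask
from .image_io import EnFaceImage, EyeRecord, Plexus

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CohortSpec",
    "generate_angiogram",
    "generate_cohort",
    "DEFAULT_PARAM_MEANS",
    "DEFAULT_PARAM_SDS",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-plexus angiogram.

    ``noise_intensity`` and ``vessel_intensity`` are inclusive integer
    ranges; their nominal supports must be ordered noise < vessel (they
    may overlap, in which case the recorded signal boundary is the upper
    edge of the noise range, i.e. its attainable maximum).
    """

    shape: Tuple[int, int] = (304, 304)
    fov_mm: float = 3.0
    n_seeds: int = 40
    vessel_width_px: Tuple[int, int] = (1, 3)
    dropout_fraction: float = 0.0
    faz_radius_mm: float = 0.25
    vessel_intensity: Tuple[int, int] = (150, 230)
    noise_intensity: Tuple[int, int] = (20, 55)
    bit_depth: int = 8
    rng_seed: int = 0
    branch_prob: float = 0.04
    step_jitter_deg: float = 14.0
    max_walkers: int = 400

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction <= 1.0):
            raise ParameterError("dropout_fraction must lie in [0, 1]")
        if self.noise_intensity[0] > self.noise_intensity[1]:
            raise ParameterError("noise_intensity range is reversed")
        if self.vessel_intensity[0] > self.vessel_intensity[1]:
            raise ParameterError("vessel_intensity range is reversed")
        if self.noise_intensity[0] >= self.vessel_intensity[0]:
            raise ParameterError("noise support must start below vessel support")
        half_field = self.fov_mm / 2.0
        if self.faz_radius_mm >= half_field:
            raise ParameterError(
                f"avascular radius {self.faz_radius_mm} mm does not fit in a "
                f"{self.fov_mm} mm field"
            )
        hi = (1 << self.bit_depth) - 1
        if self.vessel_intensity[1] > hi:
            raise ParameterError("vessel intensities exceed bit depth")


@dataclass
class GroundTruth:
    """What the generator actually drew, per plexus, before adding noise."""

    vessel_mask: Dict[Plexus, np.ndarray]
    skeleton: Dict[Plexus, np.ndarray]
    boundary_t: int
    true_vd_pct: Dict[Plexus, float]
    true_vld_per_mm: Dict[Plexus, float]


def _grow_network(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    n_seeds: int,
    widths: Tuple[int, int],
) -> Tuple[np.ndarray, np.ndarray, List[List[Tuple[int, int]]]]:
    """Grow one plexus: returns (vessel_mask, skeleton, segments)."""
    h, w = spec.shape
    scale = PixelScale.from_fov(spec.fov_mm, w)
    faz_r_px = spec.faz_radius_mm / scale.mm_per_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    segments: List[List[Tuple[int, int]]] = []
    # walker queue: (x, y, angle)
    queue: List[Tuple[float, float, float]] = []
    for _ in range(n_seeds):
        side = rng.integers(4)
        if side == 0:
            x, y, ang = 0.0, float(rng.uniform(0, h - 1)), 0.0
        elif side == 1:
            x, y, ang = float(w - 1), float(rng.uniform(0, h - 1)), math.pi
        elif side == 2:
            x, y, ang = float(rng.uniform(0, w - 1)), 0.0, math.pi / 2
        else:
            x, y, ang = float(rng.uniform(0, w - 1)), float(h - 1), -math.pi / 2
        queue.append((x, y, ang + float(rng.normal(0, 0.4))))

    jitter = math.radians(spec.step_jitter_deg)
    n_spawned = len(queue)
    max_steps = 2 * (h + w)
    while queue:
        x, y, ang = queue.pop()
        path: List[Tuple[int, int]] = []
        for _ in range(max_steps):
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                break
            if math.hypot(xi - cx, yi - cy) < faz_r_px:
                break  # networks stop at the avascular disk
            if not path or path[-1] != (yi, xi):
                path.append((yi, xi))
            if n_spawned < spec.max_walkers and rng.random() < spec.branch_prob:
                queue.append((x, y, ang + float(rng.choice([-1, 1])) * rng.uniform(0.5, 1.2)))
                n_spawned += 1
            ang += float(rng.normal(0.0, jitter))
            x += math.cos(ang)
            y += math.sin(ang)
        if len(path) >= 3:
            segments.append(path)

    seg_widths = [int(rng.integers(widths[0], widths[1] + 1)) for _ in segments]
    vessel, skeleton = _rasterize_segments(spec.shape, segments, seg_widths)
    return vessel, skeleton, segments


def _rasterize_segments(
    shape: Tuple[int, int],
    segments: List[List[Tuple[int, int]]],
    seg_widths: List[int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw centerlines and dilate them to width, one dilation per caliber."""
    skeleton = np.zeros(shape, dtype=bool)
    by_width: Dict[int, np.ndarray] = {}
    for path, width in zip(segments, seg_widths):
        canvas = by_width.setdefault(width, np.zeros(shape, dtype=bool))
        rows, cols = zip(*path)
        canvas[rows, cols] = True
        skeleton[rows, cols] = True
    vessel = np.zeros(shape, dtype=bool)
    for width, canvas in by_width.items():
        vessel |= dilation(canvas, disk(width // 2)) if width > 1 else canvas
    return vessel, skeleton


def _apply_dropout(
    segments: List[List[Tuple[int, int]]],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    widths: Tuple[int, int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Rebuild masks keeping a random subset of segments."""
    n = len(segments)
    n_drop = int(round(spec.dropout_fraction * n))
    keep_idx = sorted(rng.permutation(n)[: n - n_drop])
    kept = [segments[i] for i in keep_idx]
    seg_widths = [int(rng.integers(widths[0], widths[1] + 1)) for _ in kept]
    return _rasterize_segments(spec.shape, kept, seg_widths)


# Per-plexus tweaks: the superficial layer gets a few thick arteriole-like
# trunks on top of its capillaries; deeper layers are capillary-only.
_PLEXUS_PLAN = {
    Plexus.SCP: {"extra_trunks": 6, "trunk_width": (4, 6)},
    Plexus.MCP: {"extra_trunks": 0, "trunk_width": None},
    Plexus.DCP: {"extra_trunks": 0, "trunk_width": None},
}


def generate_angiogram(
    spec: SyntheticSpec,
) -> Tuple[Dict[Plexus, EnFaceImage], GroundTruth]:
    """Generate SCP/MCP/DCP/RETINA slabs plus exact ground truth.

    Deterministic for a fixed ``rng_seed``: every plexus draws from its own
    spawned child generator, so changing one plexus's parameters does not
    perturb the others' draws.
    """
    root = np.random.default_rng(spec.rng_seed)
    children = root.spawn(len(_PLEXUS_PLAN) + 1)
    scale = PixelScale.from_fov(spec.fov_mm, spec.shape[1])
    annulus_mask = make_parafoveal_mask(spec.shape, AnnulusSpec(), scale)
    n_annulus = int(annulus_mask.sum())
    annulus_area = n_annulus * scale.mm_per_px**2

    vessel_masks: Dict[Plexus, np.ndarray] = {}
    skeletons: Dict[Plexus, np.ndarray] = {}
    images: Dict[Plexus, EnFaceImage] = {}
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16

    for (plexus, plan), rng in zip(_PLEXUS_PLAN.items(), children):
        vessel, skel, segments = _grow_network(spec, rng, spec.n_seeds, spec.vessel_width_px)
        if spec.dropout_fraction > 0:
            vessel, skel = _apply_dropout(segments, spec, rng, spec.vessel_width_px)
        if plan["extra_trunks"]:
            trunks, trunk_skel, _ = _grow_network(
                replace(spec, branch_prob=0.0),
                rng,
                plan["extra_trunks"],
                plan["trunk_width"],
            )
            vessel |= trunks
            skel |= trunk_skel
        vessel_masks[plexus] = vessel
        skeletons[plexus] = skel

        n_lo, n_hi = spec.noise_intensity
        v_lo, v_hi = spec.vessel_intensity
        img = rng.integers(n_lo, n_hi + 1, size=spec.shape)
        img[vessel] = rng.integers(v_lo, v_hi + 1, size=int(vessel.sum()))
        images[plexus] = EnFaceImage(
            pixels=img.astype(dtype),
            plexus=plexus,
            fov_mm=spec.fov_mm,
            bit_depth=spec.bit_depth,
        )

    # Full-retina slab: union of the three plexus networks.
    retina_vessel = vessel_masks[Plexus.SCP] | vessel_masks[Plexus.MCP] | vessel_masks[Plexus.DCP]
    retina_skel = skeletons[Plexus.SCP] | skeletons[Plexus.MCP] | skeletons[Plexus.DCP]
    rng = children[-1]
    n_lo, n_hi = spec.noise_intensity
    v_lo, v_hi = spec.vessel_intensity
    img = rng.integers(n_lo, n_hi + 1, size=spec.shape)
    img[retina_vessel] = rng.integers(v_lo, v_hi + 1, size=int(retina_vessel.sum()))
    images[Plexus.RETINA] = EnFaceImage(
        pixels=img.astype(dtype), plexus=Plexus.RETINA, fov_mm=spec.fov_mm, bit_depth=spec.bit_depth
    )
    vessel_masks[Plexus.RETINA] = retina_vessel
    skeletons[Plexus.RETINA] = retina_skel

    true_vd = {
        p: 100.0 * int((m & annulus_mask).sum()) / n_annulus
        for p, m in vessel_masks.items()
    }
    true_vld = {
        p: int((s & annulus_mask).sum()) * scale.mm_per_px / annulus_area
        for p, s in skeletons.items()
    }
    truth = GroundTruth(
        vessel_mask=vessel_masks,
        skeleton=skeletons,
        boundary_t=int(spec.noise_intensity[1]),
        true_vd_pct=true_vd,
        true_vld_per_mm=true_vld,
    )
    return images, truth


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Default per-stage parameter means, approximating the covariate-adjusted
#: group means of a published five-group severity cohort.
DEFAULT_PARAM_MEANS: Dict[str, Dict[int, float]] = {
    "SCP_VD": {0: 46.38, 1: 45.76, 2: 40.72, 3: 40.12, 4: 35.52},
    "MCP_VD": {0: 46.83, 1: 45.61, 2: 43.05, 3: 41.03, 4: 37.23},
    "DCP_VD": {0: 42.05, 1: 41.15, 2: 38.52, 3: 36.87, 4: 34.16},
    "SCP_VLD": {0: 16.84, 1: 16.92, 2: 14.58, 3: 13.92, 4: 12.39},
    "SCP_AFI": {0: 0.428, 1: 0.428, 2: 0.434, 3: 0.439, 4: 0.445},
    "MCP_AFI": {0: 0.434, 1: 0.435, 2: 0.429, 3: 0.427, 4: 0.423},
    "DCP_AFI": {0: 0.421, 1: 0.423, 2: 0.422, 3: 0.415, 4: 0.410},
    "FAZ": {0: 0.262, 1: 0.212, 2: 0.259, 3: 0.335, 4: 0.390},
}

DEFAULT_PARAM_SDS: Dict[str, Dict[int, float]] = {
    "SCP_VD": {0: 4.93, 1: 4.77, 2: 4.74, 3: 4.84, 4: 4.79},
    "MCP_VD": {0: 4.48, 1: 4.34, 2: 4.31, 3: 4.40, 4: 4.35},
    "DCP_VD": {0: 4.60, 1: 4.45, 2: 4.42, 3: 4.51, 4: 4.46},
    "SCP_VLD": {0: 1.82, 1: 1.76, 2: 1.75, 3: 1.78, 4: 1.76},
    "SCP_AFI": {0: 0.015, 1: 0.014, 2: 0.014, 3: 0.014, 4: 0.013},
    "MCP_AFI": {0: 0.015, 1: 0.014, 2: 0.014, 3: 0.014, 4: 0.013},
    "DCP_AFI": {0: 0.020, 1: 0.019, 2: 0.018, 3: 0.018, 4: 0.021},
    "FAZ": {0: 0.122, 1: 0.120, 2: 0.119, 3: 0.124, 4: 0.119},
}

_DEFAULT_AGE = {0: (46.54, 13.35), 1: (53.04, 13.99), 2: (52.71, 13.76), 3: (56.81, 10.88), 4: (55.94, 11.39)}
_DEFAULT_Q = {0: (8.46, 0.83), 1: (8.17, 0.65), 2: (7.86, 0.85), 3: (7.57, 1.08), 4: (7.67, 0.77)}
_DEFAULT_SSI = {0: (71.0, 6.3), 1: (68.1, 5.7), 2: (66.4, 6.8), 3: (64.1, 8.0), 4: (64.5, 6.3)}


@dataclass(frozen=True)
class CohortSpec:
    """Per-stage sample sizes, parameter distributions, and covariate model.

    Each parameter is drawn as ``mean[stage] + beta_age * (age - age_ref)
    + beta_q * (q_score - q_ref) + Normal(0, sd[stage])``, so nonzero betas
    make age/quality genuine confounders while ``mean[stage]`` remains the
    covariate-adjusted truth at the reference covariate values.
    """

    n_per_group: Dict[int, int] = field(
        default_factory=lambda: {0: 24, 1: 23, 2: 21, 3: 21, 4: 18}
    )
    param_means: Dict[str, Dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PARAM_MEANS.items()}
    )
    param_sds: Dict[str, Dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PARAM_SDS.items()}
    )
    age_dist: Dict[int, Tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_AGE))
    q_dist: Dict[int, Tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_Q))
    ssi_dist: Dict[int, Tuple[float, float]] = field(default_factory=lambda: dict(_DEFAULT_SSI))
    beta_age: float = 0.0
    beta_q: float = 0.0
    age_ref: float = 53.0
    q_ref: float = 7.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ParameterError("group sizes must be positive")
        for pname, sds in self.param_sds.items():
            if any(s < 0 for s in sds.values()):
                raise ParameterError(f"negative sd for {pname}")


def generate_cohort(spec: CohortSpec) -> List[EyeRecord]:
    """Draw one synthetic per-eye cohort table; deterministic per seed."""
    rng = np.random.default_rng(spec.rng_seed)
    records: List[EyeRecord] = []
    for stage in sorted(spec.n_per_group):
        n = spec.n_per_group[stage]
        a_mu, a_sd = spec.age_dist[stage]
        q_mu, q_sd = spec.q_dist[stage]
        s_mu, s_sd = spec.ssi_dist[stage]
        for i in range(n):
            age = float(np.clip(rng.normal(a_mu, a_sd), 25.0, 75.0))
            q = float(np.clip(rng.normal(q_mu, q_sd), 4.0, 10.0))
            ssi = float(np.clip(rng.normal(s_mu, s_sd), 30.0, 90.0))
            sex = "M" if rng.random() < 0.4 else "F"
            params = {}
            for pname, means in spec.param_means.items():
                sd = spec.param_sds.get(pname, {}).get(stage, 0.0)
                value = (
                    means[stage]
                    + spec.beta_age * (age - spec.age_ref)
                    + spec.beta_q * (q - spec.q_ref)
                    + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                )
                params[pname] = float(value)
            records.append(
                EyeRecord(
                    eye_id=f"S{stage}E{i:03d}",
                    stage=stage,
                    age=age,
                    sex=sex,
                    q_score=q,
                    ssi=ssi,
                    params=params,
                )
            )
    return records
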