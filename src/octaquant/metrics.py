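"""Per-eye perfusion metrics from binarized and skeletonized slabs.

All area metrics are evaluated inside the parafoveal annulus; the
avascular-zone area is measured on the full-retina slab, either from a
supplied traced mask or by an assisted flood fill from a seed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk

from .binarize import ThresholdResult, binarize, skeletonize
from .errors import (
    DimensionError,
    FazError,
    FillEscapeError,
    ImplausibleFazError,
    InputError,
    MaskError,
    UndefinedMetricError,
)
from .geometry import AnnulusSpec, PixelScale, make_parafoveal_mask, mask_area_mm2
from .image_io import EnFaceImage, Plexus, normalize_intensity

__all__ = [
    "MetricSet",
    "vessel_density",
    "vessel_length_density",
    "adjusted_flow_index",
    "faz_area",
    "compute_metricset",
]

#: Areas above this are rejected as implausible avascular zones (mm^2).
DEFAULT_MAX_FAZ_MM2 = 2.0

#: Structuring-element radius for the assisted fill's morphological closing.
DEFAULT_CLOSING_RADIUS_PX = 2


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")


def vessel_density(binary: np.ndarray, mask: np.ndarray) -> float:
    """Percentage of the masked area occupied by vessel pixels."""
    binary = np.asarray(binary, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(binary, mask)
    n_mask = int(mask.sum())
    if n_mask == 0:
        raise MaskError("vessel density undefined on an empty mask")
    return 100.0 * int((binary & mask).sum()) / n_mask


def vessel_length_density(
    skeleton: np.ndarray, mask: np.ndarray, scale: PixelScale
) -> float:
    """Skeletonized vessel length per masked area, in 1/mm.

    Length is the skeleton pixel count times the pixel pitch (no diagonal
    correction), divided by the physical mask area.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(skeleton, mask)
    area = mask_area_mm2(mask, scale)
    if area == 0.0:
        raise MaskError("vessel length density undefined on an empty mask")
    length_mm = int((skeleton & mask).sum()) * scale.mm_per_px
    return length_mm / area


def adjusted_flow_index(img: EnFaceImage, mask: np.ndarray, t: int) -> float:
    """Mean normalized intensity of masked pixels at or above threshold t."""
    mask = np.asarray(mask, dtype=bool)
    _check_shapes(img.pixels, mask)
    sel = mask & (img.pixels >= t)
    if not sel.any():
        raise UndefinedMetricError(
            f"no pixels at or above threshold {t} within the mask"
        )
    return float(normalize_intensity(img)[sel].mean())


def faz_area(
    retina_bin: np.ndarray,
    scale: PixelScale,
    faz_mask: Optional[np.ndarray] = None,
    seed_px: Optional[Tuple[int, int]] = None,
    closing_radius_px: int = DEFAULT_CLOSING_RADIUS_PX,
    max_area_mm2: float = DEFAULT_MAX_FAZ_MM2,
) -> float:
    """Avascular-zone area in mm^2.

    With ``faz_mask`` supplied (the traced-mask route), the area is simply
    its foreground count times the pixel area.  Otherwise ``seed_px`` (an
    ``(x, y)`` point inside the avascular zone) starts an assisted fill:
    the binarized full-retina slab is morphologically closed to seal
    capillary gaps, and the connected background component containing the
    seed is measured.  A fill that reaches the image border means the zone
    is not enclosed and raises :class:`FillEscapeError`; an area above
    ``max_area_mm2`` raises :class:`ImplausibleFazError`.
    """
    if faz_mask is not None:
        area = mask_area_mm2(faz_mask, scale)
    elif seed_px is not None:
        retina_bin = np.asarray(retina_bin, dtype=bool)
        closed = closing(retina_bin, disk(closing_radius_px)) if closing_radius_px > 0 else retina_bin
        background = ~closed
        x, y = seed_px
        h, w = background.shape
        if not (0 <= x < w and 0 <= y < h):
            raise FazError(f"seed point ({x}, {y}) outside image {background.shape}")
        if not background[y, x]:
            raise FazError(f"seed point ({x}, {y}) is not on background")
        labels, _ = ndimage.label(background)  # 4-connectivity for background
        comp = labels == labels[y, x]
        border = np.zeros_like(comp)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        if (comp & border).any():
            raise FillEscapeError("assisted fill reached the image border")
        area = mask_area_mm2(comp, scale)
    else:
        raise FazError("either a traced mask or a seed point is required")
    if area > max_area_mm2:
        raise ImplausibleFazError(
            f"area {area:.3f} mm^2 exceeds sanity bound {max_area_mm2} mm^2"
        )
    return area


@dataclass
class MetricSet:
    """Per-eye perfusion parameters plus the threshold that produced them."""

    vd_pct: Dict[Plexus, float] = field(default_factory=dict)
    vld_per_mm: Dict[Plexus, float] = field(default_factory=dict)
    afi: Dict[Plexus, float] = field(default_factory=dict)
    faz_mm2: Optional[float] = None
    threshold_used: int = 0

    def as_row(self) -> Dict[str, float]:
        """Flatten to the per-eye CSV column naming (SCP_VD, ..., THRESHOLD)."""
        row: Dict[str, float] = {}
        for p, v in self.vd_pct.items():
            row[f"{p.value}_VD"] = v
        for p, v in self.vld_per_mm.items():
            row[f"{p.value}_VLD"] = v
        for p, v in self.afi.items():
            row[f"{p.value}_AFI"] = v
        if self.faz_mm2 is not None:
            row["FAZ"] = self.faz_mm2
        row["THRESHOLD"] = self.threshold_used
        return row


def compute_metricset(
    images: Dict[Plexus, EnFaceImage],
    result: ThresholdResult,
    annulus: Optional[AnnulusSpec] = None,
    faz_mask: Optional[np.ndarray] = None,
    faz_seed: Optional[Tuple[int, int]] = None,
    compute_vld_for: Tuple[Plexus, ...] = (Plexus.SCP, Plexus.MCP, Plexus.DCP),
) -> MetricSet:
    """Compute all parameters for one eye at the single derived threshold.

    Requires the SCP, MCP and DCP slabs; the full-retina slab is needed
    only when an avascular-zone measurement is requested (mask or seed).
    """
    annulus = annulus or AnnulusSpec()
    for p in (Plexus.SCP, Plexus.MCP, Plexus.DCP):
        if p not in images:
            raise InputError(f"missing required plexus slab: {p.value}")
    want_faz = faz_mask is not None or faz_seed is not None
    if want_faz and Plexus.RETINA not in images:
        raise InputError("missing required plexus slab: RETINA (needed for FAZ)")

    t = result.threshold
    ms = MetricSet(threshold_used=t)
    for p in (Plexus.SCP, Plexus.MCP, Plexus.DCP):
        img = images[p]
        scale = PixelScale.from_fov(img.fov_mm, img.width)
        mask = make_parafoveal_mask(img.pixels.shape, annulus, scale)
        binary = binarize(img, t)
        ms.vd_pct[p] = vessel_density(binary, mask)
        ms.afi[p] = adjusted_flow_index(img, mask, t)
        if p in compute_vld_for:
            ms.vld_per_mm[p] = vessel_length_density(skeletonize(binary), mask, scale)

    if want_faz:
        retina = images[Plexus.RETINA]
        scale = PixelScale.from_fov(retina.fov_mm, retina.width)
        ms.faz_mm2 = faz_area(
            binarize(retina, t), scale, faz_mask=faz_mask, seed_px=faz_seed
        )
    return ms
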