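"""Parafoveal annulus construction and pixel/physical unit conversion.

Convention: row-major grids, 0-based indices, origin at the top-left.  The
geometric image centre is ((W-1)/2, (H-1)/2) in pixel units.  A pixel
belongs to a region iff its centre point does (no partial-coverage
weighting); ring membership is half-open, inner radius inclusive and outer
radius exclusive, so concentric rings tile the plane without overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import GeometryError

__all__ = ["AnnulusSpec", "PixelScale", "make_parafoveal_mask", "mask_area_mm2"]


@dataclass(frozen=True)
class AnnulusSpec:
    """Analysis annulus: outer/inner ring diameters in mm, optional centre.

    Defaults give the parafoveal ring (outer diameter 3 mm, inner 1 mm)
    centred on the scan centre.
    """

    outer_diameter_mm: float = 3.0
    inner_diameter_mm: float = 1.0
    center_px: Optional[Tuple[float, float]] = None  # (x, y); None = image centre

    def __post_init__(self) -> None:
        if not (0 <= self.inner_diameter_mm < self.outer_diameter_mm):
            raise GeometryError(
                "need 0 <= inner < outer diameter, got "
                f"{self.inner_diameter_mm} / {self.outer_diameter_mm}"
            )


@dataclass(frozen=True)
class PixelScale:
    """Physical pitch of one pixel in mm."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if self.mm_per_px <= 0:
            raise GeometryError(f"mm_per_px must be positive, got {self.mm_per_px}")

    @classmethod
    def from_fov(cls, fov_mm: float, width_px: int) -> "PixelScale":
        return cls(mm_per_px=fov_mm / width_px)


def make_parafoveal_mask(
    shape: Tuple[int, int], spec: AnnulusSpec, scale: PixelScale
) -> np.ndarray:
    """Boolean mask of pixels whose centre lies in [inner_r, outer_r) mm.

    Raises :class:`GeometryError` if the annulus centre is outside the
    image or the outer ring does not fit within the grid (a degenerate
    outer ring covering the whole field is allowed explicitly by passing
    an outer diameter at least the field diagonal).
    """
    h, w = shape
    if spec.center_px is None:
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    else:
        cx, cy = spec.center_px
    if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
        raise GeometryError(f"centre ({cx}, {cy}) outside image bounds {shape}")

    outer_r_mm = spec.outer_diameter_mm / 2.0
    inner_r_mm = spec.inner_diameter_mm / 2.0
    outer_r_px = outer_r_mm / scale.mm_per_px

    # Outer ring must fit unless it deliberately swallows the whole field.
    half_diag = float(np.hypot((w - 1) / 2.0, (h - 1) / 2.0))
    fits = (
        cx - outer_r_px >= -0.5
        and cy - outer_r_px >= -0.5
        and cx + outer_r_px <= w - 0.5
        and cy + outer_r_px <= h - 0.5
    )
    if not fits and outer_r_px < half_diag:
        raise GeometryError(
            f"outer radius {outer_r_px:.1f}px exceeds image bounds {shape}"
        )

    yy, xx = np.mgrid[0:h, 0:w]
    d_mm = np.hypot(xx - cx, yy - cy) * scale.mm_per_px
    return (d_mm >= inner_r_mm) & (d_mm < outer_r_mm)


def mask_area_mm2(mask: np.ndarray, scale: PixelScale) -> float:
    """Physical area of a mask: foreground pixel count times pixel area."""
    mask = np.asarray(mask, dtype=bool)
    return float(mask.sum()) * scale.mm_per_px**2
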