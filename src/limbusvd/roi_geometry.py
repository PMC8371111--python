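"""Limbal annulus and quadrant-sector regions of interest.

Coordinate convention (the single source of truth for the whole package):

* Images are indexed ``[row, col]`` with row 0 at the **top**; "superior"
  limbus therefore corresponds to small row indices.
* Angles are measured in a mathematical y-up frame: for a pixel at
  ``(row, col)`` and a limbus center ``(cx, cy)`` (in pixel units, x = col,
  y = row), the angle is ``atan2(cy - row, col - cx)`` mapped to
  ``[0, 360)`` degrees, i.e. counterclockwise from the +x image direction
  with "up" toward the top of the image.
* Laterality resolves the nasal/temporal axis: in a right eye (OD) image
  the +x direction points temporally, in a left eye (OS) image it points
  nasally.  Superior is +y for both.

Quadrant intervals (half-open, degrees counterclockwise from +x):

========  ============  ============
interval  OD            OS
========  ============  ============
[0, 90)   ST            SN
[90,180)  SN            ST
[180,270) IN            IT
[270,360) IT            IN
========  ============  ============

All radial and angular boundaries are half-open so that no pixel ever
belongs to two ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

QUADRANTS = ("SN", "ST", "IN", "IT")
LATERALITIES = ("OD", "OS")

#: quadrant label for each 90-degree interval, keyed by laterality;
#: index i covers [90*i, 90*(i+1)) degrees.
_SECTOR_ORDER = {
    "OD": ("ST", "SN", "IN", "IT"),
    "OS": ("SN", "ST", "IT", "IN"),
}


class EmptyROIWarning(UserWarning):
    """A sector ROI has no usable pixels after exclusion."""


@dataclass(frozen=True)
class LimbusAnnotation:
    """Manual limbus delineation: center in pixels, annulus radii in mm.

    Parameters
    ----------
    cx, cy:
        Limbus center in pixel coordinates (x = column, y = row).
    r_in_mm, r_out_mm:
        Inner and outer radius of the perilimbal annulus, in millimetres.
    """

    cx: float
    cy: float
    r_in_mm: float
    r_out_mm: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_in_mm < self.r_out_mm:
            raise ValueError(
                f"require 0 <= r_in < r_out, got ({self.r_in_mm}, {self.r_out_mm})"
            )

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy,
                "r_in_mm": self.r_in_mm, "r_out_mm": self.r_out_mm}

    @classmethod
    def from_dict(cls, d: dict) -> "LimbusAnnotation":
        return cls(cx=d["cx"], cy=d["cy"],
                   r_in_mm=d["r_in_mm"], r_out_mm=d["r_out_mm"])


@dataclass(frozen=True)
class SectorROI:
    """One limbal quadrant: annulus ∩ angular sector ∩ ¬exclusion."""

    quadrant: str
    theta0: float
    theta1: float
    mask: np.ndarray

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def pixel_radii_mm(shape: tuple[int, int], annotation: LimbusAnnotation,
                   pixel_spacing_mm: float) -> np.ndarray:
    """Distance of every pixel center from the limbus center, in mm."""
    rows, cols = np.indices(shape)
    dx = cols - annotation.cx
    dy = annotation.cy - rows  # y-up
    return np.hypot(dx, dy) * pixel_spacing_mm


def pixel_angles_deg(shape: tuple[int, int], annotation: LimbusAnnotation) -> np.ndarray:
    """Angle of every pixel center about the limbus center, degrees in [0, 360)."""
    rows, cols = np.indices(shape)
    dx = cols - annotation.cx
    dy = annotation.cy - rows  # y-up
    theta = np.degrees(np.arctan2(dy, dx))
    return np.mod(theta, 360.0)


def annulus_mask(annotation: LimbusAnnotation, image_shape: tuple[int, int],
                 pixel_spacing_mm: float) -> np.ndarray:
    """Boolean mask of the perilimbal annulus: r_in <= r < r_out (mm).

    Raises
    ------
    ValueError
        If the outer circle does not fit inside the image.
    """
    h, w = image_shape
    r_out_px = annotation.r_out_mm / pixel_spacing_mm
    if (annotation.cx - r_out_px < -0.5 or annotation.cx + r_out_px > w - 0.5
            or annotation.cy - r_out_px < -0.5 or annotation.cy + r_out_px > h - 0.5):
        raise ValueError(
            f"annulus (r_out={annotation.r_out_mm} mm = {r_out_px:.1f} px) "
            f"extends outside the {image_shape} field"
        )
    r = pixel_radii_mm(image_shape, annotation, pixel_spacing_mm)
    return (r >= annotation.r_in_mm) & (r < annotation.r_out_mm)


def quadrant_sectors(laterality: str) -> dict[str, tuple[float, float]]:
    """Angular interval [theta0, theta1) in degrees for each quadrant label.

    Raises
    ------
    ValueError
        If laterality is not 'OD' or 'OS'.
    """
    if laterality not in _SECTOR_ORDER:
        raise ValueError(f"unknown laterality {laterality!r}; expected OD or OS")
    order = _SECTOR_ORDER[laterality]
    return {label: (90.0 * i, 90.0 * (i + 1)) for i, label in enumerate(order)}


def quadrant_of_angle(theta_deg: float, laterality: str) -> str:
    """Quadrant label containing an angle (degrees, any real number)."""
    order = _SECTOR_ORDER[laterality] if laterality in _SECTOR_ORDER else None
    if order is None:
        raise ValueError(f"unknown laterality {laterality!r}; expected OD or OS")
    idx = int(np.mod(theta_deg, 360.0) // 90)
    return order[idx]


def sector_mask(annotation: LimbusAnnotation, image_shape: tuple[int, int],
                theta0: float, theta1: float) -> np.ndarray:
    """Boolean wedge mask for angles in [theta0, theta1) degrees (mod 360)."""
    theta = pixel_angles_deg(image_shape, annotation)
    t0 = np.mod(theta0, 360.0)
    t1 = theta1 if theta1 == 360.0 else np.mod(theta1, 360.0)
    if t0 < t1:
        return (theta >= t0) & (theta < t1)
    # wraps through 0
    return (theta >= t0) | (theta < t1)


def make_roi(annotation: LimbusAnnotation, image_shape: tuple[int, int],
             pixel_spacing_mm: float, laterality: str, quadrant: str,
             exclusion_mask: np.ndarray | None = None) -> SectorROI:
    """Build the pixel ROI for one limbal quadrant.

    The mask is annulus ∩ sector ∩ ¬exclusion.  An ROI left empty by the
    exclusion mask is returned with an :class:`EmptyROIWarning` rather than
    failing, so callers can decide how to treat a fully occluded quadrant.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}; expected one of {QUADRANTS}")
    theta0, theta1 = quadrant_sectors(laterality)[quadrant]
    mask = annulus_mask(annotation, image_shape, pixel_spacing_mm)
    mask &= sector_mask(annotation, image_shape, theta0, theta1)
    if exclusion_mask is not None:
        if exclusion_mask.shape != tuple(image_shape):
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} != image {image_shape}"
            )
        mask &= ~exclusion_mask.astype(bool)
    if not mask.any():
        warnings.warn(
            f"ROI for quadrant {quadrant} is empty after exclusion",
            EmptyROIWarning, stacklevel=2,
        )
    return SectorROI(quadrant=quadrant, theta0=theta0, theta1=theta1, mask=mask)


def all_quadrant_rois(annotation: LimbusAnnotation, image_shape: tuple[int, int],
                      pixel_spacing_mm: float, laterality: str,
                      exclusion_mask: np.ndarray | None = None) -> dict[str, SectorROI]:
    """ROIs for all four quadrants; masks are pairwise disjoint and tile the annulus."""
    return {q: make_roi(annotation, image_shape, pixel_spacing_mm, laterality, q,
                        exclusion_mask)
            for q in QUADRANTS}
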