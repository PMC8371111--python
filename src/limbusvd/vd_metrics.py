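"""Vessel density, angular ischemia extent, and the six-level limbal grade.

Vessel density (VD) is the percentage of vessel-classified pixels within a
region of interest of the binarized en-face image.  The denominator is the
ROI pixel count, which makes the "entire area" of the analysed region
explicit.  Ischemia extent is the percentage of the limbal circumference
whose angular VD falls below a fraction of a reference VD (by default the
same eye's baseline), and is mapped onto grades I-VI:

====== ===================
grade  % circumference ischemic
====== ===================
I      0
II     > 0 and < 25
III    >= 25 and < 50
IV     >= 50 and < 75
V      >= 75 and < 100
VI     100
====== ===================

Boundaries are exact: 25, 50 and 75 belong to the higher grade; 0 and 100
are the extreme grades themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from limbusvd.roi_geometry import (
    LimbusAnnotation,
    SectorROI,
    annulus_mask,
    pixel_angles_deg,
)
from limbusvd.vessel_segmentation import BinaryVesselMap

TIMEPOINTS = ("baseline", "day1", "day3", "week1", "month1")
GRADES = ("I", "II", "III", "IV", "V", "VI")

#: (grade, inclusive lower bound, exclusive upper bound) of ischemia %.
#: The two point intervals {0} and {100} are handled explicitly.
_GRADE_INTERVALS = (
    ("I", 0.0, 0.0),
    ("II", 0.0, 25.0),
    ("III", 25.0, 50.0),
    ("IV", 50.0, 75.0),
    ("V", 75.0, 100.0),
    ("VI", 100.0, 100.0),
)


@dataclass(frozen=True)
class VDRecord:
    """One (eye, quadrant, timepoint) vessel-density measurement."""

    eye_id: str
    laterality: str
    quadrant: str
    timepoint: str
    group: str  # "injury" | "control"
    vd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vd <= 100.0:
            raise ValueError(f"vd must be in [0, 100], got {self.vd}")


@dataclass
class AngularProfile:
    """Per-angular-bin VD around the limbal annulus.

    ``vd`` holds NaN for bins flagged missing (no unexcluded pixels);
    ``bin_area`` is the number of valid pixels per bin.
    """

    bin_width: float
    vd: np.ndarray
    bin_area: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.vd.size

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.vd)


@dataclass(frozen=True)
class GradeResult:
    grade: str
    ischemia_pct: float
    interval: tuple[float, float]


def vessel_density(vessel_map: BinaryVesselMap | np.ndarray, roi: SectorROI) -> float:
    """VD% = 100 x (vessel pixels within ROI) / (ROI pixels).

    Raises
    ------
    ValueError
        If the ROI has no pixels — an occluded quadrant has no defined VD
        and must not silently read as 0%.
    """
    mask = vessel_map.mask if isinstance(vessel_map, BinaryVesselMap) else np.asarray(vessel_map)
    mask = mask.astype(bool)
    n_roi = roi.n_pixels
    if n_roi == 0:
        raise ValueError(f"ROI for quadrant {roi.quadrant} is empty; VD undefined")
    if mask.shape != roi.mask.shape:
        raise ValueError(f"mask shape {mask.shape} != ROI shape {roi.mask.shape}")
    return 100.0 * int(mask[roi.mask].sum()) / n_roi


def angular_vd_profile(vessel_map: BinaryVesselMap | np.ndarray,
                       annotation: LimbusAnnotation,
                       pixel_spacing_mm: float,
                       bin_width: float = 1.0,
                       exclusion_mask: np.ndarray | None = None) -> AngularProfile:
    """VD per angular bin of the annulus.

    Bins partition [0, 360); ``bin_width`` must divide 360.  The
    area-weighted mean of bin VDs equals the whole-annulus VD exactly.
    """
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError(f"bin_width must divide 360, got {bin_width}")
    mask = vessel_map.mask if isinstance(vessel_map, BinaryVesselMap) else np.asarray(vessel_map)
    mask = mask.astype(bool)
    n_bins = int(round(360.0 / bin_width))

    valid = annulus_mask(annotation, mask.shape, pixel_spacing_mm)
    if exclusion_mask is not None:
        valid &= ~np.asarray(exclusion_mask).astype(bool)

    theta = pixel_angles_deg(mask.shape, annotation)
    bin_idx = np.minimum((theta[valid] / bin_width).astype(int), n_bins - 1)
    area = np.bincount(bin_idx, minlength=n_bins)
    vessels = np.bincount(bin_idx, weights=mask[valid].astype(float), minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        vd = np.where(area > 0, 100.0 * vessels / np.maximum(area, 1), np.nan)
    return AngularProfile(bin_width=bin_width, vd=vd, bin_area=area)


def ischemia_extent(profile: AngularProfile, reference: float | np.ndarray,
                    drop_threshold_frac: float = 0.5) -> float:
    """Percent of the limbal circumference with VD below the ischemia cut.

    A bin is ischemic iff ``bin_vd < drop_threshold_frac * reference``;
    the reference is a scalar (e.g. the eye's baseline whole-annulus VD)
    or a per-bin array.  Missing bins are excluded from both counts.
    """
    ref = np.broadcast_to(np.asarray(reference, dtype=float), profile.vd.shape)
    if np.any(ref[~profile.missing] <= 0):
        raise ValueError("reference VD must be positive")
    valid = ~profile.missing
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all angular bins are missing; ischemia extent undefined")
    ischemic = valid & (profile.vd < drop_threshold_frac * ref)
    return 100.0 * int(ischemic.sum()) / n_valid


def grade_from_ischemia(ischemia_pct: float) -> GradeResult:
    """Map ischemia extent onto the six-level limbal-involvement grade."""
    if not 0.0 <= ischemia_pct <= 100.0:
        raise ValueError(f"ischemia_pct must be in [0, 100], got {ischemia_pct}")
    if ischemia_pct == 0.0:
        return GradeResult("I", ischemia_pct, (0.0, 0.0))
    if ischemia_pct == 100.0:
        return GradeResult("VI", ischemia_pct, (100.0, 100.0))
    for grade, lo, hi in _GRADE_INTERVALS[1:-1]:
        if lo <= ischemia_pct < hi:
            return GradeResult(grade, ischemia_pct, (lo, hi))
    raise AssertionError("unreachable")  # pragma: no cover


def eye_vd_sum(records: list[VDRecord]) -> float:
    """Sum of the four quadrant VDs of one eye at one timepoint.

    This is the eye-level response used when relating VD to the number of
    injured quadrants.

    Raises
    ------
    ValueError
        If any quadrant is missing or duplicated, naming the quadrants.
    """
    from limbusvd.roi_geometry import QUADRANTS

    present = {}
    for rec in records:
        if rec.quadrant in present:
            raise ValueError(f"duplicate quadrant {rec.quadrant}")
        present[rec.quadrant] = rec.vd
    missing = [q for q in QUADRANTS if q not in present]
    if missing:
        raise ValueError(f"missing quadrant(s): {', '.join(missing)}")
    return float(sum(present.values()))
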