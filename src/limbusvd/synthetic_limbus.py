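"""Synthetic limbal-vasculature phantom with exact per-quadrant ground truth.

The phantom draws a stylized whole-eye limbus: a circular perilimbal
annulus crossed by branching arcade vessels, rendered as quadratic Bezier
centerlines with a Gaussian cross-profile.  A ground-truth pixel is any
pixel whose tube profile reaches at least half of the profile maximum, so
the true vessel density (VD) of a quadrant is an exact pixel count, not an
estimate.  Images are corrupted by multiplicative Gamma speckle followed
by additive Gaussian noise, emulating the speckle-dominated character of
OCT angiography en-face frames.

Injury phases emulate an acute alkali burn: per-segment vessel dropout in
the injured angular sectors (acute phase), progressive recovery, and — at
one month — reparative neovascular ingrowth that can push VD above its
pre-injury level.

Vessels of each quadrant are confined to that quadrant's 90-degree wedge,
which makes the four quadrants' ground truths independent; calibration of
one quadrant to a target VD (bisection over an ordered segment pool) can
therefore proceed quadrant by quadrant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from limbusvd.roi_geometry import (
    QUADRANTS,
    LimbusAnnotation,
    all_quadrant_rois,
    pixel_angles_deg,
    pixel_radii_mm,
    quadrant_sectors,
)
from limbusvd.vessel_segmentation import EnfaceImage

PHASES = ("baseline", "day1", "day3", "week1", "month1")

#: default per-segment dropout fraction in injured sectors, by phase.
#: Values sketch the acute-loss / recovery trajectory: near-half loss on
#: day 1, partial recovery by day 3, full recovery by week 1.
PHASE_DROPOUT = {
    "baseline": 0.0,
    "day1": 0.45,
    "day3": 0.15,
    "week1": 0.0,
    "month1": 0.0,
}

_SAMPLE_STEP_PX = 0.4  # centerline sampling step along each tube
_WEDGE_MARGIN_DEG = 5.0  # keeps a family's geometry inside its own wedge
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class CalibrationError(RuntimeError):
    """A requested ground-truth VD cannot be reached by the vessel model."""


@dataclass(frozen=True)
class SceneParams:
    """Geometry, vasculature and noise parameters of one synthetic scene.

    The default field reproduces a 9 mm x 9 mm en-face frame on a 256 px
    grid with the limbus centered in the field; the annulus used for VD
    runs 2.5-3.5 mm from the center.  Vessel widths are full widths at
    half maximum, in pixels.
    """

    image_size: int = 256
    field_mm: float = 9.0
    limbus_center: tuple[float, float] | None = None
    annulus_radii_mm: tuple[float, float] = (2.5, 3.5)
    laterality: str = "OD"
    n_parent_vessels_per_quadrant: int = 2
    branching_depth: int = 2
    vessel_width_range: tuple[float, float] = (1.5, 3.0)
    vessel_intensity: float = 0.75
    speckle_shape: float | None = 4.0
    background_level: float = 0.08
    additive_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        r_in, r_out = self.annulus_radii_mm
        if not 0 < r_in < r_out:
            raise ValueError(f"need 0 < r_in < r_out, got {self.annulus_radii_mm}")
        if r_out / self.pixel_spacing_mm > self.image_size / 2:
            raise ValueError(
                f"outer annulus radius {r_out} mm exceeds half the "
                f"{self.field_mm} mm field"
            )
        if self.vessel_width_range[0] < 1.0:
            raise ValueError("minimum vessel width must be >= 1 px")
        for name in ("vessel_intensity", "background_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (None disables speckle)")
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be >= 0")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")

    @property
    def pixel_spacing_mm(self) -> float:
        return self.field_mm / self.image_size

    @property
    def center(self) -> tuple[float, float]:
        if self.limbus_center is not None:
            return self.limbus_center
        c = (self.image_size - 1) / 2.0
        return (c, c)

    @property
    def annotation(self) -> LimbusAnnotation:
        cx, cy = self.center
        r_in, r_out = self.annulus_radii_mm
        return LimbusAnnotation(cx=cx, cy=cy, r_in_mm=r_in, r_out_mm=r_out)

    def to_dict(self) -> dict:
        return {
            "image_size": self.image_size,
            "field_mm": self.field_mm,
            "limbus_center": list(self.limbus_center) if self.limbus_center else None,
            "annulus_radii_mm": list(self.annulus_radii_mm),
            "laterality": self.laterality,
            "n_parent_vessels_per_quadrant": self.n_parent_vessels_per_quadrant,
            "branching_depth": self.branching_depth,
            "vessel_width_range": list(self.vessel_width_range),
            "vessel_intensity": self.vessel_intensity,
            "speckle_shape": self.speckle_shape,
            "background_level": self.background_level,
            "additive_sigma": self.additive_sigma,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class InjurySpec:
    """Angular extent and phase of a chemical limbal injury.

    ``injured_sectors`` are half-open angular intervals in degrees (the
    package's y-up, counterclockwise-from-+x convention); they must be
    disjoint.  ``dropout_fraction`` defaults to the phase-specific value
    in :data:`PHASE_DROPOUT`.  ``ingrowth_factor`` scales the number of
    neovascular parent vessels added inside injured sectors at month 1.
    """

    injured_sectors: tuple[tuple[float, float], ...] = ()
    phase: str = "baseline"
    dropout_fraction: float | None = None
    ingrowth_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}, got {self.phase!r}")
        ivs = sorted(self.injured_sectors)
        for t0, t1 in ivs:
            if not (0.0 <= t0 < t1 <= 360.0):
                raise ValueError(f"sector ({t0}, {t1}) not within [0, 360)")
        for (a0, a1), (b0, b1) in zip(ivs, ivs[1:]):
            if b0 < a1:
                raise ValueError("injured sectors must be disjoint")
        object.__setattr__(self, "injured_sectors", tuple(tuple(s) for s in ivs))
        if self.dropout_fraction is not None and not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must be in [0, 1]")
        if self.ingrowth_factor < 0:
            raise ValueError("ingrowth_factor must be >= 0")

    @property
    def effective_dropout(self) -> float:
        if self.dropout_fraction is not None:
            return self.dropout_fraction
        return PHASE_DROPOUT[self.phase]

    @classmethod
    def from_quadrants(cls, quadrants, laterality: str, phase: str = "day1",
                       dropout_fraction: float | None = None,
                       ingrowth_factor: float = 1.0) -> "InjurySpec":
        """Build the injured angular sectors from quadrant labels."""
        sectors = quadrant_sectors(laterality)
        ivs = tuple(sectors[q] for q in quadrants)
        return cls(injured_sectors=ivs, phase=phase,
                   dropout_fraction=dropout_fraction,
                   ingrowth_factor=ingrowth_factor)

    def to_dict(self) -> dict:
        return {
            "injured_sectors": [list(s) for s in self.injured_sectors],
            "phase": self.phase,
            "dropout_fraction": self.dropout_fraction,
            "ingrowth_factor": self.ingrowth_factor,
        }


@dataclass
class SyntheticScene:
    """A generated en-face frame with its exact ground truth."""

    image: EnfaceImage
    truth_mask: np.ndarray
    exclusion_mask: np.ndarray
    params: SceneParams
    injury: InjurySpec
    true_vd_by_quadrant: dict[str, float]


# ---------------------------------------------------------------------------
# vessel geometry and rasterization
# ---------------------------------------------------------------------------

class _Segment:
    """One rasterized tube segment with per-sample prefix structure.

    ``idx``/``val`` hold the flat pixel indices and Gaussian profile values
    of all stamps, ordered sample-major so a prefix of samples is a prefix
    of the arrays; ``offsets[m]`` is the entry count of the first m
    samples.  ``tidx``/``toffsets`` are the analogous arrays restricted to
    ground-truth stamps (profile >= 0.5).
    """

    __slots__ = ("idx", "val", "offsets", "tidx", "toffsets",
                 "n_samples", "angle_deg", "quadrant_index")

    def __init__(self, idx, val, offsets, tidx, toffsets, n_samples,
                 angle_deg, quadrant_index):
        self.idx = idx
        self.val = val
        self.offsets = offsets
        self.tidx = tidx
        self.toffsets = toffsets
        self.n_samples = n_samples
        self.angle_deg = angle_deg
        self.quadrant_index = quadrant_index


def _bezier(p0, p1, p2, t):
    u = 1.0 - t
    return ((u * u)[:, None] * p0 + (2.0 * u * t)[:, None] * p1
            + (t * t)[:, None] * p2)


def _arc_uniform_samples(p0, p1, p2):
    t_coarse = np.linspace(0.0, 1.0, 65)
    pts = _bezier(p0, p1, p2, t_coarse)
    d = np.hypot(*np.diff(pts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(d)])
    length = cum[-1]
    n = max(2, int(math.ceil(length / _SAMPLE_STEP_PX)) + 1)
    s = np.linspace(0.0, length, n)
    t = np.interp(s, cum, t_coarse)
    return _bezier(p0, p1, p2, t)


def _rasterize(pts, width_px, quadrant_index, sector_of_pixel, size,
               angle_deg) -> _Segment:
    sigma = width_px / _FWHM
    radius = int(math.ceil(max(2.5 * sigma, width_px / 2 + 1.0)))
    offs = np.arange(-radius, radius + 1)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    ox = ox.ravel()
    oy = oy.ravel()

    ax = np.round(pts[:, 0]).astype(np.int64)
    ay = np.round(pts[:, 1]).astype(np.int64)
    px = ax[:, None] + ox[None, :]
    py = ay[:, None] + oy[None, :]
    dx = px - pts[:, 0:1]
    dy = py - pts[:, 1:2]
    val = np.exp(-(dx * dx + dy * dy) / (2.0 * sigma * sigma))

    inside = (px >= 0) & (px < size) & (py >= 0) & (py < size)
    flat = np.where(inside, py * size + px, 0)
    keep = inside & (val >= 1e-3)
    keep &= sector_of_pixel.ravel()[flat] == quadrant_index

    counts = keep.sum(axis=1)
    idx = flat[keep]
    v = val[keep]
    offsets = np.concatenate([[0], np.cumsum(counts)])

    truth = v >= 0.5
    tcounts_rows = np.zeros(pts.shape[0], dtype=np.int64)
    # recover per-sample truth counts from the row structure of `keep`
    row_of_entry = np.repeat(np.arange(pts.shape[0]), counts)
    np.add.at(tcounts_rows, row_of_entry[truth], 1)
    tidx = idx[truth]
    toffsets = np.concatenate([[0], np.cumsum(tcounts_rows)])

    return _Segment(idx=idx, val=v, offsets=offsets, tidx=tidx,
                    toffsets=toffsets, n_samples=pts.shape[0],
                    angle_deg=angle_deg, quadrant_index=quadrant_index)


def _pol2px(center, r, theta_deg):
    th = math.radians(theta_deg)
    return np.array([center[0] + r * math.cos(th),
                     center[1] - r * math.sin(th)])


def _point_angle(center, p) -> float:
    return float(np.mod(math.degrees(math.atan2(center[1] - p[1],
                                                p[0] - center[0])), 360.0))


class _VesselAtlas:
    """All candidate vessel segments of a scene, grouped by quadrant.

    ``base`` segments form the uninjured vasculature; ``ingrowth``
    families model month-1 neovessels; ``reserve`` segments exist only as
    calibration headroom (extra arcade vessels of the same morphology).
    Geometry depends only on ``params`` (including its seed), never on the
    injury, so a calibrated scene and a plainly generated scene share
    identical vasculature.
    """

    def __init__(self, params: SceneParams):
        self.params = params
        size = params.image_size
        ann = params.annotation
        angles = pixel_angles_deg((size, size), ann)
        self.sector_of_pixel = np.minimum((angles // 90.0).astype(np.int8), 3)
        radii = pixel_radii_mm((size, size), ann, params.pixel_spacing_mm)
        # iris/artifact exclusion: central disc well inside the annulus
        self.exclusion_mask = radii < max(ann.r_in_mm - 0.35, 0.0)

        spacing = params.pixel_spacing_mm
        self._r_in_px = ann.r_in_mm / spacing
        self._r_out_px = ann.r_out_mm / spacing
        self._center = np.array(params.center)

        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
        n_parent = params.n_parent_vessels_per_quadrant
        self.base: list[list[_Segment]] = []
        self.reserve: list[list[_Segment]] = []
        self.ingrowth: list[list[list[_Segment]]] = []
        # all families of a quadrant (base + reserve + ingrowth) share one
        # stratified angular grid, so dense calibrated quadrants stay
        # mostly parallel arcades instead of piling crossings
        for qi in range(4):
            t0 = 90.0 * qi + _WEDGE_MARGIN_DEG
            t1 = 90.0 * (qi + 1) - _WEDGE_MARGIN_DEG
            n_slots = 5 * n_parent
            span = (t1 - t0) / n_slots
            thetas = [t0 + (i + rng.uniform(0.2, 0.8)) * span
                      for i in range(n_slots)]
            base_slots = [5 * i + 2 for i in range(n_parent)]
            res_slots = [5 * i + j for i in range(n_parent) for j in (0, 4)]
            ing_slots = [5 * i + j for i in range(n_parent) for j in (1, 3)]
            self.base.append(
                [s for k in base_slots
                 for s in self._one_family(rng, qi, thetas[k], deep=False)])
            res_fams = [self._one_family(rng, qi, thetas[k], deep=False)
                        for k in res_slots]
            order = rng.permutation(len(res_fams))
            self.reserve.append([res_fams[j] for j in order])
            ing_fams = [self._one_family(rng, qi, thetas[k], deep=True)
                        for k in ing_slots]
            order = rng.permutation(len(ing_fams))
            self.ingrowth.append([ing_fams[j] for j in order])

    # -- geometry -----------------------------------------------------------

    def _one_family(self, rng, qi, theta, deep) -> list[_Segment]:
        p = self.params
        # neovascular fronds are dilated relative to mature arcade vessels
        width = rng.uniform(*p.vessel_width_range) * (1.3 if deep else 1.0)
        pad = 0.3 / p.pixel_spacing_mm
        r_start = self._r_out_px + pad
        r_end = self._r_in_px - (pad * 2.5 if deep else pad)
        j0, j1 = rng.normal(0.0, 2.0, size=2)
        p0 = _pol2px(self._center, r_start, theta + j0)
        p2 = _pol2px(self._center, max(r_end, 2.0), theta + j1)
        mid = 0.5 * (p0 + p2)
        tang = (p2 - p0) / np.linalg.norm(p2 - p0)
        perp = np.array([-tang[1], tang[0]])
        ctrl_sigma = 6.0 if deep else 4.0
        p1 = mid + rng.normal(0.0, ctrl_sigma) * perp

        segs = [self._seg(p0, p1, p2, width, qi)]
        self._branch(rng, segs, p0, p1, p2, width, qi, depth=1)
        return segs

    def _branch(self, rng, segs, p0, p1, p2, width, qi, depth) -> None:
        if depth > self.params.branching_depth:
            return
        for sign in (1.0, -1.0):
            tb = rng.uniform(0.35, 0.75)
            t_arr = np.array([tb, min(tb + 0.01, 1.0)])
            pts = _bezier(p0, p1, p2, t_arr)
            origin = pts[0]
            tang = pts[1] - pts[0]
            norm = np.linalg.norm(tang)
            if norm == 0:
                continue
            tang = tang / norm
            ang = math.radians(rng.uniform(25.0, 55.0)) * sign
            ca, sa = math.cos(ang), math.sin(ang)
            d = np.array([ca * tang[0] - sa * tang[1],
                          sa * tang[0] + ca * tang[1]])
            length = rng.uniform(12.0, 26.0) * (0.85 ** (depth - 1))
            c0 = origin
            c2 = origin + length * d
            perp = np.array([-d[1], d[0]])
            c1 = 0.5 * (c0 + c2) + rng.normal(0.0, 2.5) * perp
            w = max(1.0, width * 0.75)
            segs.append(self._seg(c0, c1, c2, w, qi))
            self._branch(rng, segs, c0, c1, c2, w, qi, depth + 1)

    def _seg(self, p0, p1, p2, width, qi) -> _Segment:
        pts = _arc_uniform_samples(p0, p1, p2)
        mid = pts[pts.shape[0] // 2]
        return _rasterize(pts, width, qi, self.sector_of_pixel,
                          self.params.image_size, _point_angle(self._center, mid))

    # -- selection ----------------------------------------------------------

    def select(self, injury: InjurySpec) -> list[tuple[_Segment, int]]:
        """Segments present under an injury spec, as (segment, n_samples)."""
        rng = np.random.default_rng(
            np.random.SeedSequence([self.params.seed, 1]))
        included: list[_Segment] = []
        all_base = [s for q in self.base for s in q]
        removed: set[int] = set()
        frac = injury.effective_dropout
        for t0, t1 in injury.injured_sectors:
            eligible = [i for i, s in enumerate(all_base)
                        if t0 <= s.angle_deg < t1]
            order = rng.permutation(len(eligible))
            n_remove = int(round(frac * len(eligible)))
            removed.update(eligible[j] for j in order[:n_remove])
        included = [s for i, s in enumerate(all_base) if i not in removed]

        if injury.phase == "month1":
            n_parent = self.params.n_parent_vessels_per_quadrant
            for t0, t1 in injury.injured_sectors:
                fams = [f for q in self.ingrowth for f in q
                        if f and t0 <= f[0].angle_deg < t1]
                span = (t1 - t0) / 90.0
                k = min(len(fams),
                        int(round(injury.ingrowth_factor * n_parent * span)))
                for f in fams[:k]:
                    included.extend(f)
        return [(s, s.n_samples) for s in included]

    @staticmethod
    def _spread_order(fams: list[list[_Segment]],
                      taken_angles: list[float]) -> list[list[_Segment]]:
        """Greedy ordering: each next family maximizes the angular distance
        to everything already present, so a dense calibrated quadrant fills
        its wedge evenly instead of piling up crossings."""
        remaining = list(fams)
        taken = list(taken_angles)
        out = []
        while remaining:
            best = max(remaining,
                       key=lambda f: min(abs(f[0].angle_deg - a) for a in taken)
                       if taken else 0.0)
            out.append(best)
            taken.append(best[0].angle_deg)
            remaining.remove(best)
        return out

    def candidates(self, qi: int, injury: InjurySpec) -> list[_Segment]:
        """Ordered calibration pool for one quadrant.

        Base arcades come first; the calibration headroom (reserve arcade
        families plus, at month 1, neovascular ingrowth families) follows
        in a max-spread angular order.  At month 1 ingrowth and reserve
        are pooled together; otherwise reserve is preferred and ingrowth
        is only reached when reserve is exhausted.
        """
        pool = list(self.base[qi])
        base_angles = [s.angle_deg for s in self.base[qi]]
        ing, res = self.ingrowth[qi], self.reserve[qi]
        if injury.phase == "month1":
            fams = self._spread_order(res + ing, base_angles)
        else:
            fams = self._spread_order(res, base_angles)
            fams += self._spread_order(
                ing, base_angles + [f[0].angle_deg for f in fams])
        for f in fams:
            pool.extend(f)
        return pool


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

def _profile_canvas(size: int, included: list[tuple[_Segment, int]]) -> np.ndarray:
    canvas = np.zeros(size * size, dtype=np.float64)
    for seg, n_samp in included:
        stop = seg.offsets[min(n_samp, seg.n_samples)]
        np.maximum.at(canvas, seg.idx[:stop], seg.val[:stop])
    return canvas.reshape(size, size)


def _assemble(atlas: _VesselAtlas, injury: InjurySpec,
              included: list[tuple[_Segment, int]]) -> SyntheticScene:
    p = atlas.params
    size = p.image_size
    canvas = _profile_canvas(size, included)
    truth = canvas >= 0.5

    clean = np.clip(p.background_level + p.vessel_intensity * canvas, 0.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 2]))
    noisy = clean
    if p.speckle_shape is not None:
        speckle = rng.gamma(shape=p.speckle_shape, scale=1.0 / p.speckle_shape,
                            size=clean.shape)
        noisy = clean * speckle
    if p.additive_sigma > 0:
        noisy = noisy + rng.normal(0.0, p.additive_sigma, size=clean.shape)
    noisy = np.clip(noisy, 0.0, 1.0)

    image = EnfaceImage(pixels=noisy, pixel_spacing_mm=p.pixel_spacing_mm,
                        laterality=p.laterality)
    rois = all_quadrant_rois(p.annotation, (size, size), p.pixel_spacing_mm,
                             p.laterality, atlas.exclusion_mask)
    true_vd = {q: 100.0 * int(truth[roi.mask].sum()) / roi.n_pixels
               for q, roi in rois.items()}
    return SyntheticScene(image=image, truth_mask=truth,
                          exclusion_mask=atlas.exclusion_mask.copy(),
                          params=p, injury=injury,
                          true_vd_by_quadrant=true_vd)


def generate_scene(params: SceneParams, injury: InjurySpec | None = None) -> SyntheticScene:
    """Render one scene; deterministic for fixed (params, injury).

    Vessel segments whose centerline midpoint falls in an injured sector
    are removed (image and ground truth together) at the spec'd dropout
    fraction; the month-1 phase adds neovascular ingrowth families inside
    injured sectors.
    """
    injury = injury if injury is not None else InjurySpec()
    atlas = _VesselAtlas(params)
    return _assemble(atlas, injury, atlas.select(injury))


def recompute_true_vd(scene: SyntheticScene) -> dict[str, float]:
    """Re-derive per-quadrant true VD by direct pixel counting."""
    p = scene.params
    rois = all_quadrant_rois(p.annotation, scene.truth_mask.shape,
                             p.pixel_spacing_mm, p.laterality,
                             scene.exclusion_mask)
    return {q: 100.0 * int(scene.truth_mask[roi.mask].sum()) / roi.n_pixels
            for q, roi in rois.items()}


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _prefix_selection(pool: list[_Segment], s: float) -> list[tuple[_Segment, int]]:
    k = int(math.floor(s))
    out = [(seg, seg.n_samples) for seg in pool[:k]]
    if k < len(pool):
        frac = s - k
        m = int(round(frac * pool[k].n_samples))
        if m > 0:
            out.append((pool[k], m))
    return out


def _truth_count(pool_sel: list[tuple[_Segment, int]], roi_flat: np.ndarray) -> int:
    chunks = []
    for seg, n_samp in pool_sel:
        stop = seg.toffsets[min(n_samp, seg.n_samples)]
        if stop:
            chunks.append(seg.tidx[:stop])
    if not chunks:
        return 0
    uniq = np.unique(np.concatenate(chunks))
    return int(roi_flat[uniq].sum())


def _calibrate_quadrant(atlas: _VesselAtlas, injury: InjurySpec, quadrant: str,
                        target_vd: float, tol: float) -> list[tuple[_Segment, int]]:
    p = atlas.params
    sectors = quadrant_sectors(p.laterality)
    qi = int(sectors[quadrant][0] // 90)
    rois = all_quadrant_rois(p.annotation, (p.image_size, p.image_size),
                             p.pixel_spacing_mm, p.laterality,
                             atlas.exclusion_mask)
    roi = rois[quadrant]
    roi_flat = roi.mask.ravel()
    n_roi = roi.n_pixels
    pool = atlas.candidates(qi, injury)
    n_total = float(len(pool))

    def vd_at(s: float) -> float:
        return 100.0 * _truth_count(_prefix_selection(pool, s), roi_flat) / n_roi

    ceiling = vd_at(n_total)
    if target_vd > ceiling + tol:
        raise CalibrationError(
            f"target VD {target_vd}% for quadrant {quadrant} exceeds the "
            f"vessel-model ceiling {ceiling:.2f}%"
        )
    lo, hi = 0.0, n_total
    v_lo, v_hi = vd_at(0.0), ceiling
    best_s, best_err = 0.0, abs(v_lo - target_vd)
    if abs(v_hi - target_vd) < best_err:
        best_s, best_err = n_total, abs(v_hi - target_vd)
    for _ in range(45):
        if best_err <= tol * 0.5:
            break
        mid = 0.5 * (lo + hi)
        v = vd_at(mid)
        err = abs(v - target_vd)
        if err < best_err:
            best_s, best_err = mid, err
        if v < target_vd:
            lo = mid
        else:
            hi = mid
    if best_err > tol:
        raise CalibrationError(
            f"could not reach VD {target_vd}% +/- {tol} in quadrant "
            f"{quadrant}; best achieved error {best_err:.3f}"
        )
    return _prefix_selection(pool, best_s)


def calibrate_to_target_vd(params: SceneParams, injury: InjurySpec,
                           quadrant: str, target_vd: float,
                           tol: float = 0.2) -> SyntheticScene:
    """Scene whose ground-truth VD in one quadrant hits a target exactly.

    Bisection runs over an ordered pool of candidate segments for that
    quadrant (existing arcade vessels, then — for the month-1 phase —
    neovascular ingrowth, then reserve arcade vessels), recomputing the
    exact ground-truth pixel count at every step.  The other quadrants
    follow the injury spec unchanged.

    Raises
    ------
    CalibrationError
        If the target exceeds the density ceiling of the vessel model or
        cannot be bracketed within ``tol``.
    """
    if not 0.0 <= target_vd <= 100.0:
        raise ValueError(f"target_vd must be in [0, 100], got {target_vd}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    atlas = _VesselAtlas(params)
    cal = _calibrate_quadrant(atlas, injury, quadrant, target_vd, tol)
    sectors = quadrant_sectors(params.laterality)
    qi = int(sectors[quadrant][0] // 90)
    others = [(s, n) for s, n in atlas.select(injury) if s.quadrant_index != qi]
    return _assemble(atlas, injury, others + cal)


def calibrate_scene(params: SceneParams, injury: InjurySpec,
                    targets: dict[str, float], tol: float = 0.2) -> SyntheticScene:
    """Calibrate several quadrants of one scene in a single pass."""
    atlas = _VesselAtlas(params)
    sectors = quadrant_sectors(params.laterality)
    cal_qis = {int(sectors[q][0] // 90) for q in targets}
    included = [(s, n) for s, n in atlas.select(injury)
                if s.quadrant_index not in cal_qis]
    for q, target in targets.items():
        included.extend(_calibrate_quadrant(atlas, injury, q, target, tol))
    return _assemble(atlas, injury, included)


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeDesign:
    eye_id: str
    laterality: str
    injured_quadrants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        bad = [q for q in self.injured_quadrants if q not in QUADRANTS]
        if bad:
            raise ValueError(f"unknown quadrant label(s): {bad}")
        if len(set(self.injured_quadrants)) != len(self.injured_quadrants):
            raise ValueError("duplicate injured quadrant")


@dataclass(frozen=True)
class StudyDesign:
    """Eyes, timepoints and the per-(group, timepoint) VD distributions.

    ``vd_distributions`` maps (group, timepoint) to a (mean, sd) pair in
    VD percent; ground-truth targets are drawn from these normals and
    clamped at 0.
    """

    eyes: tuple[EyeDesign, ...]
    timepoints: tuple[str, ...]
    vd_distributions: dict[tuple[str, str], tuple[float, float]]
    calibration_tol: float = 0.2

    def __post_init__(self) -> None:
        if not self.eyes:
            raise ValueError("design needs at least one eye")
        for tp in self.timepoints:
            if tp not in PHASES:
                raise ValueError(f"unknown timepoint {tp!r}")
        for tp in self.timepoints:
            for group in ("injury", "control"):
                if any(self._needs(group, tp)) and (group, tp) not in self.vd_distributions:
                    raise ValueError(f"missing VD distribution for ({group}, {tp})")

    def _needs(self, group, tp):
        for eye in self.eyes:
            n_inj = len(eye.injured_quadrants)
            yield (n_inj > 0) if group == "injury" else (n_inj < 4)

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    @property
    def n_quadrants(self) -> int:
        return 4 * self.n_eyes

    @property
    def n_injured_quadrants(self) -> int:
        return sum(len(e.injured_quadrants) for e in self.eyes)

    @property
    def n_control_quadrants(self) -> int:
        return self.n_quadrants - self.n_injured_quadrants

    def to_dict(self) -> dict:
        dists: dict[str, dict[str, list[float]]] = {"injury": {}, "control": {}}
        for (group, tp), (m, s) in self.vd_distributions.items():
            dists[group][tp] = [m, s]
        return {
            "eyes": [{"eye_id": e.eye_id, "laterality": e.laterality,
                      "injured_quadrants": list(e.injured_quadrants)}
                     for e in self.eyes],
            "timepoints": list(self.timepoints),
            "vd_distributions": dists,
            "calibration_tol": self.calibration_tol,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StudyDesign":
        eyes = tuple(EyeDesign(e["eye_id"], e["laterality"],
                               tuple(e["injured_quadrants"])) for e in d["eyes"])
        dists = {(group, tp): tuple(ms)
                 for group, per_tp in d["vd_distributions"].items()
                 for tp, ms in per_tp.items()}
        return cls(eyes=eyes, timepoints=tuple(d["timepoints"]),
                   vd_distributions=dists,
                   calibration_tol=d.get("calibration_tol", 0.2))


#: group VD means/SDs (percent) used by the replicate design, per timepoint.
STUDY_VD_DISTRIBUTIONS = {
    ("injury", "baseline"): (6.1, 1.6),
    ("injury", "day1"): (3.3, 2.4),
    ("injury", "day3"): (5.2, 2.5),
    ("injury", "week1"): (7.0, 2.2),
    ("injury", "month1"): (10.1, 4.3),
    ("control", "baseline"): (6.8, 2.1),
    ("control", "day1"): (7.6, 2.3),
    ("control", "day3"): (6.8, 1.3),
    ("control", "week1"): (7.1, 1.5),
    ("control", "month1"): (7.0, 1.2),
}

#: injured-quadrant count per eye in the replicate design (12 eyes,
#: graded severity 0-4; totals 28 injured / 20 control quadrants).
_REPLICATE_INJURY_COUNTS = (0, 0, 1, 1, 2, 2, 3, 3, 4, 4, 4, 4)


def replicate_study_design() -> StudyDesign:
    """The 12-eye study layout: 6 subjects x OD/OS, graded injury extent.

    28 of the 48 quadrants are injured and 20 serve as within-eye
    controls; all five timepoints are imaged, giving 240 quadrant-level
    records.
    """
    eyes = []
    for i, n_inj in enumerate(_REPLICATE_INJURY_COUNTS):
        subject = i // 2 + 1
        lat = "OD" if i % 2 == 0 else "OS"
        eyes.append(EyeDesign(eye_id=f"R{subject}-{lat}", laterality=lat,
                              injured_quadrants=tuple(QUADRANTS[:n_inj])))
    return StudyDesign(eyes=tuple(eyes), timepoints=PHASES,
                       vd_distributions=dict(STUDY_VD_DISTRIBUTIONS))


def _draw_targets(design: StudyDesign, rng) -> list[dict]:
    """Per-record ground-truth VD targets, clamped at 0."""
    rows = []
    for eye in design.eyes:
        for tp in design.timepoints:
            for q in QUADRANTS:
                group = "injury" if q in eye.injured_quadrants else "control"
                mean, sd = design.vd_distributions[(group, tp)]
                vd = max(0.0, float(rng.normal(mean, sd)))
                rows.append({"eye_id": eye.eye_id, "laterality": eye.laterality,
                             "quadrant": q, "timepoint": tp, "group": group,
                             "true_vd": vd})
    return rows


def draw_study_table(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Ground-truth VD table of one simulated study, without rendering.

    One row per (eye, quadrant, timepoint); column order is fixed:
    eye_id, laterality, quadrant, timepoint, group, true_vd.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    return pd.DataFrame(_draw_targets(design, rng),
                        columns=["eye_id", "laterality", "quadrant",
                                 "timepoint", "group", "true_vd"])


def generate_study(design: StudyDesign, seed: int,
                   scene_params: SceneParams | None = None,
                   render: bool = True):
    """Simulate a full study: one scene per (eye, timepoint) plus truth table.

    Per-quadrant ground-truth VD targets are drawn from the design's
    distributions (clamped at 0) and each quadrant is calibrated to its
    target.  Returns ``(scenes, table)``; with ``render=False`` the scenes
    list is empty and the table holds the drawn targets.
    """
    table = draw_study_table(design, seed)
    scenes: list[SyntheticScene] = []
    if not render:
        return scenes, table

    base = scene_params if scene_params is not None else SceneParams()
    achieved = []
    for ei, eye in enumerate(design.eyes):
        for ti, tp in enumerate(design.timepoints):
            sub = table[(table.eye_id == eye.eye_id) & (table.timepoint == tp)]
            targets = dict(zip(sub.quadrant, sub.true_vd))
            scene_seed = int(np.random.SeedSequence(
                [seed, 7, ei, ti]).generate_state(1)[0] % (2 ** 31))
            params = replace(base, laterality=eye.laterality, seed=scene_seed)
            injury = InjurySpec.from_quadrants(eye.injured_quadrants,
                                               eye.laterality, phase=tp)
            scene = calibrate_scene(params, injury, targets,
                                    tol=design.calibration_tol)
            scenes.append(scene)
            for q in QUADRANTS:
                achieved.append((eye.eye_id, tp, q,
                                 scene.true_vd_by_quadrant[q]))
    ach = pd.DataFrame(achieved, columns=["eye_id", "timepoint", "quadrant",
                                          "true_vd_achieved"])
    table = table.merge(ach, on=["eye_id", "timepoint", "quadrant"])
    table["true_vd"] = table.pop("true_vd_achieved")
    return scenes, table


# ---------------------------------------------------------------------------
# scene I/O
# ---------------------------------------------------------------------------

def save_scene(scene: SyntheticScene, outdir, stem: str) -> dict[str, str]:
    """Write image (16-bit TIFF), masks (8-bit PNG) and a JSON sidecar."""
    import tifffile
    from PIL import Image as PILImage
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    img16 = np.round(scene.image.pixels * 65535).astype(np.uint16)
    paths["image"] = str(outdir / f"{stem}.tiff")
    tifffile.imwrite(paths["image"], img16)
    for name, mask in (("truth", scene.truth_mask),
                       ("exclusion", scene.exclusion_mask)):
        p = str(outdir / f"{stem}_{name}.png")
        PILImage.fromarray((mask.astype(np.uint8)) * 255, mode="L").save(p)
        paths[name] = p
    sidecar = {
        "params": scene.params.to_dict(),
        "injury": scene.injury.to_dict(),
        "true_vd_by_quadrant": scene.true_vd_by_quadrant,
    }
    paths["sidecar"] = str(outdir / f"{stem}.json")
    with open(paths["sidecar"], "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    return paths
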