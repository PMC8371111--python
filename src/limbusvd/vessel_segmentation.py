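"""Binary vessel segmentation of en-face OCTA images.

The chain mirrors the standard OCTA quantification recipe: speckle
denoising (median filter, then Gaussian smoothing), multi-scale Frangi
vesselness enhancement, local adaptive (mean-offset) thresholding, and
removal of unconnected noise pixels under an optional manual exclusion
mask.  Foreground (1 / white) always means vessel.

All filters use reflection padding at the borders so that results are
bit-reproducible and orientation-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

DEFAULT_PIXEL_SPACING_MM = 9.0 / 256.0  # 9 mm field sampled at 256 A-scans


@dataclass
class EnfaceImage:
    """A 2-D en-face angiography frame with physical spacing and study labels.

    ``pixels`` is a float array normalized to [0, 1]; ``pixel_spacing_mm``
    defaults to a 9 mm field sampled on a 256-pixel grid (~35.2 um/px).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    eye_id: str = ""
    laterality: str = "OD"
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {self.pixels.shape}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"intensities must lie in [0,1], got [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _check_odd_window(name: str, value: int) -> None:
    if value < 3 or value % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 3, got {value}")


@dataclass
class SegmentationConfig:
    """Parameters of the vessel-segmentation chain.

    Defaults were validated against phantom ground truth so that measured
    vessel density tracks true density across the 2-12% working range: a
    5x5 median with light Gaussian smoothing controls speckle without
    erasing 1.5-3 px vessels, Frangi scales 0.8-2 px bracket the vessel
    half-widths, the threshold window (25 px) exceeds any vessel while
    staying below illumination-gradient wavelengths, and the offset
    balances halo over-segmentation on clean images against fragment
    loss in speckle.
    """

    median_size: int = 5
    gaussian_sigma: float = 0.5
    frangi_scales: tuple[float, ...] = (0.8, 1.2, 1.6, 2.0)
    frangi_beta: float = 0.5
    frangi_c: float | str = "auto"
    threshold_window: int = 25
    threshold_offset: float = 0.06
    min_component_px: int = 10
    bright_vessels: bool = True

    def __post_init__(self) -> None:
        _check_odd_window("median_size", self.median_size)
        _check_odd_window("threshold_window", self.threshold_window)
        if not self.frangi_scales:
            raise ValueError("frangi_scales must be non-empty")
        scales = tuple(float(s) for s in self.frangi_scales)
        if any(s <= 0 for s in scales) or list(scales) != sorted(scales):
            raise ValueError("frangi_scales must be positive and sorted ascending")
        self.frangi_scales = scales
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.frangi_c != "auto" and float(self.frangi_c) <= 0:
            raise ValueError("frangi_c must be positive or 'auto'")

    def to_dict(self) -> dict:
        return {
            "median_size": self.median_size,
            "gaussian_sigma": self.gaussian_sigma,
            "frangi_scales": list(self.frangi_scales),
            "frangi_beta": self.frangi_beta,
            "frangi_c": self.frangi_c,
            "threshold_window": self.threshold_window,
            "threshold_offset": self.threshold_offset,
            "min_component_px": self.min_component_px,
            "bright_vessels": self.bright_vessels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SegmentationConfig":
        d = dict(d)
        if "frangi_scales" in d:
            d["frangi_scales"] = tuple(d["frangi_scales"])
        return cls(**d)


@dataclass
class BinaryVesselMap:
    """Segmented vessel foreground aligned to its source image."""

    mask: np.ndarray
    config: SegmentationConfig
    exclusion_applied: bool = False

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)


def denoise(image: EnfaceImage, median_size: int = 5,
            gaussian_sigma: float = 0.5) -> EnfaceImage:
    """Speckle denoising: median filter first, then Gaussian smoothing.

    Both filters reflect at the borders; the output stays in [0, 1]
    because both are averaging operators (clipped against rounding).
    """
    _check_odd_window("median_size", median_size)
    out = ndimage.median_filter(image.pixels, size=median_size, mode="reflect")
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma, mode="reflect")
    out = np.clip(out, 0.0, 1.0)
    return replace(image, pixels=out)


def _gaussian_derivative_kernels(sigma: float):
    """Sampled Gaussian and its first/second derivatives.

    The sampled second derivative does not sum exactly to zero at small
    sigma (discretization, not truncation); the residual is subtracted so
    a constant image has an exactly zero Hessian — otherwise a multiple
    of the local mean leaks in and breaks the shift invariance of the
    vesselness map.  The first derivative is antisymmetric, hence already
    zero-sum.
    """
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g0 = np.exp(-(x * x) / (2.0 * sigma * sigma))
    g0 /= g0.sum()
    g1 = -x / sigma ** 2 * g0
    g2 = (x * x - sigma ** 2) / sigma ** 4 * g0
    g2 -= g2.mean()
    return g0, g1, g2


def _hessian(image: np.ndarray, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale-normalized Hessian (gamma = 1 => second derivatives x sigma^2)."""
    g0, g1, g2 = _gaussian_derivative_kernels(sigma)

    def sep(img, krow, kcol):
        out = ndimage.correlate1d(img, krow, axis=0, mode="reflect")
        return ndimage.correlate1d(out, kcol, axis=1, mode="reflect")

    s2 = sigma * sigma
    hrr = sep(image, g2, g0) * s2
    hrc = sep(image, g1, g1) * s2
    hcc = sep(image, g0, g2) * s2
    return hrr, hrc, hcc


def _vesselness_single_scale(image: np.ndarray, sigma: float, beta: float,
                             c: float | str, bright: bool) -> np.ndarray:
    hrr, hrc, hcc = _hessian(image, sigma)
    # eigenvalues of [[hrr, hrc], [hrc, hcc]]; ordered |l1| <= |l2|
    half_trace = 0.5 * (hrr + hcc)
    disc = np.sqrt(np.maximum(0.25 * (hrr - hcc) ** 2 + hrc ** 2, 0.0))
    e_lo = half_trace - disc
    e_hi = half_trace + disc
    swap = np.abs(e_lo) > np.abs(e_hi)
    l1 = np.where(swap, e_hi, e_lo)
    l2 = np.where(swap, e_lo, e_hi)

    structureness = np.sqrt(l1 ** 2 + l2 ** 2)
    if c == "auto":
        c_val = 0.5 * float(structureness.max())
        # a (near-)flat image has only rounding-noise curvature; treat as flat
        if c_val <= 1e-10:
            return np.zeros_like(image)
    else:
        c_val = float(c)

    with np.errstate(divide="ignore", invalid="ignore"):
        rb = np.where(l2 != 0, l1 / l2, 0.0)
    response = (np.exp(-(rb ** 2) / (2 * beta ** 2))
                * (1.0 - np.exp(-(structureness ** 2) / (2 * c_val ** 2))))
    # a bright tube has a strongly negative cross-axis curvature
    suppressed = (l2 > 0) if bright else (l2 < 0)
    response = np.where(suppressed | (l2 == 0), 0.0, response)
    return response


def frangi_vesselness(image: EnfaceImage,
                      scales: tuple[float, ...] = (0.8, 1.2, 1.6, 2.0),
                      beta: float = 0.5,
                      c: float | str = "auto",
                      bright_vessels: bool = True) -> np.ndarray:
    """Multi-scale Frangi vesselness map in [0, 1].

    Per scale sigma the image is convolved with gamma-normalized Gaussian
    second derivatives (gamma = 1, i.e. Hessian x sigma^2); with
    eigenvalues |l1| <= |l2| the bright-vessel response is zero where
    l2 > 0 and otherwise

        exp(-R_B^2 / 2 beta^2) * (1 - exp(-S^2 / 2 c^2)),

    with blobness R_B = l1/l2 and structureness S = sqrt(l1^2 + l2^2).
    ``c='auto'`` uses half the maximum S observed at that scale.  The final
    map is the pixelwise maximum over scales.
    """
    if not scales:
        raise ValueError("scales must be non-empty")
    px = np.asarray(image.pixels, dtype=np.float64)
    out = np.zeros_like(px)
    for sigma in scales:
        np.maximum(out, _vesselness_single_scale(px, float(sigma), beta, c,
                                                 bright_vessels), out=out)
    return out


def adaptive_threshold(vmap: np.ndarray, threshold_window: int = 25,
                       threshold_offset: float = 0.06) -> np.ndarray:
    """Mean-offset local thresholding: fg iff value > local mean + offset."""
    _check_odd_window("threshold_window", threshold_window)
    vmap = np.asarray(vmap, dtype=np.float64)
    local_mean = ndimage.uniform_filter(vmap, size=threshold_window, mode="reflect")
    return vmap > local_mean + threshold_offset


def clean_components(binary: np.ndarray, min_component_px: int = 10,
                     exclusion_mask: np.ndarray | None = None,
                     config: SegmentationConfig | None = None) -> BinaryVesselMap:
    """Drop excluded pixels, then remove small 8-connected components.

    Exclusion is applied *before* relabelling, so a component split by the
    exclusion boundary is re-measured on its surviving part only.
    """
    binary = np.asarray(binary).astype(bool)
    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask).astype(bool)
        if exclusion_mask.shape != binary.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} != mask {binary.shape}"
            )
        binary = binary & ~exclusion_mask
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n:
        areas = np.bincount(labels.ravel())
        keep = areas >= min_component_px
        keep[0] = False
        binary = keep[labels]
    cfg = config if config is not None else SegmentationConfig(
        min_component_px=min_component_px)
    return BinaryVesselMap(mask=binary, config=cfg,
                           exclusion_applied=exclusion_mask is not None)


def segment(image: EnfaceImage, config: SegmentationConfig | None = None,
            exclusion_mask: np.ndarray | None = None) -> BinaryVesselMap:
    """Full chain: denoise -> Frangi -> adaptive threshold -> cleanup.

    Deterministic; the exclusion mask is applied only at the final cleanup
    stage, after thresholding.
    """
    cfg = config if config is not None else SegmentationConfig()
    den = denoise(image, cfg.median_size, cfg.gaussian_sigma)
    vmap = frangi_vesselness(den, cfg.frangi_scales, cfg.frangi_beta,
                             cfg.frangi_c, cfg.bright_vessels)
    raw = adaptive_threshold(vmap, cfg.threshold_window, cfg.threshold_offset)
    return clean_components(raw, cfg.min_component_px, exclusion_mask, config=cfg)
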