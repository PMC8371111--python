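"""Segmentation operators against brute-force oracles and invariants."""

import numpy as np
import pytest
from scipy import ndimage

from limbusvd.synthetic_limbus import InjurySpec, SceneParams, generate_scene
from limbusvd.vessel_segmentation import (
    EnfaceImage,
    SegmentationConfig,
    adaptive_threshold,
    clean_components,
    denoise,
    frangi_vesselness,
    segment,
)


def _img(arr, **kw):
    return EnfaceImage(pixels=arr, **kw)


def _reflect_window(arr, r0, c0, size):
    """Brute-force reflected neighborhood (scipy 'reflect' = symmetric)."""
    half = size // 2
    pad = np.pad(arr, half, mode="symmetric")
    return pad[r0:r0 + size, c0:c0 + size]


# ---------------------------------------------------------------------------
# denoise
# ---------------------------------------------------------------------------

class TestDenoise:
    def test_constant_image_unchanged(self):
        out = denoise(_img(np.full((16, 16), 0.4)), 3, 1.0)
        assert np.allclose(out.pixels, 0.4)

    def test_median_removes_isolated_impulse(self):
        arr = np.zeros((16, 16))
        arr[8, 8] = 1.0
        out = denoise(_img(arr), 3, 0.0)  # median only
        assert np.all(out.pixels == 0.0)

    def test_median_matches_bruteforce_neighborhood(self, rng):
        arr = rng.random((16, 16))
        out = ndimage.median_filter(arr, size=3, mode="reflect")
        brute = np.empty_like(arr)
        for r in range(16):
            for c in range(16):
                brute[r, c] = np.median(_reflect_window(arr, r, c, 3))
        assert np.array_equal(out, brute)
        # and the denoise stage uses exactly this median
        assert np.array_equal(denoise(_img(arr), 3, 0.0).pixels, brute)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            denoise(_img(np.zeros((8, 8))), 4, 1.0)


# ---------------------------------------------------------------------------
# Frangi vesselness
# ---------------------------------------------------------------------------

def _hessian_oracle(arr, sigma):
    """Brute-force Hessian: explicit 2-D window correlation per pixel."""
    radius = max(1, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=float)
    g0 = np.exp(-(x * x) / (2 * sigma ** 2))
    g0 /= g0.sum()
    g1 = -x / sigma ** 2 * g0
    g2 = (x * x - sigma ** 2) / sigma ** 4 * g0
    g2 -= g2.mean()
    pad = np.pad(arr, radius, mode="symmetric")
    n = 2 * radius + 1
    kernels = {"rr": np.outer(g2, g0), "rc": np.outer(g1, g1),
               "cc": np.outer(g0, g2)}
    out = {}
    for name, k in kernels.items():
        h = np.empty_like(arr)
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                h[r, c] = np.sum(pad[r:r + n, c:c + n] * k)
        out[name] = h * sigma ** 2
    return out["rr"], out["rc"], out["cc"]


def _frangi_oracle(arr, scales, beta=0.5):
    """Per-pixel eigendecomposition oracle (numpy.linalg.eigh, loops)."""
    out = np.zeros_like(arr)
    for sigma in scales:
        hrr, hrc, hcc = _hessian_oracle(arr, sigma)
        resp = np.zeros_like(arr)
        s_all = np.empty_like(arr)
        lam = np.empty(arr.shape + (2,))
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                H = np.array([[hrr[r, c], hrc[r, c]], [hrc[r, c], hcc[r, c]]])
                w = np.linalg.eigh(H)[0]
                l1, l2 = sorted(w, key=abs)
                lam[r, c] = (l1, l2)
                s_all[r, c] = np.hypot(l1, l2)
        c_val = 0.5 * s_all.max() or 1.0
        for r in range(arr.shape[0]):
            for c in range(arr.shape[1]):
                l1, l2 = lam[r, c]
                if l2 >= 0:
                    continue
                rb = l1 / l2
                resp[r, c] = (np.exp(-rb ** 2 / (2 * beta ** 2))
                              * (1 - np.exp(-s_all[r, c] ** 2 / (2 * c_val ** 2))))
        out = np.maximum(out, resp)
    return out


class TestFrangi:
    def test_constant_image_zero_everywhere(self):
        v = frangi_vesselness(_img(np.full((32, 32), 0.7)))
        assert np.all(v == 0.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        arr = rng.random((32, 32))
        scales = (1.0, 1.5, 2.0)
        ours = frangi_vesselness(_img(arr), scales=scales)
        oracle = _frangi_oracle(arr, scales)
        assert np.allclose(ours, oracle, atol=1e-9, rtol=1e-6)

    def test_gaussian_ridge_peaks_on_centerline(self):
        """Analytic bright ridge: maximal response on the ridge center."""
        sigma_t = 1.5
        cols = np.arange(64)
        ridge = np.exp(-((cols - 31.5) ** 2) / (2 * sigma_t ** 2))
        arr = np.tile(ridge, (64, 1)) * 0.8
        v = frangi_vesselness(_img(arr), scales=(1.0, 1.5, 2.0))
        center_band = v[20:44, 31:33]
        off_ridge = np.concatenate([v[20:44, :26].ravel(), v[20:44, 38:].ravel()])
        assert center_band.min() > off_ridge.max()

    def test_rotational_equivariance(self, rng):
        arr = rng.random((32, 32))
        v = frangi_vesselness(_img(arr))
        v_rot = frangi_vesselness(_img(np.rot90(arr)))
        assert np.allclose(np.rot90(v), v_rot, atol=1e-12)

    def test_intensity_shift_invariance(self, rng):
        arr = rng.random((32, 32)) * 0.5
        v1 = frangi_vesselness(_img(arr))
        v2 = frangi_vesselness(_img(arr + 0.3))
        assert np.allclose(v1, v2, atol=1e-12)

    def test_empty_scales_rejected(self, rng):
        with pytest.raises(ValueError, match="non-empty"):
            frangi_vesselness(_img(rng.random((8, 8))), scales=())


# ---------------------------------------------------------------------------
# adaptive threshold
# ---------------------------------------------------------------------------

class TestAdaptiveThreshold:
    def test_constant_map_positive_offset_all_background(self):
        assert not adaptive_threshold(np.full((16, 16), 0.5), 5, 0.01).any()

    def test_constant_map_negative_offset_all_foreground(self):
        assert adaptive_threshold(np.full((16, 16), 0.5), 5, -0.01).all()

    def test_matches_bruteforce_local_mean(self, rng):
        arr = rng.random((16, 16))
        out = adaptive_threshold(arr, 5, 0.02)
        for r in range(16):
            for c in range(16):
                mean = _reflect_window(arr, r, c, 5).mean()
                assert out[r, c] == (arr[r, c] > mean + 0.02)


# ---------------------------------------------------------------------------
# component cleanup
# ---------------------------------------------------------------------------

def _components_oracle(binary, min_px):
    """Flood-fill (8-connected) oracle for small-object removal."""
    binary = binary.copy()
    seen = np.zeros_like(binary, dtype=bool)
    out = np.zeros_like(binary, dtype=bool)
    for r0 in range(binary.shape[0]):
        for c0 in range(binary.shape[1]):
            if binary[r0, c0] and not seen[r0, c0]:
                stack, comp = [(r0, c0)], []
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    comp.append((r, c))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < binary.shape[0]
                                    and 0 <= cc < binary.shape[1]
                                    and binary[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                if len(comp) >= min_px:
                    for r, c in comp:
                        out[r, c] = True
    return out


class TestCleanComponents:
    def test_small_component_removed(self):
        arr = np.zeros((16, 16), dtype=bool)
        arr[2:4, 2:4] = True  # 4 px
        assert not clean_components(arr, 10).mask.any()

    def test_identity_with_min_one_and_no_exclusion(self, rng):
        arr = rng.random((16, 16)) < 0.3
        assert np.array_equal(clean_components(arr, 1).mask, arr)

    def test_component_split_by_exclusion_remeasured(self):
        """A large component cut by the exclusion boundary is re-labelled."""
        arr = np.zeros((20, 20), dtype=bool)
        arr[10, :] = True  # 20-px line
        excl = np.zeros((20, 20), dtype=bool)
        excl[:, 8:12] = True  # cuts the line into 8-px and 8-px halves
        out = clean_components(arr, min_component_px=10, exclusion_mask=excl)
        assert not out.mask.any()  # both remnants are below min
        out2 = clean_components(arr, min_component_px=8, exclusion_mask=excl)
        assert out2.mask.sum() == 16

    def test_matches_floodfill_oracle(self, rng):
        arr = rng.random((24, 24)) < 0.35
        ours = clean_components(arr, 6).mask
        assert np.array_equal(ours, _components_oracle(arr, 6))

    def test_excluded_pixels_never_foreground(self, rng):
        arr = rng.random((16, 16)) < 0.5
        excl = rng.random((16, 16)) < 0.4
        out = clean_components(arr, 1, excl)
        assert not (out.mask & excl).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            clean_components(np.zeros((8, 8), bool), 1, np.zeros((4, 4), bool))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

class TestSegment:
    def test_all_zero_image_empty_map(self):
        out = segment(_img(np.zeros((64, 64))))
        assert not out.mask.any()

    def test_deterministic(self, default_scene):
        a = segment(default_scene.image)
        b = segment(default_scene.image)
        assert np.array_equal(a.mask, b.mask)

    def test_dice_against_truth_on_clean_scene(self, clean_scene):
        out = segment(clean_scene.image, exclusion_mask=clean_scene.exclusion_mask)
        inter = (out.mask & clean_scene.truth_mask).sum()
        dice = 2 * inter / (out.mask.sum() + clean_scene.truth_mask.sum())
        assert dice >= 0.7

    def test_exclusion_respected_end_to_end(self, default_scene):
        out = segment(default_scene.image,
                      exclusion_mask=default_scene.exclusion_mask)
        assert not (out.mask & default_scene.exclusion_mask).any()
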