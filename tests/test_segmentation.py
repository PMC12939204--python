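"""Grayscale, auto-contrast, isodata threshold, masks and particle analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ribeyegrade as rg
from ribeyegrade.segmentation import BinaryMask, GrayImage, histogram256

from .conftest import constant_image, make_image

# ---------------------------------------------------------------------------
# independent oracles


def sort_based_auto_contrast(pixels: np.ndarray, saturated_fraction: float) -> np.ndarray:
    """Brute-force stretch: sort all pixels, pick cut indices, rescale."""
    flat = np.sort(pixels.ravel())
    k = int(flat.size * saturated_fraction / 2)
    low, high = int(flat[k]), int(flat[flat.size - 1 - k])
    if low == high:
        return pixels.copy()
    out = np.floor((pixels.astype(float) - low) * 255.0 / (high - low) + 0.5)
    return np.clip(out, 0, 255).astype(np.uint8)


def iterate_intermeans(values: list[int]) -> int:
    """Plain-Python intermeans iteration on the raw value list."""
    lo, hi = min(values), max(values)
    t = (lo + hi) // 2
    t = max(lo, min(hi - 1, t))
    seen = set()
    while t not in seen:
        seen.add(t)
        below = [v for v in values if v <= t]
        above = [v for v in values if v > t]
        t = int(np.floor((sum(below) / len(below) + sum(above) / len(above)) / 2 + 0.5))
        t = max(lo, min(hi - 1, t))
    return t


def flood_fill_particles(mask: np.ndarray) -> list[tuple[int, tuple[int, int, int, int]]]:
    """8-connected components by BFS: (area_px, bbox) per component."""
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    out = []
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            stack, px = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                px.append((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            rows = [p[0] for p in px]
            cols = [p[1] for p in px]
            out.append((len(px), (min(cols), min(rows), max(cols), max(rows))))
    return out


# ---------------------------------------------------------------------------


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,mode,expected",
        [
            ((100, 100, 100), "unweighted", 100),
            ((100, 100, 100), "luma", 100),
            ((255, 0, 0), "unweighted", 85),
            ((255, 0, 0), "luma", 76),  # round(0.299 * 255)
            ((0, 255, 0), "luma", 150),  # round(0.587 * 255)
        ],
    )
    def test_single_pixel(self, rgb, mode, expected):
        img = constant_image(2, 2, rgb)
        assert rg.to_grayscale(img, mode=mode).pixels[0, 0] == expected

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            rg.to_grayscale(constant_image(2, 2, (1, 2, 3)), mode="bogus")


class TestAutoContrast:
    def test_constant_image_unchanged(self):
        g = GrayImage(np.full((10, 10), 42, dtype=np.uint8))
        assert (rg.auto_contrast(g).pixels == 42).all()

    def test_pure_linear_stretch(self):
        """Intensities spanning exactly {50..150} map to {0..255} endpoints."""
        g = GrayImage(np.tile(np.arange(50, 151, dtype=np.uint8), (4, 1)))
        out = rg.auto_contrast(g, saturated_fraction=0.0).pixels
        assert out.min() == 0 and out.max() == 255
        assert out[0, 0] == 0 and out[0, -1] == 255

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        ours = rg.auto_contrast(GrayImage(px), saturated_fraction=0.0035).pixels
        assert (ours == sort_based_auto_contrast(px, 0.0035)).all()

    @given(seed=st.integers(0, 10_000), sat=st.floats(0, 0.4))
    @settings(max_examples=60, derandomize=True)
    def test_monotone(self, seed, sat):
        """Auto-contrast never reverses the order of two pixel intensities."""
        rng = np.random.default_rng(seed)
        px = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        out = rg.auto_contrast(GrayImage(px), saturated_fraction=sat).pixels
        order = np.argsort(px.ravel(), kind="stable")
        assert (np.diff(out.ravel()[order].astype(int)) >= 0).all()


class TestIsodataThreshold:
    def test_two_delta_histogram(self):
        h = np.zeros(256, dtype=int)
        h[50] = 100
        h[200] = 100
        assert rg.isodata_threshold(h) == 125

    def test_constant_image_raises(self):
        with pytest.raises(rg.DegenerateHistogramError):
            rg.isodata_threshold(GrayImage(np.full((5, 5), 7, dtype=np.uint8)))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_plain_python_iteration(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.integers(0, 256, 500)
        if len(set(values.tolist())) < 2:
            pytest.skip("degenerate draw")
        ours = rg.isodata_threshold(histogram256(values))
        assert ours == iterate_intermeans(values.tolist())

    def test_two_gaussian_mixture_near_optimal_split(self):
        """Converged threshold sits within +-3 of the misassignment-minimizing scan."""
        rng = np.random.default_rng(42)
        a = np.clip(rng.normal(60, 10, 4000), 0, 255).astype(int)
        b = np.clip(rng.normal(190, 12, 4000), 0, 255).astype(int)
        values = np.concatenate([a, b])
        t = rg.isodata_threshold(histogram256(values))
        # oracle: exhaustive scan over all thresholds, counting known-label
        # errors; the minimum is a plateau, so compare to its nearest point
        errs = np.array([np.count_nonzero(a > s) + np.count_nonzero(b <= s) for s in range(255)])
        optimal = np.flatnonzero(errs == errs.min())
        assert np.abs(optimal - t).min() <= 3

    def test_idempotent_on_binary_image(self):
        """Re-thresholding an already 0/255 image reproduces its binarization."""
        rng = np.random.default_rng(0)
        binary = (rng.random((40, 40)) < 0.4).astype(np.uint8) * 255
        t = rg.isodata_threshold(GrayImage(binary))
        assert ((binary > t) == (binary == 255)).all()


def _ellipse_scene(h, w, center, axes, fg=128, bg=10):
    yy, xx = np.mgrid[0:h, 0:w]
    inside = ((xx - center[0]) / axes[0]) ** 2 + ((yy - center[1]) / axes[1]) ** 2 <= 1
    px = np.full((h, w, 3), bg, dtype=np.uint8)
    px[inside] = fg
    return make_image(px), inside


class TestSegmentRibeye:
    def test_ellipse_on_dark_background(self, cal20):
        img, inside = _ellipse_scene(300, 300, (150, 150), (100, 70))
        ci = rg.CalibratedImage(img, cal20)
        mask = rg.segment_ribeye(ci)
        assert mask.area_px == pytest.approx(inside.sum(), rel=0.02)

    def test_all_background_raises(self, cal20):
        ci = rg.CalibratedImage(constant_image(100, 100, (10, 10, 10)), cal20)
        with pytest.raises(rg.SegmentationError):
            rg.segment_ribeye(ci)

    def test_small_bright_speck_excluded(self, cal20):
        img, inside = _ellipse_scene(300, 300, (120, 150), (80, 60))
        img.pixels[10:16, 280:287] = 200  # ~0.1 cm^2 speck at 20 px/cm
        ci = rg.CalibratedImage(img, cal20)
        mask = rg.segment_ribeye(ci)
        assert not mask.pixels[10:16, 280:287].any()
        assert mask.area_px == pytest.approx(inside.sum(), rel=0.02)

    def test_internal_holes_filled(self, cal20):
        img, inside = _ellipse_scene(200, 200, (100, 100), (70, 50))
        img.pixels[95:105, 95:105] = 10  # dark cavity inside the object
        ci = rg.CalibratedImage(img, cal20)
        mask = rg.segment_ribeye(ci)
        assert mask.pixels[100, 100]


class TestSegmentMarbling:
    def test_known_fat_fraction_recovered(self, ):
        ci, truth = rg.generate_sample(
            rg.SyntheticSpec(seed=11, target_marbling_fraction=0.30)
        )
        ribeye = rg.segment_ribeye(ci)
        marbling = rg.segment_marbling(ci, ribeye)
        recovered = 100.0 * marbling.area_px / ribeye.area_px
        assert recovered == pytest.approx(truth.marbling_pct, abs=3.0)

    def test_zero_fat_gives_empty_mask(self):
        ci, _ = rg.generate_sample(rg.SyntheticSpec(seed=5, target_marbling_fraction=0.0))
        ribeye = rg.segment_ribeye(ci)
        marbling = rg.segment_marbling(ci, ribeye)
        assert marbling.area_px == 0
        assert marbling.warnings

    @pytest.mark.parametrize("seed,frac", [(1, 0.1), (2, 0.3), (3, 0.6)])
    def test_marbling_subset_of_ribeye(self, seed, frac):
        ci, _ = rg.generate_sample(rg.SyntheticSpec(seed=seed, target_marbling_fraction=frac))
        ribeye = rg.segment_ribeye(ci)
        marbling = rg.segment_marbling(ci, ribeye)
        assert not (marbling.pixels & ~ribeye.pixels).any()

    def test_empty_ribeye_raises(self, cal20):
        ci = rg.CalibratedImage(constant_image(20, 20, (50, 50, 50)), cal20)
        with pytest.raises(rg.SegmentationError):
            rg.segment_marbling(ci, BinaryMask(np.zeros((20, 20), bool)))


class TestParticleAnalysis:
    def test_size_filter_semantics(self, cal100):
        # 0.3 cm^2 and 0.7 cm^2 blobs at 100 px/cm: only the second survives
        mask = np.zeros((400, 400), bool)
        mask[10:64, 10:66] = True  # 3024 px^2 ~ 0.30 cm^2
        mask[200:284, 200:284] = True  # 7056 px^2 ~ 0.71 cm^2
        parts = rg.particle_analysis(BinaryMask(mask), cal100)
        assert len(parts) == 1
        assert parts[0].area_cm2 == pytest.approx(0.7056)

    def test_empty_mask(self, cal100):
        assert rg.particle_analysis(BinaryMask(np.zeros((10, 10), bool)), cal100) == []

    def test_total_area_matches_pixel_count(self, cal20):
        rng = np.random.default_rng(3)
        from scipy import ndimage

        mask = ndimage.binary_dilation(rng.random((100, 100)) < 0.05, iterations=3)
        parts = rg.particle_analysis(BinaryMask(mask), cal20, min_size_cm2=0.0)
        assert sum(p.area_px for p in parts) == mask.sum()

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_flood_fill_oracle(self, seed, cal100):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(4, 33)), int(rng.integers(4, 33)))
        mask = rng.random(shape) < rng.uniform(0.2, 0.6)
        parts = rg.particle_analysis(BinaryMask(mask), cal100, min_size_cm2=0.0)
        oracle = flood_fill_particles(mask)
        assert sorted((p.area_px, p.bbox) for p in parts) == sorted(oracle)


class TestCropToMask:
    def _scene(self, cal20):
        img, inside = _ellipse_scene(200, 260, (130, 100), (70, 50))
        return rg.CalibratedImage(img, cal20), BinaryMask(inside)

    def test_bbox_dimensions(self, cal20):
        ci, mask = self._scene(cal20)
        cropped, cmask = rg.crop_to_mask(ci, mask, margin_px=0)
        rows = np.flatnonzero(mask.pixels.any(axis=1))
        cols = np.flatnonzero(mask.pixels.any(axis=0))
        assert cropped.image.pixels.shape[:2] == (rows.size and rows[-1] - rows[0] + 1,
                                                  cols[-1] - cols[0] + 1)
        assert cmask.area_px == mask.area_px

    def test_measurements_invariant_under_crop(self, cal20):
        ci, mask = self._scene(cal20)
        before = rg.measure_dimensions(mask, ci.calibration)
        _, cmask = rg.crop_to_mask(ci, mask, margin_px=3)
        after = rg.measure_dimensions(cmask, ci.calibration)
        assert after == pytest.approx(before, rel=1e-12)

    def test_oversized_margin_clamped(self, cal20):
        ci, mask = self._scene(cal20)
        cropped, _ = rg.crop_to_mask(ci, mask, margin_px=10_000)
        assert cropped.image.pixels.shape == ci.image.pixels.shape

    def test_empty_mask_raises(self, cal20):
        ci, _ = self._scene(cal20)
        with pytest.raises(rg.SegmentationError):
            rg.crop_to_mask(ci, BinaryMask(np.zeros((200, 260), bool)))
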