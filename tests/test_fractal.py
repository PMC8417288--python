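"""Local box-counting dimension against an independent brute-force oracle."""

import numpy as np
import pytest

from octafract import (
    BinaryMask,
    EnFaceAngiogram,
    Layer,
    ScanGeometry,
    binarize,
    local_fractal_dimension,
    normalized_ratio_map,
)

WINDOW = 33
SIZES = (16, 8, 4, 2)


def brute_force_fd(mask: np.ndarray, i: int, j: int, window=WINDOW, sizes=SIZES) -> float:
    """Reference box-count regression, coded independently of the pipeline.

    Clips the window at the image border, tiles it per scale with boxes
    anchored at the window corner discarding trailing partial boxes, counts
    occupied boxes by explicit slicing, and fits the log-log slope with
    polyfit.
    """
    r = window // 2
    win = mask[max(i - r, 0): i + r + 1, max(j - r, 0): j + r + 1]
    if not win.any():
        return 0.0
    xs, ys = [], []
    for s in sizes:
        occupied = 0
        for a in range(0, (win.shape[0] // s) * s, s):
            for b in range(0, (win.shape[1] // s) * s, s):
                if win[a: a + s, b: b + s].any():
                    occupied += 1
        xs.append(np.log(1.0 / s))
        ys.append(np.log(max(occupied, 1)))
    slope = np.polyfit(xs, ys, 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


class TestLocalFractalDimension:
    def test_matches_brute_force_oracle_on_random_masks(self, small_geometry):
        """Center-pixel FD equals the independent oracle on random 64x64 masks."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mask = rng.random((64, 64)) < rng.uniform(0.05, 0.5)
            fm = local_fractal_dimension(BinaryMask(mask, small_geometry))
            expected = brute_force_fd(mask, 32, 32)
            assert fm.values[32, 32] == pytest.approx(expected, abs=1e-9)

    def test_matches_oracle_at_borders(self, small_geometry):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.2
        fm = local_fractal_dimension(BinaryMask(mask, small_geometry))
        for (i, j) in [(0, 0), (0, 32), (5, 63), (63, 63), (16, 2)]:
            assert fm.values[i, j] == pytest.approx(brute_force_fd(mask, i, j), abs=1e-9)

    def test_filled_square_measures_two(self):
        g = ScanGeometry(3.0, 65)
        fm = local_fractal_dimension(BinaryMask(np.ones((65, 65), bool), g))
        assert 1.9 <= fm.values[32, 32] <= 2.0

    def test_single_pixel_line_measures_one(self):
        g = ScanGeometry(3.0, 65)
        mask = np.zeros((65, 65), bool)
        mask[32, :] = True
        fm = local_fractal_dimension(BinaryMask(mask, g))
        assert 0.9 <= fm.values[32, 32] <= 1.1

    def test_empty_window_is_zero(self):
        g = ScanGeometry(3.0, 65)
        fm = local_fractal_dimension(BinaryMask(np.zeros((65, 65), bool), g))
        assert np.all(fm.values == 0.0)

    def test_values_bounded_by_plane_dimension(self, small_geometry, rng):
        mask = rng.random((64, 64)) < 0.4
        fm = local_fractal_dimension(BinaryMask(mask, small_geometry))
        assert fm.values.min() >= 0.0 and fm.values.max() <= 2.0

    def test_translation_equivariance_in_interior(self, small_geometry, rng):
        """Shifting the mask shifts the FD map (away from borders)."""
        mask = rng.random((64, 64)) < 0.2
        shifted = np.roll(mask, (5, 7), axis=(0, 1))
        g = small_geometry
        a = local_fractal_dimension(BinaryMask(mask, g)).values
        b = local_fractal_dimension(BinaryMask(shifted, g)).values
        core = a[20:40, 20:36]
        assert np.allclose(b[25:45, 27:43], core, atol=1e-12)

    def test_too_few_box_sizes_rejected(self, small_geometry):
        mask = BinaryMask(np.ones((64, 64), bool), small_geometry)
        with pytest.raises(ValueError, match="at least 3"):
            local_fractal_dimension(mask, box_sizes_px=(8, 4))

    @pytest.mark.parametrize("window", [32, -3])
    def test_bad_window_rejected(self, small_geometry, window):
        mask = BinaryMask(np.ones((64, 64), bool), small_geometry)
        with pytest.raises(ValueError):
            local_fractal_dimension(mask, window_px=window)


class TestBinarize:
    def test_noiseless_phantom_recovers_ground_truth_mask(self):
        from octafract import PhantomSpec, generate_phantom

        spec = PhantomSpec(seed=9, noise_sd=0.0)
        scp, _, truth = generate_phantom(spec)
        mask = binarize(scp)
        assert np.array_equal(mask.pixels, truth.scp_mask.pixels)

    def test_constant_image_warns_and_returns_background(self):
        g = ScanGeometry(3.0, 32)
        img = EnFaceAngiogram(np.full((32, 32), 0.5), Layer.SCP, g)
        with pytest.warns(UserWarning, match="constant image"):
            mask = binarize(img)
        assert not mask.pixels.any()

    def test_inverted_contrast_flagged(self, rng):
        g = ScanGeometry(3.0, 64)
        # vessels dark on bright: foreground fraction after Otsu > 60%
        px = np.where(rng.random((64, 64)) < 0.2, 0.1, 0.8)
        img = EnFaceAngiogram(px, Layer.SCP, g)
        with pytest.warns(UserWarning, match="contrast"):
            binarize(img)


class TestNormalizedRatio:
    def test_self_normalization_of_constant_map(self, small_geometry):
        from octafract.fractal import FractalMap

        fm = FractalMap(np.full((8, 8), 1.3), WINDOW, SIZES)
        ratio = normalized_ratio_map(fm)
        assert np.allclose(ratio.values, 1.0)
        assert ratio.max_fd == pytest.approx(1.3)

    def test_half_of_max_gives_half_ratio(self):
        from octafract.fractal import FractalMap

        values = np.zeros((4, 4))
        values[0, 0] = 2.0
        values[1, 1] = 1.0
        ratio = normalized_ratio_map(FractalMap(values, WINDOW, SIZES))
        assert ratio.values[1, 1] == pytest.approx(0.5)
        assert ratio.values.max() == pytest.approx(1.0)

    def test_all_zero_map_warns(self):
        from octafract.fractal import FractalMap

        with pytest.warns(UserWarning, match="all zero"):
            ratio = normalized_ratio_map(FractalMap(np.zeros((4, 4)), WINDOW, SIZES))
        assert np.all(ratio.values == 0.0)
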