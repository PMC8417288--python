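"""Phantom generator contracts: geometry, coverage, dropout, rendering."""

import numpy as np
import pytest

from octafract import (
    Layer,
    PhantomSpec,
    ScanGeometry,
    apply_dropout,
    generate_phantom,
    generate_vessel_layer,
    inject_projection_artifact,
    render_angiogram,
)
from octafract.phantom import faz_region, large_vessel_component


class TestVesselLayer:
    def test_faz_disc_radius_matches_closed_form(self):
        spec = PhantomSpec()
        expected = np.sqrt(spec.faz_area_mm2 / np.pi) / spec.geometry.pixel_pitch_mm
        assert spec.faz_radius_px == pytest.approx(expected)
        assert spec.faz_radius_px == pytest.approx(37.06, abs=0.05)

    def test_carved_faz_area_matches_spec_within_discretization(self):
        spec = PhantomSpec(seed=2)
        faz = faz_region(spec.geometry, spec.faz_area_mm2)
        carved = faz.sum() * spec.geometry.pixel_area_mm2()
        # one boundary ring of pixels is the discretization error budget
        ring = 2 * np.pi * spec.faz_radius_px * spec.geometry.pixel_area_mm2()
        assert abs(carved - spec.faz_area_mm2) < ring

    def test_faz_contains_no_vessels(self, normal_phantom):
        _, _, truth = normal_phantom
        spec = PhantomSpec(seed=42)
        faz = faz_region(spec.geometry, spec.faz_area_mm2)
        assert not (truth.scp_mask.pixels & faz).any()
        assert not (truth.dcp_mask.pixels & faz).any()

    def test_capillary_coverage_near_target(self):
        spec = PhantomSpec(seed=7)
        rng = np.random.default_rng(spec.seed)
        mask = generate_vessel_layer(spec, Layer.SCP, rng)
        faz = faz_region(spec.geometry, spec.faz_area_mm2)
        capillary = mask.pixels & ~large_vessel_component(mask)
        cov = (capillary & ~faz).sum() / (~faz).sum()
        # large vessels absorb some mesh pixels, so allow the band downward
        assert 0.8 * spec.capillary_density_target <= cov <= 1.1 * spec.capillary_density_target

    def test_degenerate_spec_gives_empty_mask(self):
        spec = PhantomSpec(seed=1, n_large_vessels=0, capillary_density_target=0.0)
        mask = generate_vessel_layer(spec, Layer.SCP, np.random.default_rng(1))
        assert not mask.pixels.any()

    def test_oversized_faz_rejected(self):
        g = ScanGeometry(3.0, 64)
        with pytest.raises(ValueError, match="does not fit"):
            faz_region(g, 9.0)

    def test_same_seed_same_phantom(self):
        a = generate_phantom(PhantomSpec(seed=5))
        b = generate_phantom(PhantomSpec(seed=5))
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[1].pixels, b[1].pixels)
        assert np.array_equal(a[2].scp_mask.pixels, b[2].scp_mask.pixels)

    def test_irregular_faz_needs_rng_and_stays_avascular(self):
        g = ScanGeometry(3.0, 128)
        with pytest.raises(ValueError, match="rng"):
            faz_region(g, 0.3, irregularity=0.2)
        reg = faz_region(g, 0.3, irregularity=0.2, rng=np.random.default_rng(0))
        target_px = 0.3 / g.pixel_area_mm2()
        assert reg.sum() == pytest.approx(target_px, rel=0.15)


class TestDropout:
    @pytest.fixture(scope="class")
    def base_mask(self):
        spec = PhantomSpec(seed=13)
        return generate_vessel_layer(spec, Layer.DCP, np.random.default_rng(13))

    def test_zero_dropout_is_identity(self, base_mask):
        out = apply_dropout(base_mask, 0.0, 6, np.random.default_rng(0))
        assert np.array_equal(out.pixels, base_mask.pixels)

    def test_full_dropout_erases_all_capillaries(self, base_mask):
        out = apply_dropout(base_mask, 1.0, 6, np.random.default_rng(0))
        protected = large_vessel_component(base_mask)
        assert not (out.pixels & ~protected).any()

    def test_erased_fraction_matches_request(self, base_mask):
        capillary = base_mask.pixels & ~large_vessel_component(base_mask)
        n_cap = capillary.sum()
        out = apply_dropout(base_mask, 0.3, 6, np.random.default_rng(0))
        erased = (base_mask.pixels & ~out.pixels).sum()
        assert erased == pytest.approx(0.3 * n_cap, abs=0.02 * n_cap)

    def test_large_vessels_preserved(self, base_mask):
        out = apply_dropout(base_mask, 0.8, 6, np.random.default_rng(0))
        protected = large_vessel_component(base_mask)
        assert np.array_equal(out.pixels & protected, protected)

    def test_coverage_decreases_monotonically(self, base_mask):
        covs = []
        for df in (0.0, 0.1, 0.2, 0.3, 0.4, 0.5):
            out = apply_dropout(base_mask, df, 6, np.random.default_rng(99))
            covs.append(out.count())
        assert all(a > b for a, b in zip(covs, covs[1:]))


class TestRendering:
    def test_noiseless_render_has_two_levels(self, rng):
        g = ScanGeometry(3.0, 64)
        from octafract import BinaryMask

        mask = BinaryMask(rng.random((64, 64)) < 0.3, g)
        img = render_angiogram(mask, 0.0, rng)
        assert set(np.unique(img.pixels)) == {0.1, 0.8}

    def test_empty_mask_renders_uniform_background(self, rng):
        g = ScanGeometry(3.0, 32)
        from octafract import BinaryMask

        img = render_angiogram(BinaryMask(np.zeros((32, 32), bool), g), 0.0, rng)
        assert np.all(img.pixels == 0.1)

    def test_noise_spread_matches_request(self):
        g = ScanGeometry(3.0, 304)
        from octafract import BinaryMask

        mask = BinaryMask(np.zeros((304, 304), bool), g)
        img = render_angiogram(mask, 0.05, np.random.default_rng(0))
        assert 0.04 <= img.pixels.std() <= 0.06


class TestProjectionInjection:
    @pytest.fixture(scope="class")
    def pair(self):
        spec = PhantomSpec(seed=21, noise_sd=0.02)
        scp, dcp, _ = generate_phantom(spec)
        return scp, dcp

    def test_zero_scale_is_identity(self, pair):
        scp, dcp = pair
        out = inject_projection_artifact(scp, dcp, 0.0)
        assert np.array_equal(out.pixels, dcp.pixels)

    def test_full_scale_correlates_with_scp(self, pair):
        scp, dcp = pair
        from octafract import BinaryMask, render_angiogram as render

        flat = render(
            BinaryMask(np.zeros(scp.geometry.shape, bool), scp.geometry),
            0.0,
            np.random.default_rng(0),
        )
        out = inject_projection_artifact(scp, flat, 1.0)
        r = np.corrcoef(out.pixels.ravel(), scp.pixels.ravel())[0, 1]
        assert r > 0.8

    def test_injected_slope_before_clipping(self, pair):
        scp, dcp = pair
        out = inject_projection_artifact(scp, dcp, 0.5)
        delta = (out.pixels - dcp.pixels).ravel()
        x = scp.pixels.ravel()
        unclipped = (dcp.pixels + 0.5 * scp.pixels).ravel() <= 1.0
        slope = np.polyfit(x[unclipped], delta[unclipped], 1)[0]
        assert slope == pytest.approx(0.5, abs=1e-6)

    def test_geometry_mismatch_rejected(self, pair):
        scp, _ = pair
        other = PhantomSpec(seed=1, geometry=ScanGeometry(3.0, 128))
        scp2, dcp2, _ = generate_phantom(other)
        with pytest.raises(ValueError, match="geometr"):
            inject_projection_artifact(scp, dcp2, 0.5)
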