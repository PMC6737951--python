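"""Phantom generator: geometry, pathology arithmetic, noise model, surface fraction."""

import numpy as np
import pytest
from scipy import stats as sps

import cardiomap as cm
from cardiomap.phantom import add_rician_noise


class TestGeometryAndPresets:
    def test_annulus_must_fit_in_image(self):
        with pytest.raises(ValueError, match="fit"):
            cm.GeometryConfig(image_height=20, image_width=20, center=(10.0, 10.0))

    def test_radii_ordering_enforced(self):
        with pytest.raises(ValueError):
            cm.GeometryConfig(endo_radius_mm=2.2, epi_radius_mm=1.2)

    def test_preset_relaxation_ordering_enforced(self):
        with pytest.raises(ValueError, match="T2"):
            cm.TissuePreset("bad", t1=100.0, t2=200.0, t2star=5.0)


class TestMakeLvPhantom:
    def test_zero_pathology_gives_uniform_maps(self, healthy_phantom):
        mask = healthy_phantom.myocardium_mask
        assert np.all(healthy_phantom.t1_map[mask] == cm.HEALTHY_MYOCARDIUM.t1)
        assert np.all(healthy_phantom.t2_map[mask] == cm.HEALTHY_MYOCARDIUM.t2)
        assert np.all(healthy_phantom.t2star_map[mask] == cm.HEALTHY_MYOCARDIUM.t2star)

    def test_iron_rate_arithmetic_reproduces_severe_t2star(self, geometry):
        # concentration chosen so r2star*c = 1/3.7 - 1/27 on a 27 ms T2* base
        base = cm.TissuePreset("t2star27", t1=1505.0, t2=28.5, t2star=27.0)
        rx = cm.IronRelaxivity()
        c = (1 / 3.7 - 1 / 27.0) / rx.r2star
        lesion = cm.Lesion(shape="disc", angle_deg=0.0, depth=0.5,
                           radius_mm=0.3, iron_concentration=c)
        ph = cm.make_lv_phantom(geometry, base, cm.PathologyConfig(lesions=(lesion,)))
        lesion_px = ph.iron_map > 0
        assert lesion_px.any()
        np.testing.assert_allclose(ph.t2star_map[lesion_px], 3.7, rtol=1e-12)

    def test_rate_additivity_invariants_hold_pixelwise(self, iron_phantom):
        mask = iron_phantom.myocardium_mask
        assert np.all(1 / iron_phantom.t2star_map[mask] >= 1 / iron_phantom.t2_map[mask] - 1e-12)
        assert np.all(iron_phantom.t1_map[mask] >= iron_phantom.t2_map[mask])

    def test_pathology_zero_outside_mask(self, iron_phantom):
        out = ~iron_phantom.myocardium_mask
        for f in (iron_phantom.iron_map, iron_phantom.edema_map,
                  iron_phantom.infiltration_map, iron_phantom.fibrosis_map,
                  iron_phantom.rbc_map, iron_phantom.pd_map):
            assert np.all(f[out] == 0)

    def test_deterministic_for_fixed_seed(self, geometry):
        pc = cm.PathologyConfig(
            lesions=(cm.Lesion(iron_concentration=0.8, depth=0.5),),
            texture_sd=0.1, seed=42)
        a = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM, pc)
        b = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM, pc)
        np.testing.assert_array_equal(a.t2star_map, b.t2star_map)
        np.testing.assert_array_equal(a.iron_map, b.iron_map)

    @pytest.mark.parametrize("c", [0.2, 0.5, 1.0, 2.0])
    def test_iron_monotonically_shortens_all_times(self, geometry, c):
        lesion = cm.Lesion(iron_concentration=c, depth=0.5, radius_mm=0.4)
        lo = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                                cm.PathologyConfig(lesions=(lesion,)))
        hi_lesion = cm.Lesion(iron_concentration=c * 1.5, depth=0.5, radius_mm=0.4)
        hi = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                                cm.PathologyConfig(lesions=(hi_lesion,)))
        for field in ("t1_map", "t2_map", "t2star_map"):
            assert np.all(getattr(hi, field) <= getattr(lo, field) + 1e-12)

    def test_lesion_outside_annulus_raises_with_index(self, geometry):
        bad = cm.Lesion(shape="disc", depth=0.5, radius_mm=5.0,
                        iron_concentration=1.0)
        # a giant disc is fine (clipped to the wall); an out-of-wall centre is not
        cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                           cm.PathologyConfig(lesions=(bad,)))
        with pytest.raises(ValueError, match="lesion 0"):
            cm.make_lv_phantom(
                geometry, cm.HEALTHY_MYOCARDIUM,
                cm.PathologyConfig(lesions=(cm.Lesion(depth=5.0),)))


class TestSimulatedSeries:
    def test_ir_signal_decays_to_steady_state_at_long_ti(self, healthy_phantom):
        s = cm.simulate_ir_series(healthy_phantom, rr_interval=100.0, n_ti=200,
                                  snr=None)
        mask = healthy_phantom.myocardium_mask
        np.testing.assert_allclose(
            s.frames[-1][mask], healthy_phantom.pd_map[mask], rtol=1e-3)

    def test_ir_null_point_closed_form(self):
        # signal crosses zero at TI = T1* ln(B/A); place a TI exactly there
        ph = cm.uniform_phantom((2, 2), cm.HEALTHY_MYOCARDIUM)
        eff = 1.0
        t1_star = ph.t1_map[0, 0] / eff
        null_ti = t1_star * np.log(2.0)
        rr = null_ti / 10.0  # TI grid hits the null point at index 9
        s = cm.simulate_ir_series(ph, rr_interval=rr, n_ti=20, efficiency=eff,
                                  snr=None)
        assert s.frames[9][0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_ir_times_are_rr_multiples(self, healthy_phantom):
        s = cm.simulate_ir_series(healthy_phantom, rr_interval=100.0, snr=None)
        np.testing.assert_allclose(s.times_ms % 100.0, 0.0, atol=1e-9)

    def test_se_frame_ratios_match_exponential_decay(self, healthy_phantom):
        te = np.asarray(cm.SE_ECHO_TIMES_MS)
        s = cm.simulate_echo_series(healthy_phantom, te, "SE", snr=None)
        mask = healthy_phantom.myocardium_mask
        ratios = s.frames[1:, mask] / s.frames[:-1, mask]
        expected = np.exp(-np.diff(te) / 28.5)
        np.testing.assert_allclose(
            ratios, np.broadcast_to(expected[:, None], ratios.shape), rtol=1e-12)

    def test_ute_first_echo_closed_form(self):
        ph = cm.uniform_phantom((3, 3), cm.TissuePreset("x", 1505, 28.5, 3.7, 50.0))
        s = cm.simulate_echo_series(ph, cm.UTE_ECHO_TIMES_MS, "UTE", snr=None)
        assert s.frames[0][0, 0] == pytest.approx(50.0 * np.exp(-0.1), rel=1e-12)

    def test_infinite_snr_equals_noiseless(self, healthy_phantom):
        a = cm.simulate_echo_series(healthy_phantom, cm.SE_ECHO_TIMES_MS, "SE",
                                    snr=None)
        b = cm.simulate_echo_series(healthy_phantom, cm.SE_ECHO_TIMES_MS, "SE",
                                    snr=np.inf, seed=1)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_series_determinism_per_seed(self, healthy_phantom):
        a = cm.simulate_ir_series(healthy_phantom, snr=30.0, seed=5)
        b = cm.simulate_ir_series(healthy_phantom, snr=30.0, seed=5)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_unsorted_te_rejected(self, healthy_phantom):
        with pytest.raises(ValueError):
            cm.simulate_echo_series(healthy_phantom, (5.0, 2.0, 8.0), "SE")

    def test_too_few_inversion_times_rejected(self, healthy_phantom):
        with pytest.raises(ValueError):
            cm.simulate_ir_series(healthy_phantom, n_ti=3)


class TestRicianNoise:
    def test_samples_follow_rician_cdf(self):
        # Kolmogorov-Smirnov on 1e5 magnitude samples at a fixed true signal
        rng = np.random.default_rng(123)
        s, sigma = 2.0, 1.0
        samples = add_rician_noise(np.full(100_000, s), sigma, rng)
        stat = sps.kstest(samples, sps.rice(b=s / sigma, scale=sigma).cdf)
        assert stat.pvalue > 0.001

    def test_magnitude_mean_shows_noncentral_chi_bias(self):
        # the sample mean of noisy magnitudes exceeds the true signal by the
        # closed-form Rician mean bias
        rng = np.random.default_rng(7)
        s, sigma = 3.0, 1.0
        samples = add_rician_noise(np.full(10_000, s), sigma, rng)
        expected = sps.rice(b=s / sigma, scale=sigma).mean()
        assert expected > s
        assert samples.mean() == pytest.approx(expected, rel=0.01)

    def test_sigma_zero_returns_magnitude(self):
        rng = np.random.default_rng(0)
        out = add_rician_noise(np.array([-1.0, 2.0]), 0.0, rng)
        np.testing.assert_array_equal(out, [1.0, 2.0])


class TestLesionSurfaceFraction:
    def test_no_lesions_gives_zero(self, healthy_phantom):
        assert cm.lesion_surface_fraction(healthy_phantom) == 0.0

    def test_wedge_covers_its_angular_share(self, geometry):
        lesion = cm.Lesion(shape="wedge", angle_deg=30.0, span_deg=144.0,
                           iron_concentration=1.0)
        ph = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                                cm.PathologyConfig(lesions=(lesion,)))
        assert cm.lesion_surface_fraction(ph) == pytest.approx(144 / 360, abs=0.03)

    def test_invariant_under_quarter_rotation(self, geometry):
        lesion = cm.Lesion(shape="wedge", angle_deg=10.0, span_deg=100.0,
                           iron_concentration=0.7)
        ph = cm.make_lv_phantom(geometry, cm.HEALTHY_MYOCARDIUM,
                                cm.PathologyConfig(lesions=(lesion,)))
        import dataclasses
        rotated = dataclasses.replace(
            ph,
            **{f: np.rot90(getattr(ph, f)) for f in
               ("t1_map", "t2_map", "t2star_map", "pd_map", "edema_map",
                "infiltration_map", "fibrosis_map", "iron_map", "rbc_map",
                "myocardium_mask")},
            geometry=None,
        )
        assert cm.lesion_surface_fraction(rotated) == cm.lesion_surface_fraction(ph)

    def test_empty_mask_raises(self):
        ph = cm.uniform_phantom((4, 4), cm.HEALTHY_MYOCARDIUM)
        ph.myocardium_mask = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            cm.lesion_surface_fraction(ph)
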