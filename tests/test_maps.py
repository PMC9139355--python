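"""Biomarker mapping: closed forms, round trips, hysteresis statistics."""

import numpy as np
import pytest

from phymri.cohort import AcquisitionConfig, gamma_variate
from phymri.constants import PhysioConstants
from phymri.maps import (BiomarkerMap, DynamicSeries, MultiEchoSeries,
                         VHLCurve, apply_physiological_threshold, build_vhl,
                         compute_adc, compute_case_maps, compute_cbv_cbf,
                         compute_cmro2, compute_delta_r2_curve, compute_mti,
                         compute_mvd, compute_oef, compute_po2, compute_qmax,
                         compute_vsi, fit_gamma_variate,
                         fit_relaxation_rate, mvd_closed_form,
                         oef_closed_form, po2_closed_form, vsi_closed_form)


class TestADC:
    def test_identity_and_closed_forms(self):
        s0 = np.full((4, 4, 2), 100.0)
        cases = [
            (s0.copy(), 0.0),  # S = S0 -> ADC 0
            (s0 * np.exp(-1.0), 1.0),  # e^-1 at b=1000 -> 1.0e-3 mm²/s
            (s0 * 0.5, np.log(2)),  # ratio 0.5 -> ln2/1000 ≈ 0.693e-3
        ]
        for sb, expected in cases:
            adc = compute_adc(s0, sb, b=1000.0)
            assert np.allclose(adc.values, expected, atol=1e-9)

    def test_nonpositive_signal_marks_invalid(self):
        s0 = np.full((2, 2, 1), 100.0)
        sb = np.full((2, 2, 1), 50.0)
        sb[0, 0, 0] = -1.0
        adc = compute_adc(s0, sb, b=1000.0)
        assert not adc.valid[0, 0, 0]
        assert adc.valid[1, 1, 0]


class TestDeltaR2:
    def _series(self, signal):
        t = np.arange(signal.shape[-1]) * 1.5
        return DynamicSeries(signal, t, echo_time=0.02, echo_type="GE",
                             baseline=slice(0, 8))

    def test_flat_signal_gives_zero(self):
        s = np.full((2, 2, 1, 30), 100.0)
        dr2, valid = compute_delta_r2_curve(self._series(s))
        assert np.allclose(dr2, 0.0) and valid.all()

    def test_closed_form(self):
        s = np.full((1, 1, 1, 30), 100.0)
        s[..., 15] = 100.0 * np.exp(-2.0)
        dr2, _ = compute_delta_r2_curve(self._series(s))
        assert dr2[0, 0, 0, 15] == pytest.approx(100.0, rel=1e-12)

    def test_round_trip_through_simulator(self, noiseless_case,
                                          noiseless_config):
        s = noiseless_case.series["DSC_GE"]
        dr2, _ = compute_delta_r2_curve(DynamicSeries(
            s, noiseless_config.times, noiseless_config.te_ge, "GE",
            slice(0, noiseless_config.baseline_window)))
        # reconstruct the generator's curve at one tumor voxel
        vox = tuple(np.argwhere(noiseless_case.tumor_mask)[0])
        expected = -np.log(s[vox] / s[vox][:8].mean()) / noiseless_config.te_ge
        assert np.allclose(dr2[vox], expected, atol=1e-10)


class TestGammaVariate:
    def test_noiseless_self_recovery(self):
        t = np.arange(60) * 1.5
        truth = gamma_variate(t, K=5.0, alpha=3.0, beta=1.5, t0=10.0)
        fit = fit_gamma_variate(truth, t)
        assert fit.success
        for got, want in zip((fit.K, fit.alpha, fit.beta, fit.t0),
                             (5.0, 3.0, 1.5, 10.0)):
            assert got == pytest.approx(want, rel=1e-4, abs=1e-4)

    def test_flat_curve_flagged_unfit(self):
        t = np.arange(60) * 1.5
        fit = fit_gamma_variate(np.zeros(60), t)
        assert not fit.success

    def test_noisy_peak_time_within_one_sample(self, rng):
        t = np.arange(60) * 1.5
        truth = gamma_variate(t, K=5.0, alpha=3.0, beta=1.5, t0=10.0)
        peak_t = t[np.argmax(truth)]
        hits = 0
        n = 100
        for _ in range(n):
            noisy = truth + rng.normal(0, 0.05 * truth.max(), 60)
            fit = fit_gamma_variate(noisy, t)
            if fit.success:
                fit_peak = t[np.argmax(fit.fitted)]
                hits += abs(fit_peak - peak_t) <= 1.5
        assert hits / n > 0.9


class TestCBVCBF:
    def _aif(self):
        t = np.arange(60) * 1.5
        aif = gamma_variate(t, 1.0, 3.0, 1.5, 15.0)
        return t, aif * (300.0 / aif.max())

    def test_linear_scaling(self):
        t, aif = self._aif()
        tissue = 0.05 * aif
        cbv, _ = compute_cbv_cbf(tissue[None, :], aif, t)
        assert cbv[0] == pytest.approx(5.0, rel=1e-9)

    def test_zero_tissue_gives_zero(self):
        t, aif = self._aif()
        cbv, cbf = compute_cbv_cbf(np.zeros((1, 60)), aif, t)
        assert cbv[0] == 0.0 and cbf[0] == 0.0

    def test_deconvolution_recovers_flow(self):
        # forward-convolve a known flow and exponential residue, invert
        t, aif = self._aif()
        cbf_true = 0.01  # fraction/s
        residue = np.exp(-t / 4.0)
        tissue = np.convolve(aif, residue)[:60] * 1.5 * cbf_true
        _, cbf = compute_cbv_cbf(tissue[None, :], aif, t, svd_threshold=1e-8)
        assert cbf[0] / 6000.0 == pytest.approx(cbf_true, rel=0.10)

    def test_nonpositive_aif_rejected(self):
        t = np.arange(60) * 1.5
        with pytest.raises(ValueError, match="AIF"):
            compute_cbv_cbf(np.zeros((1, 60)), np.zeros(60), t)

    def test_auto_aif_selects_arterial_curves(self, rng):
        # arterial curves: earlier, taller, narrower than tissue curves
        from phymri.maps import auto_select_aif
        t, aif = self._aif()
        arterial = np.stack([aif * rng.uniform(0.95, 1.05) for _ in range(6)])
        tissue = np.stack([
            np.convolve(aif, np.exp(-t / 6.0))[:60] * 1.5 * 0.01
            * rng.uniform(0.8, 1.2) for _ in range(60)])
        curves = np.vstack([tissue, arterial])
        est = auto_select_aif(curves, t, n_select=6)
        assert est.max() == pytest.approx(aif.max(), rel=0.06)
        assert abs(int(np.argmax(est)) - int(np.argmax(aif))) <= 1
        with pytest.raises(ValueError, match="positive peak"):
            auto_select_aif(np.zeros((3, 60)), t)


class TestVHLAndMTI:
    def test_collinear_curve_has_zero_area(self):
        se = np.linspace(0, 4, 20)
        ge = se**1.5
        vhl = build_vhl(ge, se, slice(0, 20))
        assert compute_mti(vhl) == pytest.approx(0.0, abs=1e-9)

    def test_clockwise_circle_is_plus_pi(self):
        # clockwise traversal in (x, y): MTI = +area
        theta = np.linspace(0, 2 * np.pi, 361)[:-1]
        x, y = np.cos(-theta) + 2.0, np.sin(-theta) + 2.0
        vhl = VHLCurve(x=x, y=y, time_indices=np.arange(360))
        assert compute_mti(vhl) == pytest.approx(np.pi, rel=1e-3)

    def test_orientation_antisymmetry(self):
        theta = np.linspace(0, 2 * np.pi, 361)[:-1]
        x, y = np.cos(theta) + 2.0, np.sin(theta) + 2.0
        ccw = VHLCurve(x=x, y=y, time_indices=np.arange(360))
        cw = VHLCurve(x=x[::-1], y=y[::-1], time_indices=np.arange(360))
        assert compute_mti(ccw) == pytest.approx(-np.pi, rel=1e-3)
        assert compute_mti(cw) == pytest.approx(-compute_mti(ccw), rel=1e-9)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="3"):
            build_vhl(np.ones(10), np.ones(10), slice(0, 2))

    def test_negative_se_clamped(self):
        ge = np.array([1.0, 2.0, 1.0])
        se = np.array([-1.0, 1.0, -2.0])
        vhl = build_vhl(ge, se, slice(0, 3))
        assert np.all(vhl.x >= 0)

    def test_simulated_clockwise_loop_orientation(self, profiles):
        # a case forced clockwise must give positive tumor MTI, and the
        # generator's loop traversal must have negative shoelace sign
        import dataclasses
        from phymri.cohort import simulate_case
        from phymri.maps import first_pass_window, shoelace_area
        config = AcquisitionConfig(shape=(36, 36, 14), spacing=(1, 1, 3),
                                   noise_sigma=0.0)
        prof = dataclasses.replace(profiles["GBM"], clockwise_prob=1.0)
        case = simulate_case(prof, config, seed=3)
        maps = compute_case_maps(case, config, roi=case.tumor_mask)
        tumor_mti = maps["MTI"].values[case.tumor_mask & maps["MTI"].valid]
        assert np.median(tumor_mti) > 0
        # explicit loop at one voxel
        vox = tuple(np.argwhere(case.tumor_mask)[0])
        te = config.te_ge
        ge = -np.log(case.series["DSC_GE"][vox]
                     / case.series["DSC_GE"][vox][:8].mean()) / te
        se = -np.log(case.series["DSC_SE"][vox]
                     / case.series["DSC_SE"][vox][:8].mean()) / config.te_se
        win = first_pass_window(ge, config.times)
        vhl = build_vhl(ge, se, win)
        assert shoelace_area(vhl.x, vhl.y) < 0  # clockwise


class TestQmax:
    def test_hand_value(self):
        ge = np.array([0.0, 10.0, 3.0])
        se = np.array([0.0, 4.0, 1.0])
        assert compute_qmax(ge, se) == pytest.approx(10.0 / 8.0)

    def test_identity(self):
        one = np.array([0.5, 1.0])
        assert compute_qmax(one, one) == pytest.approx(1.0)

    def test_zero_se_invalid(self):
        assert np.isnan(compute_qmax(np.ones(3), np.zeros(3)))

    def test_literal_denominator_variant(self):
        ge = np.array([4.0])
        se = np.array([9.0])
        assert compute_qmax(ge, se, literal_ge_denominator=True) == \
            pytest.approx(4.0 / 8.0)


class TestVesselArchitecture:
    def test_mvd_closed_form_spot_value(self):
        # Qmax=CBV=ADC=1, R̄=3, β=1.6781 (raw units):
        # (1/(24π²·81))^(1/3) ≈ 3.734e-2
        val = mvd_closed_form(1.0, 1.0, 1.0, 3.0, 1.6781)
        assert val == pytest.approx(3.734e-2, rel=1e-3)

    def test_vsi_closed_form_spot_value(self):
        # (1.6781/(32π))^(1/2) ≈ 0.1292
        val = vsi_closed_form(1.0, 1.0, 1.0, 1.6781)
        assert val == pytest.approx(0.1292, rel=1e-3)

    def test_mvd_zero_qmax_and_homogeneity(self):
        assert mvd_closed_form(0.0, 1.0, 1.0, 3.0, 1.6781) == 0.0
        a = mvd_closed_form(0.7, 1.0, 1.0, 3.0, 1.6781)
        b = mvd_closed_form(0.7, 2.0, 1.0, 3.0, 1.6781)
        assert b / a == pytest.approx(2.0 ** (1.0 / 3.0))

    def test_vsi_monotone_in_qmax_and_homogeneous(self):
        q = np.linspace(0.2, 3.0, 20)
        v = vsi_closed_form(q, 1.0, 1.0, 1.6781)
        assert np.all(np.diff(v) < 0)
        assert vsi_closed_form(1.0, 2.0, 2.0, 1.6781) == \
            pytest.approx(2.0 * vsi_closed_form(1.0, 1.0, 1.0, 1.6781))

    def test_map_level_invalid_handling(self):
        qmax = np.array([[[1.0, np.nan]]])
        cbv = np.array([[[10.0, 10.0]]])
        adc = np.array([[[1.0, 1.0]]])
        mvd = compute_mvd(qmax, cbv, adc)
        assert mvd.valid[0, 0, 0] and not mvd.valid[0, 0, 1]
        vsi = compute_vsi(np.array([[[0.0]]]), np.array([[[10.0]]]),
                          np.array([[[1.0]]]))
        assert not vsi.valid[0, 0, 0]


class TestRelaxometry:
    def test_exact_on_noiseless_decay(self):
        tes = np.array([0.01, 0.02, 0.04, 0.08])
        s = 100.0 * np.exp(-50.0 * tes)
        series = MultiEchoSeries(np.tile(s, (2, 2, 1, 1)), tes, "GE")
        rate, valid = fit_relaxation_rate(series)
        assert np.allclose(rate, 50.0, rtol=1e-12) and valid.all()

    def test_constant_signal_gives_zero_rate(self):
        tes = np.array([0.01, 0.02, 0.04])
        series = MultiEchoSeries(np.full((2, 2, 1, 3), 80.0), tes, "SE")
        rate, _ = fit_relaxation_rate(series)
        assert np.allclose(rate, 0.0, atol=1e-10)

    def test_rician_noise_bias_small(self, rng):
        # R = 20 1/s, 8 echoes, 2% noise: mean recovered rate within 2%
        tes = np.linspace(0.005, 0.12, 8)
        s = 100.0 * np.exp(-20.0 * tes)
        sig = np.sqrt((s + rng.normal(0, 2.0, (1000, 1, 1, 8))) ** 2
                      + rng.normal(0, 2.0, (1000, 1, 1, 8)) ** 2)
        rate, _ = fit_relaxation_rate(MultiEchoSeries(sig, tes, "SE"))
        assert rate.mean() == pytest.approx(20.0, rel=0.02)


class TestQBOLD:
    def test_oef_spot_value(self):
        # ΔR = 4.75 1/s, CBV = 0.05, printed constants at 3 T -> ≈ 0.300
        c = PhysioConstants()
        assert oef_closed_form(4.75, 0.0, 0.05, c) == \
            pytest.approx(0.300, abs=0.001)

    def test_oef_zero_when_rates_equal(self):
        oef = compute_oef(np.full((2, 2, 1), 20.0), np.full((2, 2, 1), 20.0),
                          np.full((2, 2, 1), 0.05))
        assert np.allclose(oef.values, 0.0)

    def test_oef_inverse_in_cbv(self):
        c = PhysioConstants()
        assert oef_closed_form(4.75, 0.0, 0.10, c) == \
            pytest.approx(oef_closed_form(4.75, 0.0, 0.05, c) / 2.0)

    def test_zero_cbv_invalid(self):
        oef = compute_oef(np.ones((1, 1, 1)), np.zeros((1, 1, 1)),
                          np.zeros((1, 1, 1)))
        assert not oef.valid.any()

    def test_cmro2_is_ca_cbf_oef(self):
        r2s = np.random.default_rng(0).uniform(20, 30, (3, 3, 2))
        r2 = r2s - 4.0
        cbv = np.full((3, 3, 2), 0.04)
        cbf = np.full((3, 3, 2), 50.0)
        c = PhysioConstants()
        oef = compute_oef(r2s, r2, cbv, c)
        cm = compute_cmro2(r2s, r2, cbv, cbf, c)
        assert np.allclose(cm.values, c.ca * cbf * oef.values / 100.0)

    def test_cmro2_direct_product(self):
        # CBF = 50, OEF = 0.3, Ca = 8.68 -> 130.2
        assert 8.68 * 50.0 * 0.3 == pytest.approx(130.2)

    def test_po2_full_extraction_is_p50(self):
        c = PhysioConstants()
        assert po2_closed_form(1.0, 0.0, c) == pytest.approx(27.0)

    def test_po2_spot_value(self):
        # OEF = 0.5, CMRO2 = 130.2 -> 27·3^(1/2.7) − 130.2/4.4 ≈ 11.0
        c = PhysioConstants()
        assert po2_closed_form(0.5, 130.2, c) == pytest.approx(10.97, abs=0.05)

    def test_po2_decreasing_in_oef(self):
        c = PhysioConstants()
        oefs = np.linspace(0.1, 1.0, 30)
        vals = po2_closed_form(oefs, 100.0, c)
        assert np.all(np.diff(vals) < 0)


class TestThreshold:
    def test_out_of_range_voxel_invalidated(self):
        from phymri.constants import MAP_SPECS
        vals = np.array([[[1.0, 5.0]]])  # ADC range [0, 3]
        bm = BiomarkerMap.from_spec(vals, MAP_SPECS["ADC"])
        out = apply_physiological_threshold(bm)
        assert out.valid[0, 0, 0] and not out.valid[0, 0, 1]

    def test_in_range_map_unchanged(self):
        from phymri.constants import MAP_SPECS
        vals = np.full((2, 2, 2), 1.0)
        bm = BiomarkerMap.from_spec(vals, MAP_SPECS["ADC"])
        out = apply_physiological_threshold(bm)
        assert out.valid.all() and np.array_equal(out.values, vals)

    def test_fully_out_of_range_empties_mask(self):
        from phymri.constants import MAP_SPECS
        bm = BiomarkerMap.from_spec(np.full((2, 2, 2), 99.0),
                                    MAP_SPECS["ADC"])
        assert not apply_physiological_threshold(bm).valid.any()


class TestForwardInverseRoundTrips:
    def test_zero_noise_adc_r2s_r2_recovered(self, noiseless_case,
                                             noiseless_config):
        maps = compute_case_maps(noiseless_case, noiseless_config,
                                 threshold=False,
                                 roi=noiseless_case.tumor_mask)
        adc_err = np.abs(maps["ADC"].values - noiseless_case.truth["ADC"])
        assert np.max(adc_err / np.maximum(noiseless_case.truth["ADC"],
                                           1e-9)) < 1e-6
        for name, key in (("R2star", "R2star"), ("R2", "R2")):
            rel = np.abs(maps[name].values - noiseless_case.truth[key]) \
                / noiseless_case.truth[key]
            assert rel.max() < 1e-6

    def test_time_reversal_flips_mti_sign(self, noiseless_case,
                                          noiseless_config):
        import copy
        maps = compute_case_maps(noiseless_case, noiseless_config,
                                 roi=noiseless_case.tumor_mask,
                                 gamma_fit=False, threshold=False)
        rev = copy.copy(noiseless_case)
        rev.series = dict(noiseless_case.series)
        rev.series["DSC_GE"] = noiseless_case.series["DSC_GE"][..., ::-1]
        rev.series["DSC_SE"] = noiseless_case.series["DSC_SE"][..., ::-1]
        rev.aif_ge = noiseless_case.aif_ge[::-1].copy()
        # reversing both series traverses every loop backwards
        tm = noiseless_case.tumor_mask
        mti_fwd = maps["MTI"].values[tm]
        from phymri.maps import first_pass_window
        # recompute loop areas directly on reversed curves at 20 voxels
        te_ge, te_se = noiseless_config.te_ge, noiseless_config.te_se
        flips = 0
        voxels = np.argwhere(tm)[:20]
        for vox in map(tuple, voxels):
            ge = -np.log(noiseless_case.series["DSC_GE"][vox]
                         / noiseless_case.series["DSC_GE"][vox][:8].mean()) / te_ge
            se = -np.log(noiseless_case.series["DSC_SE"][vox]
                         / noiseless_case.series["DSC_SE"][vox][:8].mean()) / te_se
            win = first_pass_window(ge, noiseless_config.times)
            mti = compute_mti(build_vhl(ge, se, win))
            n = len(ge)
            rwin = slice(n - win.stop, n - win.start)
            mti_rev = compute_mti(build_vhl(ge[::-1], se[::-1], rwin))
            flips += mti == pytest.approx(-mti_rev, rel=1e-6, abs=1e-9)
        assert flips == 20
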