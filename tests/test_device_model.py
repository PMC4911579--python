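"""Transfer-curve forward model, figure extraction and decoupling algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biofet
from biofet import device_model as dm
from biofet import synthetic_data as syn
from biofet.errors import (
    DataConventionError,
    ExtractionError,
    InsufficientReplicatesError,
    InvalidParameterError,
)

MU_001_CM2 = 0.01 * 1e-4  # 0.01 cm²/Vs in SI


class TestSaturationCurrent:
    def test_hand_evaluated_magnitude(self):
        # W=4 mm, L=200 um, C_i=9 nF/cm2, mu=0.01 cm2/Vs, V_G=-100, V_T=-10:
        # (W/2L)*C_i*mu*(V_G-V_T)^2 = 10 * 9e-5 * 1e-6 * 8100 = 7.29 uA
        i = dm.saturation_current(-100.0, -10.0, MU_001_CM2, 4e-3, 200e-6, 9e-5)
        assert i == pytest.approx(-7.29e-6, rel=1e-12)

    def test_zero_at_threshold(self):
        assert dm.saturation_current(-10.0, -10.0, MU_001_CM2, 4e-3, 200e-6, 9e-5) == 0.0

    def test_linear_in_mobility(self):
        i1 = dm.saturation_current(-100.0, -10.0, MU_001_CM2, 4e-3, 200e-6, 9e-5)
        i2 = dm.saturation_current(-100.0, -10.0, 2 * MU_001_CM2, 4e-3, 200e-6, 9e-5)
        assert i2 == pytest.approx(2 * i1)

    def test_polarity_sign(self):
        assert dm.saturation_current(100.0, 10.0, MU_001_CM2, 4e-3, 200e-6, 9e-5,
                                     polarity="n") > 0

    @pytest.mark.parametrize("bad", ["width", "length", "c_area", "mobility"])
    def test_nonpositive_parameters_rejected(self, bad):
        kwargs = dict(width=4e-3, length=200e-6, c_area=9e-5, mobility=MU_001_CM2)
        kwargs[bad] = 0.0
        with pytest.raises(InvalidParameterError):
            dm.saturation_current(-100.0, -10.0, **kwargs)


class TestExtractFigures:
    @pytest.mark.parametrize("vt", [-30.0, -10.0, 0.0, 7.6])
    @pytest.mark.parametrize("mu", [0.002, 0.01, 0.05])
    def test_noiseless_round_trip(self, vt, mu):
        curve = syn.gen_transfer_curve(biofet.CurveGenSpec(true_vt=vt, true_mu_cm2=mu))
        fig = dm.extract_figures(curve)
        assert fig.threshold_voltage == pytest.approx(vt, abs=1e-9 * max(1, abs(vt)))
        assert fig.mobility_cm2 == pytest.approx(mu, rel=1e-9)
        assert fig.fit_r2 == pytest.approx(1.0)
        lo, hi = fig.fit_window
        assert curve.gate_voltage.min() <= lo <= hi <= curve.gate_voltage.max()

    def test_noisy_median_vt_error_below_one_volt(self):
        errors = []
        for seed in range(50):
            curve = syn.gen_transfer_curve(biofet.CurveGenSpec(
                true_vt=-10.0, true_mu_cm2=0.01, noise_rel=0.02, seed=seed))
            fig = dm.extract_figures(curve)
            errors.append(abs(fig.threshold_voltage - (-10.0)))
        assert np.median(errors) < 1.0

    def test_rolloff_region_excluded(self):
        spec = biofet.CurveGenSpec(true_vt=-10.0, true_mu_cm2=0.01,
                                   noise_rel=0.02, rolloff_onset=-60.0, seed=3)
        fig = dm.extract_figures(syn.gen_transfer_curve(spec))
        # window must avoid the clamped high-|V_G| region
        assert fig.fit_window[0] >= -70.0
        assert abs(fig.threshold_voltage + 10.0) < 2.0

    def test_noiseless_rolloff_recovery_within_noisy_tolerance(self):
        spec = biofet.CurveGenSpec(true_vt=-10.0, true_mu_cm2=0.01, rolloff_onset=-60.0)
        fig = dm.extract_figures(syn.gen_transfer_curve(spec))
        assert fig.threshold_voltage == pytest.approx(-10.0, abs=1.0)
        assert fig.mobility_cm2 == pytest.approx(0.01, rel=0.05)

    def test_n_type_symmetric(self):
        spec = biofet.CurveGenSpec(true_vt=10.0, true_mu_cm2=0.01, polarity="n",
                                   v_start=-20.0, v_stop=100.0, v_step=10.0,
                                   drain_bias=80.0)
        fig = dm.extract_figures(syn.gen_transfer_curve(spec))
        assert fig.threshold_voltage == pytest.approx(10.0, abs=1e-9)

    def test_no_linear_window_raises(self):
        vg = np.linspace(20, -100, 13)
        rng = np.random.default_rng(0)
        curve = biofet.TransferCurve(vg, -np.abs(rng.lognormal(0, 2, 13)) * 1e-6,
                                     -80.0, 4e-3, 200e-6, 9e-5)
        with pytest.raises(ExtractionError, match="R²|linearity|points"):
            dm.extract_figures(curve)

    def test_mixed_sign_currents_rejected(self):
        curve = syn.gen_transfer_curve(
            biofet.CurveGenSpec(true_vt=-10.0, true_mu_cm2=0.01))
        flipped = np.array(curve.drain_current)
        flipped[-1] *= -1  # one accumulation point with the wrong sign
        bad = biofet.TransferCurve(curve.gate_voltage, flipped, -80.0,
                                   4e-3, 200e-6, 9e-5)
        with pytest.raises((DataConventionError, ExtractionError)):
            dm.extract_figures(bad)


class TestNormalizedResponse:
    def test_identity(self):
        assert dm.normalized_response(-1e-6, -1e-6) == 0.0

    def test_magnitude_decrease_is_negative(self):
        assert dm.normalized_response(-0.7e-6, -1e-6) == pytest.approx(-0.30)

    def test_zero_baseline_raises(self):
        with pytest.raises(DataConventionError, match="dev7"):
            dm.normalized_response(-1e-6, 0.0, device_id="dev7")

    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           i0=st.floats(min_value=0.1, max_value=10),
           r=st.floats(min_value=-0.9, max_value=2.0))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_invariant_under_common_rescaling(self, scale, i0, r):
        i1 = i0 * (1 + r)
        base = dm.normalized_response(-i1, -i0)
        assert dm.normalized_response(-i1 * scale, -i0 * scale) == pytest.approx(
            base, rel=1e-9, abs=1e-12)


class TestFirstOrderDecompose:
    def test_mobility_only_channel(self):
        resp = dm.first_order_decompose(delta_mu_rel=-0.20, delta_vt_term=0.0)
        assert resp.delta_I_rel == pytest.approx(-0.20)

    def test_threshold_only_channel(self):
        resp = dm.first_order_decompose(delta_mu_rel=0.0, delta_vt_term=0.16)
        assert resp.delta_I_rel == pytest.approx(-0.32)

    def test_null_perturbation(self):
        resp = dm.first_order_decompose(delta_mu_rel=0.0, delta_vt_term=0.0)
        assert resp.delta_I_rel == 0.0 and resp.residual == 0.0

    def test_solve_each_unknown(self):
        r = dm.first_order_decompose(delta_I_rel=-0.32, delta_mu_rel=0.0)
        assert r.delta_vt_term == pytest.approx(0.16)
        r = dm.first_order_decompose(delta_I_rel=-0.20, delta_vt_term=0.0)
        assert r.delta_mu_rel == pytest.approx(-0.20)

    def test_all_three_keeps_residual(self):
        r = dm.first_order_decompose(-0.25, -0.20, 0.01)
        assert r.residual == pytest.approx(-0.25 - (-0.20 - 0.02))

    def test_sign_law_negative_overdrive(self):
        # (V_G - V_T0) < 0 and dV_T < 0 make the threshold term positive,
        # driving dI/I0 negative.
        vg, vt0, dvt = -100.0, 7.6, -29.04
        term = dvt / (vg - vt0)
        assert term > 0
        resp = dm.first_order_decompose(delta_mu_rel=0.0, delta_vt_term=term)
        assert resp.delta_I_rel < 0

    def test_too_few_knowns_rejected(self):
        with pytest.raises(InvalidParameterError):
            dm.first_order_decompose(delta_I_rel=-0.2)

    @given(a=st.floats(min_value=-0.05, max_value=0.05),
           b=st.floats(min_value=-0.05, max_value=0.05))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_first_order_closure_on_paired_curves(self, a, b):
        """Residual of the exact paired-curve response is O(perturbation²)."""
        vg, vt0 = -100.0, -10.0
        dvt = b * (vg - vt0)
        spec = biofet.CurveGenSpec(true_vt=vt0, true_mu_cm2=0.01)
        base, sig = syn.gen_paired_transfer_curves(spec, delta_vt=dvt, delta_mu_rel=a)
        i0 = dm.current_at(base, vg)
        i1 = dm.current_at(sig, vg)
        resp = biofet.BindingResponse(
            delta_I_rel=dm.normalized_response(i1, i0),
            delta_mu_rel=a, delta_vt_term=b)
        assert abs(resp.residual) <= 3 * 0.05**2 + 1e-12


class TestAggregation:
    def test_mean_sd_rsd(self):
        agg = dm.aggregate([-0.2, -0.25, -0.3], ["a", "b", "c"])
        assert agg.mean == pytest.approx(-0.25)
        assert agg.rsd == pytest.approx(agg.sd / 0.25)
        assert agg.n_devices == 3

    def test_degenerate_spread(self):
        agg = dm.aggregate([-0.23] * 9)
        assert agg.sd == pytest.approx(0.0, abs=1e-12)
        assert agg.rsd == pytest.approx(0.0, abs=1e-12)

    def test_reported_sav_responses_not_significantly_different(self):
        # FBI -0.23 +/- 0.01 vs PFC -0.30 +/- 0.17, nine devices each
        res = dm.compare_groups_from_stats(-0.23, 0.01, 9, -0.30, 0.17, 9, alpha=0.05)
        assert not res.significant
        assert res.pvalue > 0.05

    def test_group_vs_itself(self):
        g = [-0.21, -0.24, -0.22, -0.26]
        res = dm.compare_groups(g, g)
        assert res.pvalue == pytest.approx(1.0)
        assert not res.significant

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            dm.compare_groups([-0.2], [-0.3, -0.2])
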