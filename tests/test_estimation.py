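"""Tests for the gas-exchange/fluorescence estimation chain."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import canophot as cp
from canophot.estimation import CalibrationError, DataQualityError

KIN = cp.MEASUREMENT_KINETICS


class TestPhiPSII:
    @pytest.mark.parametrize("fs,fm,expected", [
        (500.0, 1000.0, 0.5),   # half quenching
        (1000.0, 1000.0, 0.0),  # fully quenched
        (0.0, 1000.0, 1.0),     # open-centre limit
    ])
    def test_reference_points(self, fs, fm, expected):
        assert cp.phi_psii(fs, fm) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cp.phi_psii(100.0, 0.0)
        with pytest.raises(DataQualityError):
            cp.phi_psii(1200.0, 1000.0)

    @given(fm=st.floats(1e-3, 1e5), frac=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_in_unit_interval(self, fm, frac):
        assert 0.0 <= cp.phi_psii(frac * fm, fm) <= 1.0


class TestJFromFluorescence:
    def test_zero_phi_gives_zero(self):
        assert cp.j_from_fluorescence(0.0, 1500.0, 0.425) == 0.0

    def test_hand_arithmetic(self):
        assert cp.j_from_fluorescence(0.25, 1500.0, 0.425) == pytest.approx(159.375)

    def test_identity_case(self):
        assert cp.j_from_fluorescence(1.0, 1.0, 1.0) == 1.0


class TestCalibration:
    def test_exact_line_recovery(self):
        # A = 0.425 x - 1.0 at x = 10, 20, 30 (PPFD-distinct points)
        pts = [(4 * x / p, p, 0.425 * x - 1.0)
               for x, p in [(10.0, 200.0), (20.0, 150.0), (30.0, 100.0)]]
        res = cp.calibrate_alphabeta_rd(pts)
        assert res.alphabeta == pytest.approx(0.425, abs=1e-12)
        assert res.Rd == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)

    def test_line_through_origin_gives_zero_rd(self):
        pts = [(4 * x / p, p, 0.5 * x)
               for x, p in [(10.0, 200.0), (20.0, 150.0), (30.0, 100.0)]]
        assert cp.calibrate_alphabeta_rd(pts).Rd == 0.0

    def test_too_few_points(self):
        with pytest.raises(CalibrationError):
            cp.calibrate_alphabeta_rd([(0.5, 100.0, 5.0), (0.6, 200.0, 10.0)])

    def test_single_light_level_rejected(self):
        pts = [(0.5, 100.0, 5.0), (0.6, 100.0, 6.0), (0.7, 100.0, 7.0)]
        with pytest.raises(CalibrationError):
            cp.calibrate_alphabeta_rd(pts)

    def test_negative_slope_rejected(self):
        pts = [(4 * x / p, p, -0.3 * x)
               for x, p in [(10.0, 200.0), (20.0, 150.0), (30.0, 100.0)]]
        with pytest.raises(DataQualityError):
            cp.calibrate_alphabeta_rd(pts)

    def test_small_negative_rd_clamped_with_warning(self):
        pts = [(4 * x / p, p, 0.425 * x + 0.05)
               for x, p in [(10.0, 200.0), (20.0, 150.0), (30.0, 100.0)]]
        with pytest.warns(UserWarning):
            res = cp.calibrate_alphabeta_rd(pts)
        assert res.Rd == 0.0

    def test_noisy_recovery_consistent_with_ols_errors(self, truth_leaf):
        """Noise sd 0.1 on A: estimates fall within 3 OLS standard errors."""
        hits_ab = hits_rd = 0
        n_rep = 100
        for rep in range(n_rep):
            cfg = cp.SyntheticConfig(truth=truth_leaf, noise_sd_A=0.1,
                                     seed=1000 + rep)
            res = cp.calibrate_from_records(cp.synth_low_o2_light_response(cfg))
            if abs(res.alphabeta - truth_leaf.alphabeta) <= 3 * res.se_slope:
                hits_ab += 1
            if abs(res.Rd - truth_leaf.Rd25) <= 3 * res.se_intercept:
                hits_rd += 1
        # with 5 points the se has 3 dof: P(|t_3| <= 3) ~ 0.94, so demand
        # coverage safely consistent with that, not the Gaussian 99.7%
        assert hits_ab >= 0.85 * n_rep
        assert hits_rd >= 0.85 * n_rep


class TestVariableJ:
    def test_hand_algebra_worked_value(self):
        # term = 40*408/96 = 170; gm = 25 / (295-170) = 0.200
        assert cp.gm_variable_j(25.0, 295.0, 200.0, 1.0, 40.0) == pytest.approx(0.200)

    def test_no_flux_gives_zero(self):
        assert cp.gm_variable_j(0.0, 295.0, 200.0, 0.0, 40.0) == 0.0

    def test_inconsistent_electron_transport_rejected(self):
        with pytest.raises(DataQualityError):
            cp.gm_variable_j(25.0, 295.0, 100.0, 1.0, 40.0)  # J <= 4(A+Rd)

    def test_ci_below_drawdown_rejected(self):
        with pytest.raises(DataQualityError):
            cp.gm_variable_j(25.0, 100.0, 200.0, 1.0, 40.0)

    def test_pointwise_roundtrip_from_forward_model(self, aci_records,
                                                    truth_leaf):
        """Forward records generated with gm=0.25 invert to gm exactly."""
        for r in aci_records:
            j = cp.j_from_fluorescence(cp.phi_psii(r.Fs, r.Fm_prime), r.PPFD,
                                       truth_leaf.alphabeta)
            gm = cp.gm_variable_j(r.A, r.Ci, j, truth_leaf.Rd25, 40.0)
            assert gm == pytest.approx(truth_leaf.gm25, rel=1e-6)

    def test_consistency_with_cc_from_gm(self):
        a, ci, j, rd, g = 22.0, 310.0, 180.0, 1.2, 40.0
        gm = cp.gm_variable_j(a, ci, j, rd, g)
        cc = cp.cc_from_gm(a, ci, gm)
        assert cc == pytest.approx(g * (j + 8 * (a + rd)) / (j - 4 * (a + rd)))


class TestCcTransform:
    def test_zero_flux_keeps_ci(self):
        assert cp.cc_from_gm(0.0, 295.0, 0.2) == 295.0

    def test_hand_arithmetic(self):
        assert cp.cc_from_gm(25.0, 295.0, 0.2) == pytest.approx(170.0)

    def test_infinite_gm_limit(self):
        assert cp.cc_from_gm(25.0, 295.0, float("inf")) == 295.0

    def test_curve_count_and_order_preserved(self, aci_records):
        acc = cp.transform_aci_to_acc(aci_records, 0.25)
        assert len(acc) == len(aci_records) == 13
        assert [a for _, a in acc] == [r.A for r in aci_records]

    def test_offending_point_named(self, aci_records):
        with pytest.raises(DataQualityError, match="point 0"):
            cp.transform_aci_to_acc(aci_records, 1e-3)

    def test_invalid_gm(self):
        with pytest.raises(ValueError):
            cp.cc_from_gm(25.0, 295.0, 0.0)


class TestFvcbFit:
    def test_noiseless_roundtrip_within_one_percent(self, aci_records,
                                                    truth_leaf):
        acc = cp.transform_aci_to_acc(aci_records, truth_leaf.gm25)
        fit = cp.fit_fvcb_params(acc, truth_leaf.Rd25,
                                 alphabeta=truth_leaf.alphabeta)
        assert fit.Vcmax == pytest.approx(truth_leaf.Vcmax25, rel=0.01)
        assert fit.Jmax == pytest.approx(truth_leaf.Jmax25, rel=0.01)
        assert fit.TPU == pytest.approx(truth_leaf.TPU25, rel=0.01)
        assert set(fit.limiting_states) == {"rubisco", "rubp", "tpu"}

    def test_tpu_absent_without_high_cc_plateau(self, aci_records, truth_leaf):
        acc = [(cc, a) for cc, a in
               cp.transform_aci_to_acc(aci_records, truth_leaf.gm25)
               if cc < 250.0]
        fit = cp.fit_fvcb_params(acc, truth_leaf.Rd25,
                                 alphabeta=truth_leaf.alphabeta)
        assert fit.TPU is None

    def test_adding_on_model_point_never_raises_sse(self, aci_records,
                                                    truth_leaf):
        acc = cp.transform_aci_to_acc(aci_records, truth_leaf.gm25)
        base = cp.fit_fvcb_params(acc, truth_leaf.Rd25,
                                  alphabeta=truth_leaf.alphabeta)
        j = cp.j_light_response(1500.0, base.Jmax, 0.7, eff=truth_leaf.alphabeta)
        cc_new = 350.0
        a_new, _ = cp.net_assimilation_at_cc(cc_new, Vcmax=base.Vcmax, J=j,
                                             TPU=base.TPU, Rd=truth_leaf.Rd25,
                                             kin=KIN)
        grown = cp.fit_fvcb_params(acc + [(cc_new, a_new)], truth_leaf.Rd25,
                                   alphabeta=truth_leaf.alphabeta)
        assert grown.sse <= base.sse + 1e-9


class TestSlnAve:
    def test_uniform_nitrogen_reduces_to_total_over_area(self):
        s = cp.LeafNitrogenSample(N_o=2.0, N_other=2.0, DM_o=5.0,
                                  DM_other=15.0, LA_o=0.05, LA_other=0.20)
        assert cp.sln_ave(s) == pytest.approx(1.6)

    def test_hand_arithmetic(self):
        s = cp.LeafNitrogenSample(N_o=2.5, N_other=1.5, DM_o=4.0,
                                  DM_other=16.0, LA_o=0.05, LA_other=0.20)
        assert cp.sln_ave(s) == pytest.approx(1.36)

    def test_single_stratum_collapse(self):
        s = cp.LeafNitrogenSample(N_o=2.0, N_other=0.0, DM_o=5.0,
                                  DM_other=0.0, LA_o=0.05, LA_other=0.0)
        assert cp.sln_ave(s) == pytest.approx(0.02 * 5.0 / 0.05)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            cp.LeafNitrogenSample(N_o=2.0, N_other=2.0, DM_o=5.0,
                                  DM_other=15.0, LA_o=0.0, LA_other=0.0)


class TestFullChain:
    def test_zero_noise_chain_recovers_all_parameters(self, aci_records,
                                                      low_o2_records,
                                                      truth_leaf):
        res = cp.estimate_leaf_parameters(aci_records, low_o2_records)
        assert res["calibration"].alphabeta == pytest.approx(
            truth_leaf.alphabeta, rel=1e-6)
        assert res["calibration"].Rd == pytest.approx(truth_leaf.Rd25, rel=1e-6)
        assert res["gm"] == pytest.approx(truth_leaf.gm25, rel=1e-6)
        fit = res["fit"]
        assert fit.Vcmax == pytest.approx(truth_leaf.Vcmax25, rel=0.01)
        assert fit.Jmax == pytest.approx(truth_leaf.Jmax25, rel=0.01)
        assert fit.TPU == pytest.approx(truth_leaf.TPU25, rel=0.01)
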