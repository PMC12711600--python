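"""Conductivity arithmetic, QC rule, sigmoid vulnerability fits, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hydrotraits as ht
from hydrotraits.vulnerability import VCFitError, sigmoid_plc


class TestConductivity:
    def test_ratio(self):
        m = ht.FlowMeasurement(jv=2e-6, dp_dl=0.004)
        assert ht.initial_conductivity(m) == pytest.approx(5e-4)

    def test_zero_flow(self):
        assert ht.initial_conductivity(ht.FlowMeasurement(0.0, 0.01)) == 0.0

    def test_scale_invariance(self):
        k1 = ht.initial_conductivity(ht.FlowMeasurement(2e-6, 0.004))
        k2 = ht.initial_conductivity(ht.FlowMeasurement(4e-6, 0.008))
        assert k1 == pytest.approx(k2)

    def test_invalid_gradient(self):
        with pytest.raises(ValueError, match="dp_dl"):
            ht.FlowMeasurement(1e-6, 0.0)


class TestPLC:
    @pytest.mark.parametrize(
        "k_i,k_max,expected", [(2.0, 2.0, 0.0), (0.0, 2.0, 100.0), (1.0, 2.0, 50.0)]
    )
    def test_closed_form(self, k_i, k_max, expected):
        plc, clipped = ht.percent_loss_conductivity(k_i, k_max)
        assert plc == pytest.approx(expected)
        assert not clipped

    def test_negative_plc_clipped_and_flagged(self):
        plc, clipped = ht.percent_loss_conductivity(2.1, 2.0)
        assert plc == 0.0
        assert clipped

    def test_invalid_kmax(self):
        with pytest.raises(ValueError, match="k_max"):
            ht.percent_loss_conductivity(1.0, 0.0)


class TestEquilibrationQC:
    def test_accept_and_mean(self):
        assert ht.equilibration_qc(-1.50, -1.60)
        rec = ht.BranchRecord(
            branch_id="b", psi_leaf_a=-1.50, psi_leaf_b=-1.60,
            k_i=1.0, k_max=2.0,
        )
        assert rec.psi_stem == pytest.approx(-1.55)

    def test_reject_large_difference(self):
        assert not ht.equilibration_qc(-1.50, -1.75)

    def test_boundary_is_rejected(self):
        # exactly 0.20 MPa is not "< 0.20"
        assert not ht.equilibration_qc(-1.50, -1.70)


class TestFitVulnerability:
    def test_noise_free_recovery(self, vc_series_clean):
        series, truth = vc_series_clean
        fit = ht.fit_vulnerability(series.records)
        assert fit.converged
        assert fit.psi50 == pytest.approx(truth["psi50"], abs=1e-4)
        assert fit.slope_a == pytest.approx(truth["slope_a"], abs=1e-3)

    def test_round_trip_from_own_parameters(self, vc_series_clean):
        series, _ = vc_series_clean
        fit = ht.fit_vulnerability(series.records)
        regen, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=fit.psi50, slope_a=fit.slope_a,
                           n_branches=25, seed=1)
        )
        refit = ht.fit_vulnerability(regen.records)
        assert refit.psi50 == pytest.approx(fit.psi50, abs=1e-5)

    def test_fitted_curve_monotone(self, vc_series_clean):
        series, _ = vc_series_clean
        fit = ht.fit_vulnerability(series.records)
        psi = np.linspace(-8, 0, 200)
        plc = sigmoid_plc(psi, fit.slope_a, fit.psi50)
        assert np.all(np.diff(plc) <= 0)  # PLC falls as psi rises toward 0

    def test_insufficient_span(self):
        recs = [
            ht.BranchRecord(branch_id=str(i), psi_leaf_a=-2.0,
                            psi_leaf_b=-2.0, k_i=1.0, k_max=2.0)
            for i in range(8)
        ]
        with pytest.raises(VCFitError, match="span"):
            ht.fit_vulnerability(recs)

    def test_too_few_records(self):
        recs = [
            ht.BranchRecord(branch_id=str(i), psi_leaf_a=-float(i + 1),
                            psi_leaf_b=-float(i + 1), k_i=1.0, k_max=2.0)
            for i in range(4)
        ]
        with pytest.raises(VCFitError, match=">= 6"):
            ht.fit_vulnerability(recs)

    def test_weibull_model_close_to_sigmoid_truth(self, vc_series_clean):
        series, truth = vc_series_clean
        fit = ht.fit_vulnerability(series.records, model="weibull")
        assert fit.converged
        assert fit.psi50 == pytest.approx(truth["psi50"], abs=0.1)


class TestPsiAtPLC:
    def test_p50_is_psi50(self, vc_series_clean):
        series, _ = vc_series_clean
        fit = ht.fit_vulnerability(series.records)
        assert ht.psi_at_plc(fit, 50.0) == pytest.approx(fit.psi50)

    def test_closed_form_p12(self):
        fit = ht.VCFit(psi50=-3.0, slope_a=2.0, psi12=float("nan"),
                       n_branches=0, converged=True)
        assert ht.psi_at_plc(fit, 12.0) == pytest.approx(
            -3.0 + np.log(88 / 12) / 2.0
        )
        assert ht.psi_at_plc(fit, 12.0) == pytest.approx(-2.004, abs=1e-3)

    def test_log_odds_symmetry(self):
        fit = ht.VCFit(psi50=-2.5, slope_a=1.3, psi12=float("nan"),
                       n_branches=0, converged=True)
        d12 = ht.psi_at_plc(fit, 12.0) - fit.psi50
        d88 = ht.psi_at_plc(fit, 88.0) - fit.psi50
        assert d12 == pytest.approx(-d88)

    def test_threshold_ordering(self, vc_series_clean):
        series, _ = vc_series_clean
        fit = ht.fit_vulnerability(series.records)
        assert ht.psi_at_plc(fit, 12) > ht.psi_at_plc(fit, 50) > ht.psi_at_plc(fit, 88)

    @pytest.mark.parametrize("p", [0.0, 100.0, -5.0, 120.0])
    def test_p_out_of_range(self, p):
        fit = ht.VCFit(psi50=-3.0, slope_a=2.0, psi12=-2.0,
                       n_branches=0, converged=True)
        with pytest.raises(ValueError, match="p"):
            ht.psi_at_plc(fit, p)


class TestBootstrap:
    def test_noise_free_interval_degenerate(self, vc_series_clean):
        series, _ = vc_series_clean
        ci50, ci12 = ht.bootstrap_ci(series.records, n_boot=200, seed=5)
        assert ci50[1] - ci50[0] < 1e-6
        assert ci12[1] - ci12[0] < 1e-6

    def test_same_seed_identical(self):
        series, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=20,
                           noise_sd_plc=5.0, seed=3)
        )
        a = ht.bootstrap_ci(series.records, n_boot=200, seed=11)
        b = ht.bootstrap_ci(series.records, n_boot=200, seed=11)
        assert a == b

    def test_nboot_floor(self, vc_series_clean):
        series, _ = vc_series_clean
        with pytest.raises(ValueError, match="n_boot"):
            ht.bootstrap_ci(series.records, n_boot=50, seed=1)

    def test_ci_bounds_ordered_and_bracket_estimate(self):
        series, _ = ht.gen_vc_observations(
            ht.VCGenParams(psi50_true=-3.0, slope_a=2.0, n_branches=30,
                           noise_sd_plc=5.0, seed=7)
        )
        fit = ht.fit_vulnerability(series.records, n_boot=200, seed=7)
        lo, hi = fit.ci95_psi50
        assert lo < hi
        assert lo < fit.psi50 < hi


class TestSpecificConductivity:
    def test_no_pith(self):
        assert ht.specific_conductivity(1e-6, 2e-5) == pytest.approx(0.05)

    def test_pith_subtracted(self):
        assert ht.specific_conductivity(1e-6, 2e-5, 1e-5) == pytest.approx(0.1)

    def test_degenerate_area(self):
        with pytest.raises(ValueError, match="functional"):
            ht.specific_conductivity(1e-6, 1e-5, 1e-5)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    a=st.floats(0.3, 8.0),
    psi50=st.floats(-8.0, -0.5),
    p=st.floats(1.0, 99.0),
)
def test_psi_at_plc_inverts_sigmoid(a, psi50, p):
    """psi_at_plc is the exact inverse of the sigmoid PLC model."""
    fit = ht.VCFit(psi50=psi50, slope_a=a, psi12=float("nan"),
                   n_branches=0, converged=True)
    psi_p = ht.psi_at_plc(fit, p)
    assert float(sigmoid_plc(np.array([psi_p]), a, psi50)[0]) == pytest.approx(
        p, abs=1e-8
    )
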