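"""Connectivity tests: Wald GCT, weighted-chi-square nulls, cMVGC, decisions."""

import numpy as np
import pytest
from scipy.stats import chi2

from gcconnbench import (
    VARModel,
    WeightedChiSquareNull,
    conditional_mvgc_test,
    decide_connectivity,
    fit_nuttall_strand,
    fit_yule_walker_lwr,
    gct_all_pairs,
    granger_causality_test,
    pdc_asymptotic_pvalues,
    simulate_model2,
    simulate_var,
    weighted_chisq_tail,
)
from gcconnbench.spectral_measures import FrequencyGrid
from gcconnbench.var_estimation import EstimatedVAR, pair_coefficient_covariance


@pytest.fixture(scope="module")
def est_model2_k2000():
    return fit_nuttall_strand(simulate_model2(2000, seed=314), order=3)


class TestGrangerCausalityTest:
    def test_zero_coefficients_give_unit_pvalue(self):
        model = VARModel(coeffs=np.zeros((2, 3, 3)))
        est = EstimatedVAR(model=model, n_samples_used=1000,
                           regressor_cov=np.eye(6), method="nuttall_strand")
        res = granger_causality_test(est, 0, 1)
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.dof_or_weights == 2

    def test_self_pair_rejected(self, est_model2_k2000):
        with pytest.raises(ValueError):
            granger_causality_test(est_model2_k2000, 1, 1)

    def test_strong_connection_detected(self, est_model2_k2000):
        # 1 -> 2 has a 0.5 coefficient: overwhelming at K = 2000
        assert granger_causality_test(est_model2_k2000, 1, 0).p_value < 1e-10

    def test_statistic_is_wald_quadratic_form(self, est_model2_k2000):
        res = granger_causality_test(est_model2_k2000, 2, 0)
        a = est_model2_k2000.coeffs[:, 2, 0]
        c = pair_coefficient_covariance(est_model2_k2000, 2, 0)
        assert res.statistic == pytest.approx(a @ np.linalg.solve(c, a))
        assert res.p_value == pytest.approx(chi2.sf(res.statistic, 3))

    def test_all_pairs_diagonal_nan(self, est_model2_k2000):
        pmat = gct_all_pairs(est_model2_k2000)
        assert np.all(np.isnan(np.diag(pmat)))
        off = ~np.eye(5, dtype=bool)
        assert np.all((pmat[off] >= 0) & (pmat[off] <= 1))


class TestWeightedChiSquareTail:
    def test_single_unit_weight_matches_chisquare(self):
        null = WeightedChiSquareNull([1.0])
        for s in (0.5, 3.0, 7.0):
            assert weighted_chisq_tail(s, null) == pytest.approx(chi2.sf(s, 1))

    def test_zero_statistic(self):
        assert weighted_chisq_tail(0.0, WeightedChiSquareNull([1.0, 0.5])) == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            weighted_chisq_tail(-1.0, WeightedChiSquareNull([1.0]))

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightedChiSquareNull([0.0, 0.0])
        with pytest.raises(ValueError):
            WeightedChiSquareNull([-0.5, 1.0])

    def test_patnaik_close_to_frozen_monte_carlo(self):
        # P(chi2_1 + 0.5 chi2_1 > 3) from 10^6 draws (PCG64 seed 0): 0.13559
        p = weighted_chisq_tail(3.0, WeightedChiSquareNull([1.0, 0.5]))
        assert p == pytest.approx(0.13559, abs=0.01)

    def test_patnaik_imhof_agree_in_decision_region(self):
        for l2 in (0.25, 0.5, 1.0):
            null = WeightedChiSquareNull([1.0, l2])
            s1, s2 = 1 + l2, 1 + l2 ** 2
            for ptarget in (0.05, 0.02, 0.01, 0.005):
                s = float(chi2.isf(ptarget, s1 ** 2 / s2)) * s2 / s1
                assert weighted_chisq_tail(s, null) == pytest.approx(
                    weighted_chisq_tail(s, null, "imhof"), abs=0.005)


class TestPdcAsymptotics:
    def test_strong_connection_tiny_pvalue(self, grid32):
        m = VARModel(coeffs=np.array([[[0.3, 0.0], [0.9, 0.3]]]))
        s = simulate_var(m, 5000, seed=17, burn_in=500)
        est = fit_nuttall_strand(s, order=1)
        fld = pdc_asymptotic_pvalues(est, grid32, "ipdc")
        assert np.nanmin(fld.pvalues[1, 0]) < 1e-6

    def test_pvalues_attached_and_valid(self, est_model2_k2000, grid32):
        for meas in ("ipdc", "idtf"):
            fld = pdc_asymptotic_pvalues(est_model2_k2000, grid32, meas)
            off = ~np.eye(5, dtype=bool)
            pv = fld.pvalues[off]
            assert pv.shape == (20, 32)
            assert np.all((pv >= 0) & (pv <= 1))
            assert np.all(np.isnan(fld.pvalues[np.eye(5, dtype=bool)]))

    def test_unknown_measure_rejected(self, est_model2_k2000, grid32):
        with pytest.raises(ValueError):
            pdc_asymptotic_pvalues(est_model2_k2000, grid32, "pdc2")

    def test_null_distribution_matches_brute_force_limit(self, est_model2_k2000):
        """Parametric sampling of the estimator's Gaussian limit reproduces
        the analytic weighted-chi-square p-value for a null pair."""
        est = est_model2_k2000
        i, j, fi = 0, 1, 5  # pair 2 -> 1 is absent in Model 2
        grid = FrequencyGrid.uniform(32)
        f = grid.freqs[fi]
        k = est.n_samples_used
        c_pair = pair_coefficient_covariance(est, i, j)
        rng = np.random.default_rng(2718)
        draws = rng.multivariate_normal(np.zeros(3), c_pair, size=200_000)
        phases = np.exp(-2j * np.pi * f * np.arange(1, 4))
        abar_ij = -(draws @ phases)
        # same denominator plug-in the analytic route uses
        from gcconnbench.spectral_measures import frequency_response
        abar, _ = frequency_response(est.model, grid)
        sigma_inv = np.linalg.inv(est.innovation_cov)
        den = float((abar[fi, :, j].conj() @ sigma_inv @ abar[fi, :, j]).real)
        stats = k * np.abs(abar_ij) ** 2 / (est.innovation_cov[i, i] * den)
        s0 = float(np.quantile(stats, 0.95))
        fld = pdc_asymptotic_pvalues(est, grid, "ipdc")
        # recompute analytic tail at s0 using the same weights machinery
        from gcconnbench.inference import _eig2, _patnaik_sf_two
        lags = np.arange(1, 4)
        cos_v = np.cos(2 * np.pi * f * lags)
        sin_v = np.sin(2 * np.pi * f * lags)
        g = c_pair * k / est.innovation_cov[i, i]
        # weights = eig of projected covariance / denominator
        cc = cos_v @ g @ cos_v
        ss = sin_v @ g @ sin_v
        cs = cos_v @ g @ sin_v
        e1, e2 = _eig2(np.array(cc), np.array(ss), np.array(cs))
        p_analytic = _patnaik_sf_two(np.array(s0), e1 / den, e2 / den)
        assert float(p_analytic) == pytest.approx(0.05, abs=0.005)


class TestConditionalMVGC:
    def test_statistic_nonnegative_and_self_pair_rejected(self):
        s = simulate_model2(500, seed=23)
        res = conditional_mvgc_test(s, 0, 1, order=3)
        assert res.statistic >= 0.0
        with pytest.raises(ValueError):
            conditional_mvgc_test(s, 2, 2, order=3)

    def test_bivariate_matches_explicit_regressions(self):
        """For N = 2 the conditional test degenerates to pairwise Geweke GC;
        compare against the log variance ratio of two explicit least-squares
        regressions."""
        m = VARModel(coeffs=np.array([[[0.4, 0.0], [0.3, 0.4]]]))
        s = simulate_var(m, 20000, seed=29, burn_in=500)
        p = 1
        res = conditional_mvgc_test(s, 1, 0, order=p)
        x = s.values - s.values.mean(axis=1, keepdims=True)
        y = x[1, p:]
        full_design = np.column_stack([x[1, :-1], x[0, :-1]])
        red_design = x[1, :-1][:, None]
        var_full = _ols_residual_var(full_design, y)
        var_red = _ols_residual_var(red_design, y)
        f_oracle = np.log(var_red / var_full)
        f_ours = res.statistic / s.n_samples
        assert f_ours == pytest.approx(f_oracle, abs=2e-3)
        assert res.p_value < 1e-10  # the 0.3 coupling is overwhelming

    def test_detects_strong_connection_and_not_reverse(self):
        s = simulate_model2(2000, seed=31)
        assert conditional_mvgc_test(s, 1, 0, order=3).p_value < 1e-8
        assert conditional_mvgc_test(s, 0, 1, order=3).p_value > 0.001


def _ols_residual_var(design, y):
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return resid @ resid / y.size


class TestDecideConnectivity:
    def test_all_unit_pvalues_no_detection(self):
        p = np.ones((4, 4))
        assert not decide_connectivity(p, alpha=0.01).decisions.any()

    def test_single_significant_frequency_detects(self):
        p = np.ones((3, 3, 32))
        p[0, 1, 17] = 0.005
        dec = decide_connectivity(p, alpha=0.01)
        assert dec.decisions[0, 1]
        assert dec.decisions.sum() == 1

    def test_bonferroni_scales_by_pair_count(self):
        # 42 ordered pairs: raw 0.0005 -> adjusted 0.021, not detected at 1%
        p = np.ones((7, 7))
        p[0, 1] = 0.0005
        assert not decide_connectivity(p, alpha=0.01,
                                       correction="bonferroni").decisions.any()
        assert decide_connectivity(p, alpha=0.01).decisions[0, 1]

    def test_fdr_keeps_strong_rejections(self):
        p = np.ones((3, 3))
        p[0, 1] = 1e-8
        dec = decide_connectivity(p, alpha=0.01, correction="fdr_bh")
        assert dec.decisions[0, 1] and dec.decisions.sum() == 1

    def test_diagonal_never_detected(self):
        p = np.zeros((3, 3)) + 1e-9
        dec = decide_connectivity(p, alpha=0.05)
        assert not np.diag(dec.decisions).any()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            decide_connectivity(np.ones((3, 3)), alpha=1.5)
        with pytest.raises(ValueError):
            decide_connectivity(np.ones((3, 3)), correction="holm")
        bad = np.ones((3, 3))
        bad[0, 1] = np.nan
        with pytest.raises(ValueError):
            decide_connectivity(bad)
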