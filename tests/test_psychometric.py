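"""Erf dose-detectability model: evaluation, inversion, fitting, reductions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf, ndtr

import lcdetect as lc
from lcdetect.psychometric import PsychometricFit

DOSES = [5.0, 10.0, 15.0, 20.0, 25.0]

pos_alpha = st.floats(min_value=1e-3, max_value=5.0)
pos_beta = st.floats(min_value=0.2, max_value=3.0)


def make_fit(alpha, beta, algorithm=None):
    return PsychometricFit(
        alpha=alpha, beta=beta, residual_ss=0.0, n_points=5,
        fit_mode="aggregate-ls", algorithm=algorithm,
    )


class TestValue:
    @given(alpha=pos_alpha, beta=pos_beta)
    @settings(max_examples=50, derandomize=True)
    def test_zero_dose_is_guessing(self, alpha, beta):
        assert lc.psychometric_value(alpha, beta, 0.0) == 0.5

    def test_phi_of_one(self):
        # alpha * d^beta = 1 -> detectability Phi(1)
        assert lc.psychometric_value(0.2, 1.0, 5.0) == pytest.approx(
            0.8413447460685429, abs=1e-12
        )

    def test_saturation(self):
        assert 1.0 - lc.psychometric_value(1.0, 1.0, 50.0) < 1e-12

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lc.psychometric_value(0.3, 1.0, -1.0)

    @pytest.mark.parametrize("alpha,beta", [(0.0, 1.0), (-0.5, 1.0), (0.3, 0.0)])
    def test_invalid_parameters_rejected(self, alpha, beta):
        with pytest.raises(ValueError):
            lc.psychometric_value(alpha, beta, 5.0)

    @given(alpha=pos_alpha, beta=pos_beta)
    @settings(max_examples=30, derandomize=True)
    def test_strictly_increasing_in_dose(self, alpha, beta):
        # doses kept below saturation so strictness is visible in floats
        d = np.linspace(0.01, 1.0, 30)
        v = lc.psychometric_value(alpha, beta, d)
        assert np.all(np.diff(v) > 0)

    @given(alpha=pos_alpha, beta=pos_beta, d=st.floats(0.5, 40))
    @settings(max_examples=30, derandomize=True)
    def test_erf_and_normal_cdf_forms_agree(self, alpha, beta, d):
        x = alpha * d**beta
        assert lc.psychometric_value(alpha, beta, d) == pytest.approx(
            0.5 * (1.0 + erf(x / np.sqrt(2.0))), abs=1e-15
        )


class TestInversion:
    def test_boundary_target(self):
        assert lc.invert_dose(make_fit(0.3, 1.0), 0.5) == 0.0

    def test_below_floor_warns(self):
        with pytest.warns(UserWarning):
            assert lc.invert_dose(make_fit(0.3, 1.0), 0.4) == 0.0

    def test_unattainable_target(self):
        with pytest.raises(ValueError):
            lc.invert_dose(make_fit(0.3, 1.0), 1.0)

    def test_phi_identity_dose(self):
        assert lc.invert_dose(make_fit(0.1, 1.0), 0.841345) == pytest.approx(
            10.0, rel=1e-4
        )

    @pytest.mark.parametrize("d", [2.0, 5.0, 8.0])
    def test_round_trip_named_parameters(self, d):
        # for these parameters doses much above ~8 mGy saturate the curve
        # beyond double resolution, so the inverse is checked below that
        fit = make_fit(0.3, 1.3)
        assert lc.invert_dose(fit, lc.psychometric_value(0.3, 1.3, d)) == pytest.approx(
            d, rel=1e-9
        )

    @given(alpha=pos_alpha, beta=pos_beta, d=st.floats(0.1, 50.0))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_property(self, alpha, beta, d):
        if alpha * d**beta > 5.0:
            # saturated: rounding of the detectability value itself loses
            # the dose information, so the inverse is ill-conditioned
            return
        psi = lc.psychometric_value(alpha, beta, d)
        assert lc.invert_dose(make_fit(alpha, beta), psi) == pytest.approx(d, rel=1e-9)


class TestFitting:
    def test_zero_noise_recovery(self):
        pts = [(d, lc.psychometric_value(0.3, 0.8, d), 480) for d in DOSES]
        fit = lc.fit_psychometric(pts)
        assert fit.alpha == pytest.approx(0.3, rel=1e-4)
        assert fit.beta == pytest.approx(0.8, rel=1e-4)
        assert fit.residual_ss < 1e-12
        assert fit.converged

    def test_binomial_ml_mode_zero_noise(self):
        pts = [(d, lc.psychometric_value(0.3, 0.8, d), 480) for d in DOSES]
        fit = lc.fit_psychometric(pts, mode="trial-binomial-ml")
        assert fit.alpha == pytest.approx(0.3, rel=1e-3)
        assert fit.beta == pytest.approx(0.8, rel=1e-3)

    def test_beats_grid_oracle(self):
        rng = np.random.default_rng(7)
        n = 480
        pts = [
            (d, rng.binomial(n, lc.psychometric_value(0.25, 0.6, d)) / n, n)
            for d in DOSES
        ]
        fit = lc.fit_psychometric(pts)
        dose = np.array([p[0] for p in pts])
        prop = np.array([p[1] for p in pts])
        alphas = np.logspace(-4, 1, 200)
        betas = np.logspace(np.log10(0.1), np.log10(5.0), 200)
        grid_best = np.inf
        for b in betas:
            pred = ndtr(alphas[:, None] * dose[None, :] ** b)
            sse = np.sum((prop[None, :] - pred) ** 2, axis=1)
            grid_best = min(grid_best, sse.min())
        assert fit.objective <= grid_best + 1e-12

    def test_binomial_noise_recovery(self):
        # mean of 200 replicate estimates within 3 MC standard errors
        alpha, beta, n = 0.3, 0.8, 4800
        rng = np.random.default_rng(11)
        est = np.empty((200, 2))
        for i in range(200):
            pts = [
                (d, rng.binomial(n, lc.psychometric_value(alpha, beta, d)) / n, n)
                for d in DOSES
            ]
            fit = lc.fit_psychometric(pts)
            est[i] = fit.alpha, fit.beta
        for j, truth in enumerate((alpha, beta)):
            se = est[:, j].std(ddof=1) / np.sqrt(len(est))
            assert abs(est[:, j].mean() - truth) <= 3 * se

    def test_non_identifiable_flagged(self):
        pts = [(d, 0.5, 100) for d in DOSES]
        with pytest.warns(UserWarning, match="identifiable"):
            fit = lc.fit_psychometric(pts)
        assert fit.non_identifiable

    def test_single_dose_rejected(self):
        with pytest.raises(ValueError):
            lc.fit_psychometric([(5.0, 0.8, 100), (5.0, 0.9, 100)])


class TestEquivalentDose:
    def test_identity(self):
        fit = make_fit(0.3, 0.8)
        assert lc.equivalent_dose(fit, fit, 10.0) == pytest.approx(10.0, rel=1e-12)

    def test_better_algorithm_needs_less_dose(self):
        ref, test = make_fit(0.2, 0.8), make_fit(0.35, 0.8)
        for d in DOSES:
            assert lc.equivalent_dose(ref, test, d) < d

    def test_equal_beta_closed_form_ratio(self):
        aref, atest, beta = 0.2, 0.32, 0.9
        ref, test = make_fit(aref, beta), make_fit(atest, beta)
        expected = (aref / atest) ** (1.0 / beta)
        for d in [2.0, 10.0, 30.0]:
            assert lc.equivalent_dose(ref, test, d) / d == pytest.approx(
                expected, rel=1e-10
            )

    def test_increasing_in_reference_dose(self):
        ref, test = make_fit(0.2, 0.7), make_fit(0.3, 0.9)
        eq = [lc.equivalent_dose(ref, test, d) for d in DOSES]
        assert np.all(np.diff(eq) > 0)

    def test_matched_detectability_equal_on_both_curves(self):
        ref, test = make_fit(0.25, 0.6), make_fit(0.4, 0.55)
        d_eq = lc.equivalent_dose(ref, test, 15.0)
        assert lc.psychometric_value(0.4, 0.55, d_eq) == pytest.approx(
            lc.psychometric_value(0.25, 0.6, 15.0), rel=1e-10
        )


class TestReductionTables:
    def test_percent_reduction_examples(self):
        assert round(lc.percent_reduction(5.0, 2.1)) == 58
        assert round(lc.percent_reduction(10.0, 4.4)) == 56
        assert lc.percent_reduction(15.0, 15.0) == 0.0

    def test_table_layout_and_summary(self):
        fits = {
            "FBP": make_fit(0.2302, 0.5772, "FBP"),
            "DLH": make_fit(0.3902, 0.5409, "DLH"),
        }
        table = lc.dose_reduction_table(fits, "FBP", DOSES)
        assert len(table) == 5
        assert (table["algorithm"] == "DLH").all()
        summary = lc.summarize_average(table, "DLH")
        assert summary.min_reduction <= summary.average_reduction <= summary.max_reduction

    def test_single_row_average(self):
        df = pd.DataFrame(
            [{"reference_algorithm": "FBP", "reference_dose_mGy": 5.0,
              "algorithm": "DLH", "equivalent_dose_mGy": 2.1,
              "reduction_pct": 58.0}]
        )
        assert lc.summarize_average(df, "DLH").average_reduction == 58.0

    def test_missing_reference_fit(self):
        with pytest.raises(ValueError):
            lc.dose_reduction_table({"DLH": make_fit(0.4, 0.5)}, "FBP", DOSES)


class TestConventionInvariance:
    def test_sqrt2_placement_is_absorbable(self):
        """Fitting/inverting under the erf convention without the internal
        sqrt(2) (alpha rescaled by 1/sqrt(2)) gives identical doses."""
        from scipy.special import erfinv

        alpha, beta = 0.25, 0.7
        alpha_b = alpha / np.sqrt(2.0)

        def value_b(a, b, d):
            return 0.5 * (1.0 + erf(a * d**b))

        def invert_b(a, b, target):
            return (erfinv(2.0 * target - 1.0) / a) ** (1.0 / b)

        for d in [2.0, 10.0, 25.0]:
            psi = lc.psychometric_value(alpha, beta, d)
            assert value_b(alpha_b, beta, d) == pytest.approx(psi, abs=1e-15)
            assert invert_b(alpha_b, beta, psi) == pytest.approx(
                lc.invert_dose(make_fit(alpha, beta), psi), rel=1e-12
            )
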