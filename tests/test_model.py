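"""Likelihood, masks, and maximum-likelihood fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm

import emaxrisk as er
from emaxrisk.model import internal_from_natural, natural_from_internal
from emaxrisk.params import ParameterError


def _rows(x, y):
    return [er.AnalysisRow(nt_probnp=float(c), event=int(e)) for c, e in zip(x, y)]


class TestNegativeLogLikelihood:
    def test_single_event_at_half_probability(self):
        params = er.EmaxParams(0.0, 1.0, 500.0, 1.0)  # P(500) = 0.5
        assert er.negative_log_likelihood(_rows([500.0], [1]), params) == pytest.approx(
            math.log(2.0), abs=1e-12)

    def test_event_and_nonevent_at_same_concentration(self):
        params = er.EmaxParams(0.0, 1.0, 500.0, 1.0)
        nll = er.negative_log_likelihood(_rows([500.0, 500.0], [1, 0]), params)
        assert nll == pytest.approx(2.0 * math.log(2.0), abs=1e-12)

    def test_matches_literal_per_row_summation(self, small_cohort_rows):
        params = er.EmaxParams(0.08, 0.6, 1500.0, 1.3)
        # independent oracle: plain python loop over the Bernoulli terms
        total = 0.0
        for row in small_cohort_rows:
            ratio = row.nt_probnp ** params.gamma / (
                row.nt_probnp ** params.gamma + params.ec50 ** params.gamma)
            p = params.p0 + params.pmax * ratio
            total -= row.event * math.log(p) + (1 - row.event) * math.log(1 - p)
        assert er.negative_log_likelihood(small_cohort_rows, params) == pytest.approx(
            total, abs=1e-12)

    def test_conflicting_degenerate_probability_returns_inf(self):
        params = er.EmaxParams(0.0, 0.5, 500.0, 1.0)  # P(0) = 0 exactly
        data = (np.array([0.0]), np.array([1]))
        assert er.negative_log_likelihood(data, params) == math.inf

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            er.negative_log_likelihood([], er.EmaxParams(0.1, 0.5, 100.0, 1.0))


class TestFixedMask:
    def test_all_fixed_rejected(self):
        with pytest.raises(ParameterError):
            er.FixedMask(p0=0.0, pmax=1.0, ec50=100.0, gamma=1.0)

    def test_invalid_fixed_values_rejected(self):
        with pytest.raises(ParameterError):
            er.FixedMask(pmax=1.5)
        with pytest.raises(ParameterError):
            er.FixedMask(p0=0.6, pmax=0.6)
        with pytest.raises(ParameterError):
            er.FixedMask(ec50=-10.0)

    def test_full_range_pmax_requires_fixed_p0(self):
        with pytest.raises(ParameterError):
            er.FixedMask(pmax=1.0)  # would leave no headroom for a free p0

    def test_free_names(self):
        assert er.FixedMask.log_logistic().free_names == ("ec50", "gamma")
        assert er.FixedMask.gamma_fixed(1.0).free_names == ("p0", "pmax", "ec50")


class TestReparameterization:
    @pytest.mark.parametrize("mask", [
        er.FixedMask.free(),
        er.FixedMask.gamma_fixed(1.0),
        er.FixedMask.log_logistic(),
        er.FixedMask(pmax=0.0, ec50=1000.0, gamma=1.0),
        er.FixedMask(p0=0.05),
    ])
    def test_round_trip_and_validity(self, mask):
        params = er.EmaxParams(
            p0=mask.p0 if mask.p0 is not None else 0.07,
            pmax=mask.pmax if mask.pmax is not None else 0.55,
            ec50=mask.ec50 if mask.ec50 is not None else 2800.0,
            gamma=mask.gamma if mask.gamma is not None else 1.4,
        )
        theta = internal_from_natural(params, mask)
        assert theta.size == mask.n_free
        back = natural_from_internal(theta, mask)
        np.testing.assert_allclose(back, params.as_array(), rtol=1e-9)
        # any internal point maps to an admissible parameter set
        rng = np.random.default_rng(0)
        for _ in range(20):
            nat = natural_from_internal(theta + rng.normal(0, 3, theta.size), mask)
            er.EmaxParams.from_array(nat)  # must not raise


class TestFit:
    def test_single_concentration_proportion_recovered_exactly(self):
        # only p0 free: the MLE is the observed event fraction
        x = np.full(40, 750.0)
        y = np.array([1] * 12 + [0] * 28)
        fit = er.fit_emax(_rows(x, y),
                          mask=er.FixedMask(pmax=0.0, ec50=1000.0, gamma=1.0))
        assert fit.params.p0 == pytest.approx(12 / 40, abs=1e-7)
        assert fit.converged

    def test_log_logistic_fit_matches_logistic_regression_oracle(self):
        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(np.log(800.0), 1.2, 3000))
        p = er.emax_probability(x, er.EmaxParams(0.0, 1.0, 4200.0, 1.21))
        y = (rng.random(x.size) < p).astype(int)
        fit = er.EmaxRiskModel(y, x).fit(mask=er.FixedMask.log_logistic())
        oracle = sm.Logit(y, sm.add_constant(np.log(x))).fit(disp=0)
        slope, intercept = oracle.params[1], oracle.params[0]
        assert fit.params.gamma == pytest.approx(slope, rel=1e-4)
        assert fit.params.ec50 == pytest.approx(np.exp(-intercept / slope), rel=1e-4)
        assert fit.nll == pytest.approx(-oracle.llf, rel=1e-9)

    def test_single_free_parameter_beats_dense_grid_search(self):
        # brute-force oracle over ln(ec50) on a small dataset
        rng = np.random.default_rng(8)
        x = np.exp(rng.normal(np.log(1000.0), 1.0, 50))
        p = er.emax_probability(x, er.EmaxParams(0.0, 1.0, 1200.0, 1.0))
        y = (rng.random(50) < p).astype(int)
        mask = er.FixedMask(p0=0.0, pmax=1.0, gamma=1.0)
        fit = er.fit_emax(_rows(x, y), mask=mask)
        grid_nll = min(
            er.negative_log_likelihood(_rows(x, y), er.EmaxParams(0.0, 1.0, ec, 1.0))
            for ec in np.geomspace(10.0, 1e5, 20_000)
        )
        assert fit.nll <= grid_nll + 1e-6

    def test_row_permutation_leaves_estimates_unchanged(self, small_cohort_rows):
        mask = er.FixedMask.gamma_fixed(1.0)
        fit_a = er.fit_emax(small_cohort_rows, mask=mask)
        rng = np.random.default_rng(1)
        shuffled = list(small_cohort_rows)
        rng.shuffle(shuffled)
        fit_b = er.fit_emax(shuffled, mask=mask)
        # identical up to floating-point summation order
        assert fit_a.nll == pytest.approx(fit_b.nll, abs=1e-6)
        np.testing.assert_allclose(fit_a.params.as_array(), fit_b.params.as_array(),
                                   rtol=1e-4, atol=1e-6)

    def test_all_event_and_all_nonevent_data_rejected(self):
        x = np.geomspace(100.0, 5000.0, 10)
        with pytest.raises(er.NonIdentifiableError):
            er.fit_emax(_rows(x, np.ones(10)))
        with pytest.raises(er.NonIdentifiableError):
            er.fit_emax(_rows(x, np.zeros(10)))

    def test_multistart_agrees_across_restart_seeds(self, small_cohort_rows):
        mask = er.FixedMask.gamma_fixed(1.0)
        nlls = [er.fit_emax(small_cohort_rows, mask=mask,
                            options=er.FitOptions(seed=s)).nll for s in (0, 1, 2)]
        assert max(nlls) - min(nlls) < 1e-6

    def test_fixed_parameters_reported_exactly(self):
        rng = np.random.default_rng(12)
        x = np.exp(rng.normal(np.log(900.0), 1.0, 400))
        p = er.emax_probability(x, er.EmaxParams(0.0, 1.0, 1000.0, 1.0))
        y = (rng.random(400) < p).astype(int)
        fit = er.EmaxRiskModel(y, x).fit(mask=er.FixedMask.log_logistic())
        assert fit.params.p0 == 0.0
        assert fit.params.pmax == 1.0

    def test_estimates_converge_with_sample_size(self):
        """Median EC50 error shrinks monotonically over n in {500, 5e3, 5e4}."""
        base = er.preset_configs()["explorys_child"]
        opts = er.FitOptions(n_starts=2)
        medians = []
        for n in (500, 5000, 50_000):
            errs = []
            for rep in range(20):
                cohort = er.generate_cohort(replace(base, n=n, seed=777 + rep))
                fit = er.EmaxRiskModel.from_rows(cohort.analysis_rows).fit(
                    mask=er.FixedMask.gamma_fixed(1.0), options=opts)
                errs.append(abs(fit.params.ec50 - 3730.0) / 3730.0)
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_summary_mentions_key_quantities(self, explorys_like_fit):
        text = explorys_like_fit.summary()
        assert "ec50" in text and "Log-likelihood" in text
        assert str(explorys_like_fit.n_obs) in text
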