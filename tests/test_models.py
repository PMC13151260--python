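"""Logistic and LASSO-logistic confirmatory models."""

import numpy as np
import pytest

from gaitcausal.cohort import make_binary_design
from gaitcausal.models import (LassoConfig, fit_lasso_logistic, fit_logistic,
                               forest_table, lambda_max)
from gaitcausal.simulate import default_cohort_spec, generate_cohort

from conftest import binary_design_from_arrays


def two_by_two_design(a, b, c, d):
    """a = exposed responders, b = exposed non-, c = unexposed responders,
    d = unexposed non-responders."""
    x = np.r_[np.ones(a + b), np.zeros(c + d)].astype(int)
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)].astype(int)
    return binary_design_from_arrays(x[:, None], y, ["exposure"])


class TestLogistic:
    def test_two_by_two_matches_closed_form(self):
        fit = fit_logistic(two_by_two_design(30, 10, 10, 30))
        assert fit.or_[0] == pytest.approx(9.0, abs=1e-6)   # ad/bc oracle
        assert fit.ci_low[0] < 9.0 < fit.ci_high[0]
        assert fit.p_values[0] < 0.05

    def test_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        design = binary_design_from_arrays(y[:, None], y, ["mirror"])
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_logistic(design)
        assert fit.separation_flag

    def test_single_class_rejected(self):
        design = binary_design_from_arrays(
            np.random.default_rng(0).integers(0, 2, (20, 1)), np.ones(20))
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(design)

    def test_unknown_term_rejected(self, large_design):
        with pytest.raises(KeyError):
            fit_logistic(large_design, ["not_a_column"])

    def test_planted_trunk_or_recovered(self, large_design):
        fit = fit_logistic(large_design, ["sias_trunk_verticality",
                                          "sias_position_sense",
                                          "days_to_ragt"])
        ors = dict(zip(fit.terms, fit.or_))
        assert ors["days_to_ragt"] < 1 < ors["sias_trunk_verticality"]

    def test_wald_ci_coverage(self):
        # 95% CI should contain the true OR in 90-99% of repeated samples
        true_or = 3.0
        beta = np.log(true_or)
        covered = 0
        n_rep, n = 200, 500
        rng = np.random.default_rng(314)
        for _ in range(n_rep):
            x = rng.integers(0, 2, n)
            p = 1.0 / (1.0 + np.exp(-(-beta / 2 + beta * x)))
            y = (rng.uniform(size=n) < p).astype(int)
            fit = fit_logistic(binary_design_from_arrays(x[:, None], y, ["x"]))
            covered += fit.ci_low[0] <= true_or <= fit.ci_high[0]
        assert 0.90 * n_rep <= covered <= 0.99 * n_rep


class TestLasso:
    def test_full_shrinkage_at_large_lambda(self, large_design):
        from gaitcausal.models import _lasso_solve
        Xs = ((large_design.matrix - large_design.matrix.mean())
              / large_design.matrix.std(ddof=0)).to_numpy(float)
        y = np.asarray(large_design.outcome, float)
        coef_inf, _ = _lasso_solve(Xs, y, 100.0 * lambda_max(Xs, y))
        assert np.all(coef_inf == 0.0)
        assert np.all(np.exp(coef_inf) == 1.0)

    def test_lambda_zero_matches_mle(self, fixture_cohort):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = make_binary_design(fixture_cohort)
        terms = ["sias_trunk_verticality", "days_to_ragt", "sias_touch"]
        Xs = ((design.matrix[terms] - design.matrix[terms].mean())
              / design.matrix[terms].std(ddof=0))
        std_design = binary_design_from_arrays(
            np.zeros((len(Xs), len(terms))), design.outcome, terms)
        std_design.matrix = Xs
        mle = fit_logistic(std_design, terms)
        from gaitcausal.models import _lasso_solve
        coef0, _ = _lasso_solve(Xs.to_numpy(float),
                                np.asarray(design.outcome, float), 0.0)
        assert np.abs(coef0 - mle.coef).max() < 1e-4

    def test_path_monotone_in_lambda(self, large_design):
        from gaitcausal.models import _lasso_solve
        Xs = ((large_design.matrix - large_design.matrix.mean())
              / large_design.matrix.std(ddof=0)).to_numpy(float)
        y = np.asarray(large_design.outcome, float)
        lam_hi = lambda_max(Xs, y)
        grid = np.geomspace(lam_hi, lam_hi * 1e-4, 25)
        n_active = [np.count_nonzero(_lasso_solve(Xs, y, lam)[0])
                    for lam in grid]
        # grid is decreasing, so active count must be non-decreasing
        assert all(b >= a for a, b in zip(n_active, n_active[1:]))
        assert n_active[0] == 0

    def test_cv_fit_reports_zeroed_terms_as_or_one(self, fixture_cohort):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = make_binary_design(fixture_cohort)
        fit = fit_lasso_logistic(design, config=LassoConfig(
            n_bootstrap_ci=25, seed=1))
        assert fit.lambda_star in fit.lambda_grid
        zeroed = fit.coef == 0
        assert np.all(fit.or_[zeroed] == 1.0)
        assert np.all(np.isnan(fit.ci_low[zeroed]))
        nz = ~zeroed
        if nz.any():
            assert np.all(fit.ci_low[nz] <= fit.or_[nz] * 1.5)

    def test_selection_consistency_small(self):
        # 3 planted signals among independent noise columns: signals kept,
        # most noise dropped (full 10-seed version in the acceptance suite)
        hits = 0
        for s in range(3):
            design = _three_signal_design(seed=s)
            fit = fit_lasso_logistic(design, config=LassoConfig(
                n_bootstrap_ci=0, seed=s, rule="1se"))
            sel = set(fit.selected)
            signals_kept = {"sias_trunk_verticality", "sias_position_sense",
                            "days_to_ragt"} <= sel
            noise = set(fit.terms) - {"sias_trunk_verticality",
                                      "sias_position_sense", "days_to_ragt"}
            noise_dropped = len(noise - sel)
            hits += signals_kept and noise_dropped >= 4
        assert hits >= 2


def _three_signal_design(seed: int, n: int = 5000):
    spec = default_cohort_spec(n, seed=seed)
    spec.outcome_coefs = {
        "sias_trunk_verticality": float(np.log(7.79)),
        "sias_position_sense": float(np.log(3.37)),
        "days_to_ragt": float(np.log(0.19)),
    }
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = make_binary_design(generate_cohort(spec))
    keep = ["sias_trunk_verticality", "sias_position_sense", "days_to_ragt",
            "age", "sex", "stroke_type", "affected_side",
            "fim_expression", "fim_social_interaction"]
    design.matrix = design.matrix[keep]
    return design


class TestForestTable:
    def test_rows_follow_selection_order(self, large_design):
        fit = fit_logistic(large_design, ["days_to_ragt",
                                          "sias_trunk_verticality"])
        tab = forest_table(fit, ["sias_trunk_verticality", "days_to_ragt"])
        assert list(tab["term"]) == ["sias_trunk_verticality", "days_to_ragt"]
        assert {"or", "ci_low", "ci_high", "p"} <= set(tab.columns)
        row = tab.iloc[0]
        assert row["ci_low"] <= row["or"] <= row["ci_high"]

    def test_empty_selection_gives_empty_table(self, large_design):
        fit = fit_logistic(large_design, ["days_to_ragt"])
        assert len(forest_table(fit, [])) == 0

    def test_lasso_zeroed_term_row(self, fixture_cohort):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            design = make_binary_design(fixture_cohort)
        fit = fit_lasso_logistic(design, config=LassoConfig(
            n_bootstrap_ci=0, seed=2))
        tab = forest_table(fit)
        zeroed = tab[tab["or"] == 1.0]
        if len(zeroed):
            assert zeroed["ci_low"].isna().all()
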