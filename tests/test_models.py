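import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from surrocohort.models import (FitComponent, FitResult, ModelError,
                                digit_preference_profile, estimate_propensity,
                                fit_conditional_logistic, fit_count_model,
                                fit_cox_tv, select_covariates,
                                wilcoxon_paired, zinb_marginal_zero_fraction,
                                _propensity_design)
from surrocohort.simulate import simulate_zinb_outcomes


# ---------------------------------------------------------------------------
# Cox: brute-force partial-likelihood oracle


def cox_partial_loglik(df, beta):
    """Hand-written counting-process partial log-likelihood (no ties)."""
    ll = 0.0
    for _, g in df.groupby("stratum"):
        for ev in g[g["event"]].itertuples():
            t = ev.t_stop
            risk = g[(g["t_start"] < t) & (t <= g["t_stop"])]
            ll += (beta * ev.statin_exposed
                   - math.log(np.exp(beta * risk["statin_exposed"]).sum()))
    return ll


def toy_records():
    rows = [
        ("P1", "s", 0, 50, 0.0, False),
        ("P1", "s", 50, 150, 1.0, True),
        ("P2", "s", 0, 120, 0.0, True),
        ("P3", "s", 0, 200, 0.0, False),
        ("P4", "s", 0, 90, 1.0, True),
        ("P5", "s", 0, 300, 1.0, False),
    ]
    return pd.DataFrame(rows, columns=["patient_id", "stratum", "t_start",
                                       "t_stop", "statin_exposed", "event"])


class TestCoxTimeVarying:
    def test_toy_fit_matches_partial_likelihood_maximiser(self):
        df = toy_records()
        fit = fit_cox_tv(df, [])
        got = math.log(fit.term("statin_exposed").estimate)
        res = optimize.minimize_scalar(lambda b: -cox_partial_loglik(df, b),
                                       bounds=(-5, 5), method="bounded",
                                       options={"xatol": 1e-10})
        assert abs(got - res.x) < 1e-4

    def test_stratification_changes_the_risk_sets(self):
        df = toy_records()
        strat = df.copy()
        strat.loc[strat["patient_id"].isin(["P4", "P5"]), "stratum"] = "t"
        fit_pooled = fit_cox_tv(df, [])
        fit_strat = fit_cox_tv(strat, [])
        oracle = optimize.minimize_scalar(
            lambda b: -cox_partial_loglik(strat, b),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10})
        assert abs(math.log(fit_strat.term("statin_exposed").estimate)
                   - oracle.x) < 1e-4
        assert not math.isclose(fit_pooled.term("statin_exposed").estimate,
                                fit_strat.term("statin_exposed").estimate)

    def test_constant_exposure_is_inestimable(self):
        df = toy_records()
        df["statin_exposed"] = 1.0
        with pytest.raises(ModelError, match="statin_exposed"):
            fit_cox_tv(df, [])

    def test_no_events_is_model_error(self):
        df = toy_records()
        df["event"] = False
        with pytest.raises(ModelError, match="no events"):
            fit_cox_tv(df, [])

    def test_ci_contains_estimate(self):
        fit = fit_cox_tv(toy_records(), [])
        c = fit.term("statin_exposed")
        assert c.ci_low <= c.estimate <= c.ci_high
        assert 0 <= c.p <= 1


class TestCovariateSelection:
    def _fit(self, pvals):
        comps = [FitComponent("hazard", name, 1.0, 0.9, 1.1, p)
                 for name, p in pvals.items()]
        return FitResult("cox_tv", comps)

    def test_strict_threshold(self):
        fit = self._fit({"statin_exposed": 0.8, "a": 0.09, "b": 0.11,
                         "c": 0.10})
        kept = select_covariates(fit, alpha=0.1, forced=["statin_exposed"])
        assert kept == ["statin_exposed", "a"]  # p=0.10 and 0.11 dropped

    def test_forced_terms_survive_any_p(self):
        fit = self._fit({"statin_exposed": 0.99})
        assert select_covariates(fit, forced=["statin_exposed"]) == [
            "statin_exposed"]

    def test_empty_components_yield_forced_only(self):
        assert select_covariates(FitResult("cox_tv", []), forced=["x"]) == ["x"]


# ---------------------------------------------------------------------------
# Conditional logistic


def pair_table(n10, n01, n11=7, n00=9):
    rows = []
    pid = 0
    for count, (ye, yu) in [(n11, (1, 1)), (n00, (0, 0)), (n10, (1, 0)),
                            (n01, (0, 1))]:
        for _ in range(count):
            rows.append((pid, "exposed", 1.0, ye))
            rows.append((pid, "unexposed", 0.0, yu))
            pid += 1
    return pd.DataFrame(rows, columns=["pair_id", "arm", "exposed", "any_os"])


def conditional_loglik(outcomes, cols, beta):
    """Independent oracle: sum over discordant pairs of the within-pair
    conditional probability of the observed case."""
    ll = 0.0
    for _, g in outcomes.groupby("pair_id"):
        y = g["any_os"].to_numpy()
        if y.sum() != 1:
            continue
        eta = g[cols].to_numpy(dtype=float) @ beta
        ll += eta[y == 1][0] - np.logaddexp(eta[0], eta[1])
    return ll


class TestConditionalLogistic:
    def test_closed_form_equals_discordant_ratio(self):
        fit = fit_conditional_logistic(pair_table(10, 5))
        assert fit.term("exposed").estimate == pytest.approx(2.0, abs=1e-12)

    def test_all_concordant_is_error(self):
        with pytest.raises(ModelError, match="discordant"):
            fit_conditional_logistic(pair_table(0, 0))

    def test_one_sided_discordance_is_error(self):
        with pytest.raises(ModelError):
            fit_conditional_logistic(pair_table(8, 0))

    def test_closed_form_agrees_with_statsmodels(self, rng):
        # dual route: exact formula vs numerical conditional MLE
        import statsmodels.api as sm
        from statsmodels.discrete.conditional_models import ConditionalLogit
        for _ in range(5):
            n10, n01 = rng.integers(3, 25, 2)
            tbl = pair_table(int(n10), int(n01))
            ours = math.log(fit_conditional_logistic(tbl)
                            .term("exposed").estimate)
            res = ConditionalLogit(tbl["any_os"].to_numpy(),
                                   tbl[["exposed"]].to_numpy(),
                                   groups=tbl["pair_id"].to_numpy()).fit(disp=0)
            assert abs(ours - res.params[0]) < 1e-4

    def test_covariate_fit_matches_likelihood_maximiser(self, rng):
        tbl = pair_table(12, 8, n11=5, n00=5)
        tbl["z"] = rng.integers(0, 2, len(tbl)).astype(float)
        fit = fit_conditional_logistic(tbl, ["z"])
        got = np.array([math.log(fit.term("exposed").estimate),
                        math.log(fit.term("z").estimate)])
        res = optimize.minimize(
            lambda b: -conditional_loglik(tbl, ["exposed", "z"], b),
            x0=np.zeros(2), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(got, res.x, atol=1e-4)


# ---------------------------------------------------------------------------
# Count models


class TestCountModels:
    def test_offset_identity_doubling_followup_halves_intercept(self, rng):
        df = simulate_zinb_outcomes(800, rng, structural_zero_frac=0.0)
        fit1 = fit_count_model(df, zero_inflated=False)
        df2 = df.assign(followup_days=df["followup_days"] * 2)
        fit2 = fit_count_model(df2, zero_inflated=False)
        ratio = fit2.term("const", "count").estimate / \
            fit1.term("const", "count").estimate
        assert ratio == pytest.approx(0.5, rel=1e-3)

    def test_all_zero_outcomes_degenerate(self):
        df = pd.DataFrame({"exposed": [1.0, 0.0], "followup_days": [365, 365],
                           "os_days": [0, 0]})
        with pytest.raises(ModelError):
            fit_count_model(df, zero_inflated=True)

    def test_plain_nb_recovers_rate_ratio(self, rng):
        df = simulate_zinb_outcomes(6000, rng, rate_ratio=0.7,
                                    structural_zero_frac=0.0)
        fit = fit_count_model(df, zero_inflated=False)
        assert fit.term("exposed", "count").estimate == pytest.approx(
            0.7, abs=0.08)

    def test_zinb_reports_both_parts_and_marginal_zeros(self, rng):
        df = simulate_zinb_outcomes(4000, rng, rate_ratio=0.88,
                                    structural_zero_frac=0.8)
        fit = fit_count_model(df, zero_inflated=True)
        assert fit.converged
        assert {c.component for c in fit.components} == {"zero_inflation",
                                                         "count"}
        empirical = (df["os_days"] == 0).mean()
        assert abs(zinb_marginal_zero_fraction(fit) - empirical) < 0.02


# ---------------------------------------------------------------------------
# Wilcoxon


class TestWilcoxon:
    def test_all_zero_differences_error(self):
        with pytest.raises(ModelError):
            wilcoxon_paired([0.0, 0.0, 0.0])

    def test_exact_p_matches_sign_enumeration(self):
        diffs = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0])
        _, p = wilcoxon_paired(diffs)
        ranks = stats.rankdata(np.abs(diffs))
        w_obs = ranks[diffs > 0].sum()
        dist = [sum(r for r, s in zip(ranks, signs) if s)
                for signs in itertools.product([True, False], repeat=6)]
        dist = np.array(dist)
        p_le = np.mean(dist <= w_obs)
        p_ge = np.mean(dist >= w_obs)
        assert p == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_sign_flip_symmetry(self, rng):
        d = rng.normal(0.3, 1.0, 25)
        _, p1 = wilcoxon_paired(d)
        _, p2 = wilcoxon_paired(-d)
        assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# Propensity


class TestPropensity:
    def _frame(self, rng, n=400, shift=0.0):
        age = rng.integers(30, 80, n).astype(float)
        z = rng.random(n) < 0.5
        cvd = (rng.random(n) < 0.3 + shift * z).astype(float)
        return pd.DataFrame({"exposed": z.astype(float), "age_years": age,
                             "cond_cvd": cvd})

    def test_intercept_only_scores_equal_exposed_fraction(self, rng):
        df = self._frame(rng)
        df["cond_cvd"] = 1.0  # constant covariate is dropped from the design
        pr = estimate_propensity(df, ["cond_cvd"], age_col="missing")
        assert np.allclose(pr.scores, df["exposed"].mean(), atol=1e-6)

    def test_design_contains_age_squared_and_interactions(self, rng):
        df = self._frame(rng)
        X, names = _propensity_design(df, ["age_years", "cond_cvd"],
                                      "age_years")
        assert "age_years^2" in names
        assert "age_years:cond_cvd" in names

    def test_exchangeable_groups_have_high_overlap(self, rng):
        df = self._frame(rng, n=2000, shift=0.0)
        pr = estimate_propensity(df, ["age_years", "cond_cvd"])
        assert pr.overlap_coefficient > 0.9
        assert ((pr.scores > 0) & (pr.scores < 1)).all()

    def test_too_few_per_group_is_error(self, rng):
        df = self._frame(rng, n=4)
        df["exposed"] = [1.0, 0.0, 0.0, 0.0]
        with pytest.raises(ModelError):
            estimate_propensity(df, ["age_years"])


# ---------------------------------------------------------------------------
# Digit preference


class TestDigitPreference:
    def test_direct_counts(self):
        prof = digit_preference_profile([7, 14, 30, 30, 8], n_resamples=50)
        assert prof.count_mult7 == 2
        assert prof.count_mult30 == 2
        assert prof.n == 5
        assert sum(prof.histogram.values()) == 5

    def test_empty_input_no_test(self):
        prof = digit_preference_profile([])
        assert prof.n == 0 and math.isnan(prof.p_value)

    def test_uniform_durations_not_flagged(self, rng):
        d = rng.integers(1, 101, 3000)
        prof = digit_preference_profile(d, n_resamples=400, seed=rng)
        assert prof.p_value > 0.05
        assert abs(prof.excess) < 0.05

    def test_heaped_durations_flagged(self, rng):
        base = rng.integers(10, 60, 500)
        heaped = np.where(rng.random(500) < 0.5,
                          (base // 7).clip(min=1) * 7, base)
        prof = digit_preference_profile(heaped, n_resamples=400, seed=rng)
        assert prof.p_value < 0.05
        assert prof.excess > 0
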