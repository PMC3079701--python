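"""Statistical models and diagnostics for both cohort designs.

Estimation is delegated to the standard survival/count-model stacks —
lifelines for the stratified time-varying Cox model (Efron tie handling),
statsmodels for conditional logistic, negative binomial, zero-inflated
negative binomial and the propensity logistic, scipy for the paired Wilcoxon
signed-rank test — behind a uniform :class:`FitResult` surface.  All effect
estimates are reported on the ratio scale with 95% confidence bounds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit
from statsmodels.discrete.count_model import ZeroInflatedNegativeBinomialP

from lifelines import CoxTimeVaryingFitter
from lifelines.exceptions import ConvergenceError


class ModelError(ValueError):
    """The requested model is degenerate or inestimable on these data."""


@dataclass(frozen=True)
class FitComponent:
    """One reported parameter: estimate on the ratio scale with 95% CI and p."""

    component: str
    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class FitResult:
    """Effect estimates from one model fit.

    ``components`` holds one entry per (model part, parameter); multi-part
    models (zero-inflated NB) report the logit and count parts separately.
    """

    model_label: str
    components: list[FitComponent] = field(default_factory=list)
    n_observations: int = 0
    n_events_or_nonzero: int = 0
    converged: bool = True

    def term(self, name: str, component: str | None = None) -> FitComponent:
        for c in self.components:
            if c.term == name and (component is None
                                   or c.component == component):
                return c
        raise KeyError(f"no component for term {name!r}"
                       + (f" in part {component!r}" if component else ""))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.components])


def _safe_exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:
        return math.inf


def _ratio_components(part: str, names, coefs, ses) -> list[FitComponent]:
    out = []
    z975 = stats.norm.ppf(0.975)
    for name, b, se in zip(names, coefs, ses):
        if not np.isfinite(se) or se <= 0:
            out.append(FitComponent(part, name, _safe_exp(b), math.nan,
                                    math.nan, math.nan))
            continue
        z = b / se
        p = 2 * stats.norm.sf(abs(z))
        out.append(FitComponent(part, name, _safe_exp(b),
                                _safe_exp(b - z975 * se),
                                _safe_exp(b + z975 * se), p))
    return out


# ---------------------------------------------------------------------------
# Stratified time-varying Cox


def fit_cox_tv(records: pd.DataFrame, covariates: list[str] | None = None,
               exposure: str = "statin_exposed", strata: str = "stratum",
               ) -> FitResult:
    """Stratified Cox model on counting-process (start, stop] rows.

    Partial-likelihood estimation with stratum-specific baseline hazards and
    Efron tie handling; returns the hazard ratio, 95% CI and Wald p for the
    exposure and every covariate.

    Raises :class:`ModelError` when there are no events or a requested column
    is constant (inestimable); non-convergence is returned as a flagged
    result, never silently.
    """
    covariates = list(covariates or [])
    terms = [exposure] + covariates
    n_events = int(records["event"].sum())
    if n_events == 0:
        raise ModelError("no events in the dataset")
    for col in terms:
        if records[col].nunique() <= 1:
            raise ModelError(f"covariate {col!r} is constant; inestimable")
    df = records[["patient_id", "t_start", "t_stop", "event", strata]
                 + terms].copy()
    df["event"] = df["event"].astype(int)
    # a light ridge fallback handles monotone partial likelihoods (a binary
    # adjuster whose carriers all reach events first drives its coefficient
    # to infinity)
    for label, penalizer in [("cox_tv", 0.0), ("cox_tv_ridge", 1e-3)]:
        ctv = CoxTimeVaryingFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ctv.fit(df, id_col="patient_id", event_col="event",
                        start_col="t_start", stop_col="t_stop",
                        strata=[strata])
        except (ConvergenceError, np.linalg.LinAlgError):
            continue
        summ = ctv.summary
        comps = _ratio_components("hazard", summ.index.tolist(),
                                  summ["coef"].to_numpy(),
                                  summ["se(coef)"].to_numpy())
        return FitResult(label, comps, len(records), n_events, converged=True)
    return FitResult("cox_tv", [], len(records), n_events, converged=False)


def select_covariates(full_fit: FitResult, alpha: float = 0.1,
                      forced: list[str] | None = None) -> list[str]:
    """Covariates retained from a full-model fit: p < ``alpha`` (strict), plus
    every name in ``forced`` (the exposure is always forced) regardless of p."""
    forced = list(forced or [])
    kept = list(forced)
    for c in full_fit.components:
        if c.term in kept:
            continue
        if np.isfinite(c.p) and c.p < alpha:
            kept.append(c.term)
    return kept


# ---------------------------------------------------------------------------
# Conditional logistic for 1:1 pairs


def discordant_counts(outcomes: pd.DataFrame, y: str = "any_os"
                      ) -> tuple[int, int]:
    """(n10, n01): pairs where only the exposed / only the unexposed member
    has the outcome."""
    wide = outcomes.pivot_table(index="pair_id", columns="arm", values=y,
                                aggfunc="first")
    e = wide["exposed"].astype(bool)
    u = wide["unexposed"].astype(bool)
    return int((e & ~u).sum()), int((~e & u).sum())


def fit_conditional_logistic(outcomes: pd.DataFrame,
                             covariates: list[str] | None = None,
                             y: str = "any_os") -> FitResult:
    """Conditional logistic regression within 1:1 matched pairs.

    With no covariates the conditional likelihood depends only on discordant
    pairs and the exposure odds ratio has the exact closed form ``n10/n01``
    (classical matched-pairs estimator, Wald SE ``sqrt(1/n10 + 1/n01)``),
    which is returned directly; with covariates the conditional likelihood is
    maximised numerically (statsmodels).
    """
    covariates = list(covariates or [])
    n10, n01 = discordant_counts(outcomes, y)
    if n10 + n01 == 0:
        raise ModelError("no discordant pairs; conditional OR inestimable")
    if not covariates:
        if n10 == 0 or n01 == 0:
            raise ModelError("all discordant pairs point one way; "
                             "conditional OR diverges")
        beta = math.log(n10 / n01)
        se = math.sqrt(1.0 / n10 + 1.0 / n01)
        comps = _ratio_components("odds", ["exposed"], [beta], [se])
        return FitResult("conditional_logit", comps,
                         n_observations=outcomes["pair_id"].nunique(),
                         n_events_or_nonzero=n10 + n01)
    cols = ["exposed"] + covariates
    model = ConditionalLogit(outcomes[y].astype(int).to_numpy(),
                             outcomes[cols].astype(float).to_numpy(),
                             groups=outcomes["pair_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=0)
    comps = _ratio_components("odds", cols, res.params, res.bse)
    retvals = getattr(res, "mle_retvals", None) or {}
    return FitResult("conditional_logit", comps,
                     n_observations=outcomes["pair_id"].nunique(),
                     n_events_or_nonzero=n10 + n01,
                     converged=bool(retvals.get("converged", True)))


# ---------------------------------------------------------------------------
# (Zero-inflated) negative binomial with offset


def fit_count_model(outcomes: pd.DataFrame, covariates: list[str] | None = None,
                    zero_inflated: bool = True, y: str = "os_days",
                    exposure: str = "exposed",
                    followup: str = "followup_days") -> FitResult:
    """Negative-binomial model of days on therapy, offset by log follow-up.

    ``zero_inflated=True`` fits a two-part mixture: a logit for membership in
    the structural-zero (never-treated) class and a negative binomial for days
    among the susceptible, the offset applying to the count part.  Components
    are reported as ``zero_inflation`` odds ratios (odds of being a structural
    zero) and ``count`` rate ratios.  ``zero_inflated=False`` fits a plain NB.

    Rows with zero follow-up carry no information and are dropped; all-zero
    outcomes are degenerate and raise; non-convergence is flagged, not silent.
    """
    covariates = list(covariates or [])
    df = outcomes[outcomes[followup] > 0]
    yv = df[y].to_numpy(dtype=float)
    if len(df) == 0 or (yv > 0).sum() == 0:
        raise ModelError("no nonzero outcomes; count model degenerate")
    cols = [exposure] + covariates
    X = sm.add_constant(df[cols].astype(float).to_numpy())
    names = ["const"] + cols
    offset = np.log(df[followup].to_numpy(dtype=float))
    nonzero = int((yv > 0).sum())

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nb = sm.NegativeBinomial(yv[yv > 0], X[yv > 0],
                                 offset=offset[yv > 0]).fit(disp=0)
        if not zero_inflated:
            nb_all = sm.NegativeBinomial(yv, X, offset=offset).fit(disp=0)
            comps = _ratio_components("count", names, nb_all.params[:-1],
                                      nb_all.bse[:-1])
            res = FitResult("negative_binomial", comps, len(df), nonzero,
                            bool(nb_all.mle_retvals.get("converged", True)))
            res.dispersion = float(nb_all.params[-1])
            return res
        logit = sm.Logit((yv == 0).astype(float), X).fit(disp=0)
        start = np.r_[logit.params, nb.params[:-1], max(nb.params[-1], 0.05)]
        model = ZeroInflatedNegativeBinomialP(yv, X, exog_infl=X,
                                              offset=offset, inflation="logit")
        res = model.fit(start_params=start, method="bfgs", maxiter=500,
                        disp=0)
        if not res.mle_retvals.get("converged", True):
            res = model.fit(start_params=res.params, method="nm",
                            maxiter=2000, disp=0)
            res = model.fit(start_params=res.params, method="bfgs",
                            maxiter=500, disp=0)
    k = X.shape[1]
    params, bse = np.asarray(res.params), np.asarray(res.bse)
    comps = (_ratio_components("zero_inflation", names, params[:k], bse[:k])
             + _ratio_components("count", names, params[k:2 * k],
                                 bse[k:2 * k]))
    out = FitResult("zinb", comps, len(df), nonzero,
                    bool(res.mle_retvals.get("converged", True)))
    out.dispersion = float(params[-1])
    out._sm_result = res  # retained for marginal-probability diagnostics
    return out


def zinb_marginal_zero_fraction(fit: FitResult) -> float:
    """Model-implied marginal P(Y=0), averaged over the fitted sample.

    Mixture zero probability: pi_i + (1 - pi_i) * NB(0 | mu_i, alpha).
    """
    res = getattr(fit, "_sm_result", None)
    if res is None:
        raise ModelError("marginal zero fraction requires a zero-inflated fit")
    model = res.model
    k = model.exog.shape[1]
    params = np.asarray(res.params)
    eta_infl = model.exog_infl @ params[:k]
    pi = 1.0 / (1.0 + np.exp(-eta_infl))
    mu = np.exp(model.exog @ params[k:2 * k] + model.offset)
    alpha = max(params[-1], 1e-8)
    nb_n = 1.0 / alpha
    p0 = (nb_n / (nb_n + mu)) ** nb_n
    return float(np.mean(pi + (1 - pi) * p0))


# ---------------------------------------------------------------------------
# Paired Wilcoxon


def wilcoxon_paired(differences, zero_method: str = "wilcox"
                    ) -> tuple[float, float]:
    """Signed-rank test on within-pair differences.

    Zero differences are dropped (``zero_method='wilcox'``; Pratt handling via
    ``zero_method='pratt'``); ties get mid-ranks; the p-value is exact for
    small samples without ties and a normal approximation otherwise.
    """
    d = np.asarray(differences, dtype=float)
    if np.all(d == 0):
        raise ModelError("all paired differences are zero")
    res = stats.wilcoxon(d, zero_method=zero_method, method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Propensity overlap


@dataclass
class PropensityResult:
    """Propensity scores with a between-group overlap summary."""

    scores: np.ndarray
    exposed: np.ndarray
    bin_edges: np.ndarray
    hist_exposed: np.ndarray      # per-group density over shared bins
    hist_unexposed: np.ndarray
    overlap_coefficient: float    # sum of per-bin minimum shares, in [0, 1]
    converged: bool
    separation: bool


def _propensity_design(df: pd.DataFrame, covariates: list[str],
                       age_col: str) -> tuple[np.ndarray, list[str]]:
    """Main effects, all pairwise interactions, and age squared.

    Continuous covariates are centred before interactions are formed to
    reduce collinearity.
    """
    cols, names = [], []
    centred = {}
    for c in covariates:
        v = df[c].to_numpy(dtype=float)
        if len(np.unique(v)) > 2:
            v = v - v.mean()
        centred[c] = v
        cols.append(v)
        names.append(c)
    for i in range(len(covariates)):
        for j in range(i + 1, len(covariates)):
            cols.append(centred[covariates[i]] * centred[covariates[j]])
            names.append(f"{covariates[i]}:{covariates[j]}")
    if age_col in centred:
        cols.append(centred[age_col] ** 2)
        names.append(f"{age_col}^2")
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    # drop constant and duplicate columns (exact collinearity)
    keep, seen = [], []
    for idx in range(X.shape[1]):
        v = X[:, idx]
        if np.ptp(v) == 0:
            continue
        if any(np.array_equal(v, w) for w in seen):
            continue
        keep.append(idx)
        seen.append(v)
    return X[:, keep], [names[i] for i in keep]


def estimate_propensity(df: pd.DataFrame, covariates: list[str],
                        exposure: str = "exposed", age_col: str = "age_years",
                        n_bins: int = 20) -> PropensityResult:
    """Propensity scores from a logistic model of exposure on baseline
    covariates with first-order interactions and age squared, plus an overlap
    diagnostic.

    The overlap coefficient sums, over shared score bins, the minimum of the
    two groups' bin shares: 1 means identical score distributions, 0 disjoint
    support.  Perfect separation is flagged, not raised.
    """
    z = df[exposure].astype(float).to_numpy()
    if (z == 1).sum() < 2 or (z == 0).sum() < 2:
        raise ModelError("need at least 2 patients per exposure group")
    X, _names = _propensity_design(df, covariates, age_col)
    X = sm.add_constant(X, has_constant="add")
    converged, separation = True, False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(z, X).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", True))
            scores = np.asarray(res.predict(X))
            if np.any(scores < 1e-10) or np.any(scores > 1 - 1e-10):
                separation = True
        except Exception:  # perfect separation raises in statsmodels
            separation = True
            converged = False
            scores = np.full(len(z), z.mean())
    scores = np.clip(scores, 1e-10, 1 - 1e-10)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    he = np.histogram(scores[z == 1], bins=edges)[0] / max((z == 1).sum(), 1)
    hu = np.histogram(scores[z == 0], bins=edges)[0] / max((z == 0).sum(), 1)
    overlap = float(np.minimum(he, hu).sum())
    return PropensityResult(scores, z.astype(bool), edges, he, hu, overlap,
                            converged, separation)


# ---------------------------------------------------------------------------
# Digit-preference profiling


@dataclass
class DigitPreferenceProfile:
    """Heaping profile of recorded prescription durations.

    ``excess`` is the share of observations at preferred multiples in excess
    of the local smooth baseline (mean count of the ±2-day neighbours that are
    not themselves preferred values); its p-value comes from a jitter
    resampling null in which each duration is displaced uniformly within ±2
    days, destroying heaping while preserving the coarse shape.
    """

    histogram: dict[int, int]
    n: int
    count_mult7: int
    count_mult10: int
    count_mult30: int
    excess: float
    p_value: float


def _preferred_mask(days: np.ndarray) -> np.ndarray:
    return (days % 7 == 0) | (days % 10 == 0) | (days % 30 == 0)


def _excess_statistic(counts: np.ndarray) -> float:
    """Excess share at preferred multiples over their smooth-neighbour baseline."""
    n = counts.sum()
    if n == 0:
        return 0.0
    days = np.arange(len(counts))
    preferred = _preferred_mask(days) & (days > 0)
    total = 0.0
    for m in np.flatnonzero(preferred):
        neigh = [m + d for d in (-2, -1, 1, 2)
                 if 0 < m + d < len(counts) and not preferred[m + d]]
        baseline = np.mean(counts[neigh]) if neigh else 0.0
        total += counts[m] - baseline
    return float(total / n)


def digit_preference_profile(durations, n_resamples: int = 2000,
                             seed: int | np.random.Generator = 0
                             ) -> DigitPreferenceProfile:
    """Profile heaping of positive integer durations at multiples of 7/10/30.

    Empty input returns an empty profile with no test (p = NaN).
    """
    d = np.asarray(durations, dtype=int)
    if len(d) == 0:
        return DigitPreferenceProfile({}, 0, 0, 0, 0, 0.0, math.nan)
    if (d < 1).any():
        raise ValueError("durations must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    top = int(d.max()) + 3
    counts = np.bincount(d, minlength=top)
    obs = _excess_statistic(counts)
    jitter = rng.integers(-2, 3, size=(n_resamples, len(d)))
    null = np.empty(n_resamples)
    for b in range(n_resamples):
        db = np.maximum(d + jitter[b], 1)
        null[b] = _excess_statistic(np.bincount(db, minlength=top))
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_resamples)
    hist = {int(k): int(v) for k, v in zip(*np.unique(d, return_counts=True))}
    return DigitPreferenceProfile(
        histogram=hist, n=len(d),
        count_mult7=int((d % 7 == 0).sum()),
        count_mult10=int((d % 10 == 0).sum()),
        count_mult30=int((d % 30 == 0).sum()),
        excess=obs, p_value=float(p))
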