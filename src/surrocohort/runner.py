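"""End-to-end study orchestration and the design-comparison experiment.

Each run function takes either a ready :class:`~surrocohort.claims_data.ClaimsBundle`
or a :class:`~surrocohort.simulate.SimulationConfig` (in which case a bundle is
generated first), executes one complete study design, and returns a
:class:`StudyReport` carrying cohort accounting, fitted models and
diagnostics.  A single master seed spawns independent substreams for
simulation, matching order and resampling, so every number in a report is a
deterministic function of (input, seed).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_data import ClaimsBundle, clean_prescriptions, derive_study_anchors
from .design_matched import identify_new_users, match_pairs, matched_outcomes
from .design_tte import (assign_subcohorts, build_cessation_dataset,
                         build_initiation_dataset)
from .episodes import DEFAULT_GRACE_DAYS, build_all_episodes
from .models import (FitResult, ModelError, digit_preference_profile,
                     estimate_propensity, fit_conditional_logistic,
                     fit_count_model, fit_cox_tv, select_covariates,
                     wilcoxon_paired)
from .simulate import OS, STATIN, SimulationConfig, simulate_claims

EXPOSURE_TERM = "statin_exposed"


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit substream seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


@dataclass
class StudyReport:
    """One complete study: cohort accounting, fits, diagnostics, provenance."""

    design: str
    counts: dict = field(default_factory=dict)
    person_time: dict = field(default_factory=dict)
    n_events: dict = field(default_factory=dict)
    fits: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {"design": self.design, "counts": self.counts,
               "person_time": self.person_time, "n_events": self.n_events,
               "provenance": self.provenance, "warnings": self.warnings,
               "fits": {}}
        for label, fit in self.fits.items():
            if isinstance(fit, FitResult):
                out["fits"][label] = {
                    "converged": fit.converged,
                    "n": fit.n_observations,
                    "components": [c.__dict__ for c in fit.components]}
            else:
                out["fits"][label] = fit
        return out

    def to_text(self) -> str:
        lines = [f"design: {self.design}", f"counts: {self.counts}",
                 f"person-time: {self.person_time}",
                 f"events: {self.n_events}"]
        for label, fit in self.fits.items():
            lines.append(f"[{label}]")
            if isinstance(fit, FitResult):
                for c in fit.components:
                    lines.append(
                        f"  {c.component}/{c.term}: {c.estimate:.3f} "
                        f"({c.ci_low:.3f}, {c.ci_high:.3f}) p={c.p:.4f}")
            else:
                lines.append(f"  {fit}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def _provenance(source, seed) -> dict:
    if isinstance(source, SimulationConfig):
        blob = json.dumps(source.to_dict(), sort_keys=True, default=str)
    else:
        blob = f"bundle:{source.n_patients}:{len(source.prescriptions)}"
    return {"seed": seed,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}


def _resolve_bundle(source, rng) -> ClaimsBundle:
    if isinstance(source, SimulationConfig):
        bundle, _ = simulate_claims(source, rng=rng)
        return bundle
    return source


@dataclass
class StudyData:
    """Cleaned bundle with anchors and per-drug episode tables."""

    bundle: ClaimsBundle
    anchors: pd.DataFrame
    os_episodes: pd.DataFrame
    statin_episodes: pd.DataFrame
    cleaning_log: pd.DataFrame


def prepare_study_data(bundle: ClaimsBundle,
                       grace_days: int = DEFAULT_GRACE_DAYS) -> StudyData:
    """Clean prescriptions, derive RA anchors, build OS and statin episodes."""
    cleaned, log = clean_prescriptions(bundle)
    anchors = derive_study_anchors(cleaned)
    return StudyData(
        bundle=cleaned, anchors=anchors,
        os_episodes=build_all_episodes(cleaned, OS, grace_days),
        statin_episodes=build_all_episodes(cleaned, STATIN, grace_days),
        cleaning_log=log)


def _usable_covariates(records: pd.DataFrame, candidates: list[str],
                       min_level: int = 5) -> list[str]:
    """Covariates that vary and have enough mass in each level to estimate."""
    out = []
    for c in candidates:
        v = records[c]
        if v.nunique() <= 1:
            continue
        if set(v.unique()) <= {0.0, 1.0}:
            counts = v.groupby(records["patient_id"]).first().value_counts()
            if counts.min() < min_level:
                continue
        out.append(c)
    return out


def _tte_covariate_candidates(records: pd.DataFrame) -> list[str]:
    base = ["female", "incident_flag", "coverage_full", "plan_ppo", "prior_os"]
    extra = [c for c in records.columns
             if c.startswith("cond_") or c.startswith("drug_")]
    return base + extra


def run_time_to_event_study(source, seed: int = 0, adjust: bool = True,
                            alpha_select: float = 0.1) -> StudyReport:
    """Run the full unmatched time-to-event study.

    Pipeline: anchors -> sub-cohorts -> initiation and cessation
    counting-process datasets -> full Cox fits -> p<``alpha_select``
    covariate retention (exposure always forced) -> final fits.  Calendar
    year of RA index enters the full model as indicator terms.
    """
    sim_seed, = spawn_seeds(seed, 1)
    bundle = _resolve_bundle(source, np.random.default_rng(sim_seed))
    data = prepare_study_data(bundle)
    assignments = assign_subcohorts(data.os_episodes, data.anchors)

    report = StudyReport(design="time_to_event",
                         provenance=_provenance(source, seed))
    report.counts["cohort"] = len(data.anchors)
    report.counts["subcohort_I"] = int((assignments["subcohort"] == "I").sum())
    report.counts["subcohort_II"] = int((assignments["subcohort"] == "II").sum())

    for label, build in [("initiation", build_initiation_dataset),
                         ("cessation", None)]:
        if label == "initiation":
            records, excl = build_initiation_dataset(
                bundle, data.anchors, assignments, data.statin_episodes)
        else:
            records, excl = build_cessation_dataset(
                bundle, data.anchors, assignments, data.os_episodes,
                data.statin_episodes)
        report.counts[f"{label}_excluded"] = len(excl)
        if len(records) == 0:
            report.warnings.append(f"{label}: no analysable patients; skipped")
            continue
        records = _encode_ra_year(records)
        report.person_time[label] = int(
            (records["t_stop"] - records["t_start"]).sum())
        report.n_events[label] = int(records["event"].sum())
        if report.n_events[label] == 0:
            report.warnings.append(f"{label}: no events; model skipped")
            continue
        covs = _usable_covariates(records, _tte_covariate_candidates(records)
                                  + [c for c in records.columns
                                     if c.startswith("ra_year_")])
        try:
            if adjust and covs:
                full = fit_cox_tv(records, covs)
                if not full.converged:
                    # retry without the calendar-year indicators, the usual
                    # culprits for a singular design in small cohorts
                    covs = [c for c in covs if not c.startswith("ra_year_")]
                    full = fit_cox_tv(records, covs)
                    report.warnings.append(
                        f"{label}: full model refitted without calendar-year "
                        "terms")
                report.fits[f"{label}_full"] = full
                if full.converged:
                    kept = select_covariates(full, alpha_select,
                                             forced=[EXPOSURE_TERM])
                    kept = [k for k in kept if k != EXPOSURE_TERM]
                else:
                    kept = []
                report.fits[f"{label}_selected"] = fit_cox_tv(records, kept)
            else:
                report.fits[f"{label}_selected"] = fit_cox_tv(records, [])
        except ModelError as err:
            report.warnings.append(f"{label}: {err}")
    return report


def _encode_ra_year(records: pd.DataFrame) -> pd.DataFrame:
    if "ra_year" not in records.columns:
        return records
    records = records.copy()
    years = sorted(records["ra_year"].unique())
    for y in years[1:]:  # first year is the reference level
        records[f"ra_year_{y}"] = (records["ra_year"] == y).astype(float)
    return records


def _matched_covariate_candidates(outcomes: pd.DataFrame) -> list[str]:
    base = ["female", "coverage_full", "plan_ppo", "prior_os", "os_run_in"]
    extra = [c for c in outcomes.columns
             if c.startswith("cond_") or c.startswith("drug_")]
    return base + extra


def _screen_part_covariates(outcomes: pd.DataFrame, candidates: list[str],
                            alpha: float = 0.1) -> list[str]:
    """Per-part covariate screening for the zero-inflated model.

    Binary part: multivariable logistic of any-OS on the candidates; count
    part: multivariable NB of OS days with offset.  Covariates reaching
    p < alpha in either screening model are retained (union, since the
    fitted mixture uses one design matrix for both parts).
    """
    import statsmodels.api as sm

    kept: list[str] = []
    df = outcomes[outcomes["followup_days"] > 0]
    X = sm.add_constant(df[candidates].astype(float).to_numpy())
    try:
        logit = sm.Logit(df["any_os"].astype(float).to_numpy(), X).fit(disp=0)
        for name, p in zip(candidates, logit.pvalues[1:]):
            if p < alpha:
                kept.append(name)
    except Exception:
        pass
    try:
        nb = sm.NegativeBinomial(
            df["os_days"].to_numpy(dtype=float), X,
            offset=np.log(df["followup_days"].to_numpy(dtype=float))
        ).fit(disp=0)
        for name, p in zip(candidates, nb.pvalues[1:-1]):
            if p < alpha and name not in kept:
                kept.append(name)
    except Exception:
        pass
    return kept


def run_matched_study(source, seed: int = 0, adjust: bool = True,
                      run_in_days: int = 90, window_days: int = 365
                      ) -> StudyReport:
    """Run the full matched new-user study.

    Pipeline: new-user identification -> 1:1 sex/exact-age matching ->
    run-in/observation outcomes -> conditional logistic (binary outcome),
    paired Wilcoxon + unadjusted NB + adjusted zero-inflated NB (days on
    therapy) -> propensity-overlap diagnostic -> digit-preference profile.
    """
    sim_seed, match_seed, resample_seed = spawn_seeds(seed, 3)
    bundle = _resolve_bundle(source, np.random.default_rng(sim_seed))
    data = prepare_study_data(bundle)
    report = StudyReport(design="matched_new_user",
                         provenance=_provenance(source, seed))

    exposed = identify_new_users(bundle := data.bundle, data.anchors)
    pairs, dropped = match_pairs(bundle, data.anchors, exposed,
                                 seed=np.random.default_rng(match_seed))
    report.counts["eligible_exposed"] = len(exposed)
    report.counts["pairs"] = len(pairs)
    report.counts["exposed_dropped"] = len(dropped)
    if len(pairs) == 0:
        report.warnings.append("zero matched pairs; analyses skipped")
        return report

    outcomes = matched_outcomes(bundle, pairs, data.os_episodes,
                                run_in_days, window_days)
    for arm in ("exposed", "unexposed"):
        sub = outcomes[outcomes["arm"] == arm]
        report.person_time[arm] = int(sub["followup_days"].sum())
        report.n_events[f"{arm}_any_os"] = int(sub["any_os"].sum())

    candidates = _usable_covariates(outcomes,
                                    _matched_covariate_candidates(outcomes))
    try:
        report.fits["binary_crude"] = fit_conditional_logistic(outcomes)
    except ModelError as err:
        report.warnings.append(f"binary_crude: {err}")
    if adjust and candidates:
        try:
            report.fits["binary_adjusted"] = fit_conditional_logistic(
                outcomes, candidates)
        except (ModelError, Exception) as err:
            report.warnings.append(f"binary_adjusted: {err}")

    wide = outcomes.pivot_table(index="pair_id", columns="arm",
                                values=["os_days", "followup_days"],
                                aggfunc="first")
    both = (wide[("followup_days", "exposed")] > 0) & \
           (wide[("followup_days", "unexposed")] > 0)
    prop = (wide["os_days"] / wide["followup_days"])[both]
    diffs = (prop["exposed"] - prop["unexposed"]).to_numpy()
    try:
        stat, p = wilcoxon_paired(diffs)
        report.fits["wilcoxon"] = {"statistic": stat, "p": p,
                                   "n_pairs": int(both.sum())}
    except ModelError as err:
        report.warnings.append(f"wilcoxon: {err}")

    try:
        report.fits["count_nb_crude"] = fit_count_model(
            outcomes, zero_inflated=False)
    except ModelError as err:
        report.warnings.append(f"count_nb_crude: {err}")
    try:
        kept = (_screen_part_covariates(outcomes, candidates)
                if adjust and candidates else [])
        report.fits["count_zinb"] = fit_count_model(outcomes, kept,
                                                    zero_inflated=True)
    except ModelError as err:
        report.warnings.append(f"count_zinb: {err}")

    try:
        prop_covs = candidates + ["age_years"]
        pr = estimate_propensity(outcomes, prop_covs)
        report.diagnostics["propensity_overlap"] = pr.overlap_coefficient
        report.diagnostics["propensity_separation"] = pr.separation
    except ModelError as err:
        report.warnings.append(f"propensity: {err}")

    matched_ids = set(outcomes["patient_id"])
    os_rx = bundle.prescriptions[
        (bundle.prescriptions["drug_class"] == OS)
        & bundle.prescriptions["patient_id"].isin(matched_ids)]
    profile = digit_preference_profile(
        os_rx["days_supplied"].to_numpy(),
        seed=np.random.default_rng(resample_seed))
    report.diagnostics["digit_preference"] = {
        "n": profile.n, "mult7": profile.count_mult7,
        "mult10": profile.count_mult10, "mult30": profile.count_mult30,
        "excess": profile.excess, "p": profile.p_value,
        "flagged": (profile.p_value < 0.05
                    if not math.isnan(profile.p_value) else False)}
    return report


# ---------------------------------------------------------------------------
# Operating characteristics


SCENARIOS = ("null", "effect", "confounded_null")


def scenario_config(name: str, n_patients: int = 1000,
                    **overrides) -> SimulationConfig:
    """Preset simulator configurations for the design-comparison experiment.

    ``null``: no exposure effect, no confounding (size check);
    ``effect``: protective exposure (log HR = log 0.7), no confounding;
    ``confounded_null``: no exposure effect, confounders acting on both the
    statin-initiation hazard and the flare intensity.
    """
    if name == "null":
        kw = dict(statin_flare_logHR=0.0, confounder_logHRs={})
    elif name == "effect":
        kw = dict(statin_flare_logHR=math.log(0.7), confounder_logHRs={})
    elif name == "confounded_null":
        kw = dict(statin_flare_logHR=0.0)
    else:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    kw.update(overrides)
    return SimulationConfig(n_patients=n_patients, **kw)


@dataclass
class OperatingCharacteristics:
    """Monte-Carlo operating characteristics of one design in one scenario."""

    scenario: str
    design: str
    n_replicates: int
    n_fitted: int
    rejection_rate: float
    mean_log_effect: float
    empirical_se: float
    ci_coverage: float | None   # of the scenario's true log HR; None when the
                                # design's estimand is not on that scale


def _initiation_estimate(bundle) -> tuple[float, float, float] | None:
    """Crude initiation-design Cox estimate: (log HR, SE, p)."""
    data = prepare_study_data(bundle)
    assignments = assign_subcohorts(data.os_episodes, data.anchors)
    records, _ = build_initiation_dataset(bundle, data.anchors, assignments,
                                          data.statin_episodes)
    if len(records) == 0 or records["event"].sum() == 0:
        return None
    try:
        fit = fit_cox_tv(records, [])
    except ModelError:
        return None
    if not fit.converged:
        return None
    c = fit.term(EXPOSURE_TERM)
    if not (np.isfinite(c.ci_low) and np.isfinite(c.ci_high)):
        return None
    log_hr = math.log(c.estimate)
    se = (math.log(c.ci_high) - math.log(c.ci_low)) / (2 * 1.959963984540054)
    return log_hr, se, c.p


def _matched_estimate(bundle, match_seed: int
                      ) -> tuple[float, float, float] | None:
    """Crude matched-design conditional-logistic estimate: (log OR, SE, p)."""
    data = prepare_study_data(bundle)
    exposed = identify_new_users(data.bundle, data.anchors)
    pairs, _ = match_pairs(data.bundle, data.anchors, exposed,
                           seed=np.random.default_rng(match_seed))
    if len(pairs) == 0:
        return None
    outcomes = matched_outcomes(data.bundle, pairs, data.os_episodes)
    try:
        fit = fit_conditional_logistic(outcomes)
    except ModelError:
        return None
    c = fit.term("exposed")
    log_or = math.log(c.estimate)
    se = (math.log(c.ci_high) - math.log(c.ci_low)) / (2 * 1.959963984540054)
    return log_or, se, c.p


def run_operating_characteristics(scenarios=SCENARIOS, n_replicates: int = 100,
                                  n_patients: int = 1000, seed: int = 0,
                                  alpha: float = 0.05
                                  ) -> list[OperatingCharacteristics]:
    """Size/power/bias/coverage of both designs on fresh simulated cohorts.

    For each scenario and replicate, one bundle is simulated and both designs
    are run with crude (exposure-only) fits; per design the Wald rejection
    rate at ``alpha``, mean log effect, empirical SE over replicates, and —
    for the initiation design, whose estimand is the flare-intensity log HR —
    95% CI coverage of the scenario truth are tabulated side by side.  No
    composite "winner" score is computed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    z975 = 1.959963984540054
    results = []
    seeds = spawn_seeds(seed, len(list(scenarios)))
    for scen, scen_seed in zip(scenarios, seeds):
        truth = scenario_config(scen).statin_flare_logHR
        rng = np.random.default_rng(scen_seed)
        rows = {"initiation": [], "matched": []}
        for _ in range(n_replicates):
            cfg = scenario_config(scen, n_patients,
                                  seed=int(rng.integers(2**31)))
            bundle, _ = simulate_claims(cfg)
            est = _initiation_estimate(bundle)
            if est is not None:
                rows["initiation"].append(est)
            est = _matched_estimate(bundle, int(rng.integers(2**31)))
            if est is not None:
                rows["matched"].append(est)
        for design, fitted in rows.items():
            if not fitted:
                results.append(OperatingCharacteristics(
                    scen, design, n_replicates, 0, math.nan, math.nan,
                    math.nan, None))
                continue
            arr = np.array(fitted)
            logs, ses, ps = arr[:, 0], arr[:, 1], arr[:, 2]
            coverage = None
            if design == "initiation":
                coverage = float(np.mean((logs - z975 * ses <= truth)
                                         & (truth <= logs + z975 * ses)))
            results.append(OperatingCharacteristics(
                scen, design, n_replicates, len(fitted),
                float(np.mean(ps < alpha)), float(np.mean(logs)),
                float(np.std(logs, ddof=1)) if len(logs) > 1 else math.nan,
                coverage))
    return results
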