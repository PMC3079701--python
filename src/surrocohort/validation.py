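"""Validation experiments: oracle checks and Monte-Carlo operating characteristics.

Every function here exercises the package end to end against an independent
route — a brute-force day-coverage oracle, a raw-table predicate sweep, or a
simulation with known truth — and returns plain numbers.  They back the
package's acceptance checks and are reusable as benchmarks for modified
designs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .claims_data import derive_study_anchors
from .design_matched import identify_new_users, match_pairs
from .design_tte import (assign_subcohorts, build_cessation_dataset,
                         build_initiation_dataset)
from .episodes import episode_intervals
from .models import (digit_preference_profile, fit_conditional_logistic,
                     fit_count_model, zinb_marginal_zero_fraction, ModelError)
from .runner import _initiation_estimate, prepare_study_data, scenario_config
from .simulate import OS, STATIN, simulate_claims, simulate_zinb_outcomes


# ---------------------------------------------------------------------------
# Brute-force day-coverage oracle (independent of episodes.episode_intervals)


def pill_count_episodes(dates, supplies, grace: int) -> list[tuple[int, int]]:
    """Day-by-day supply-queue walk: each dispensing adds its supply to a
    queue consumed one day at a time; maximal covered runs are then merged
    when the uncovered gap is at most the grace period."""
    events = sorted(zip(dates, supplies))
    covered = []
    remaining, day, i = 0, events[0][0], 0
    while i < len(events) or remaining > 0:
        while i < len(events) and events[i][0] == day:
            remaining += events[i][1]
            i += 1
        if remaining > 0:
            covered.append(day)
            remaining -= 1
        day += 1
        if remaining == 0 and i < len(events):
            day = max(day, events[i][0])
    runs = []
    start = prev = covered[0]
    for d in covered[1:]:
        if d != prev + 1:
            runs.append((start, prev + 1))
            start = d
        prev = d
    runs.append((start, prev + 1))
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= grace:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(m) for m in merged]


def episode_oracle_check(n_histories: int = 1000, seed: int = 0,
                         max_dispensings: int = 10, max_supply: int = 90,
                         graces: tuple[int, ...] = (0, 30, 45)) -> dict:
    """Random dispensing histories: episode construction vs the pill-count oracle."""
    rng = np.random.default_rng(seed)
    n_total = n_mismatch = 0
    for _ in range(n_histories):
        k = int(rng.integers(1, max_dispensings + 1))
        dates = rng.integers(0, 400, k)
        supplies = rng.integers(1, max_supply + 1, k)
        for grace in graces:
            got = [(s, e) for s, e, _ in
                   episode_intervals(dates, supplies, grace)]
            want = pill_count_episodes(dates.tolist(), supplies.tolist(),
                                       grace)
            n_total += 1
            n_mismatch += got != want
    return {"n_total": n_total, "n_mismatch": n_mismatch,
            "agreement": 1.0 - n_mismatch / n_total}


# ---------------------------------------------------------------------------
# Person-time conservation and exposure oracle in the TTE datasets


def person_time_check(n_patients: int = 1000, seed: int = 0) -> dict:
    """Counting-process rows must partition follow-up exactly, with row
    exposure matching day-level membership in oracle-built statin coverage."""
    cfg = scenario_config("confounded_null", n_patients, seed=seed)
    bundle, _ = simulate_claims(cfg)
    data = prepare_study_data(bundle)
    asg = assign_subcohorts(data.os_episodes, data.anchors)
    ra = data.anchors.set_index("patient_id")["ra_index"]

    statin_rx = bundle.prescriptions[bundle.prescriptions["drug_class"]
                                     == STATIN]
    oracle_eps = {pid: pill_count_episodes(g["dispense_date"].tolist(),
                                           g["days_supplied"].tolist(), 45)
                  for pid, g in statin_rx.groupby("patient_id")}

    init, _ = build_initiation_dataset(bundle, data.anchors, asg,
                                       data.statin_episodes)
    cess, _ = build_cessation_dataset(bundle, data.anchors, asg,
                                      data.os_episodes, data.statin_episodes)
    gap_errors = overlap_errors = exposure_mismatch = n_rows = n_checked = 0
    for rec in (init, cess):
        if len(rec) == 0:
            continue
        for pid, g in rec.groupby("patient_id"):
            g = g.sort_values("t_start")
            starts = g["t_start"].to_numpy()
            stops = g["t_stop"].to_numpy()
            if starts[0] != 0:
                gap_errors += 1
            gap_errors += int((starts[1:] != stops[:-1]).sum())
            overlap_errors += int((stops <= starts).sum())
            origin = int(ra.loc[pid])
            eps = oracle_eps.get(pid, [])
            for a, b, x in zip(starts, stops, g["statin_exposed"]):
                mid = origin + (a + b) // 2
                member = any(s <= mid < e for s, e in eps)
                exposure_mismatch += member != bool(x)
            n_rows += len(g)
            n_checked += 1
    return {"n_patients_checked": n_checked, "n_rows": n_rows,
            "partition_errors": gap_errors + overlap_errors,
            "exposure_mismatches": exposure_mismatch}


# ---------------------------------------------------------------------------
# Type-I error and effect recovery for the initiation-design Cox fit


def cox_null_size(n_replicates: int = 500, n_patients: int = 1000,
                  seed: int = 0, alpha: float = 0.05) -> dict:
    """Wald rejection rate of the statin term under the simulator's null."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_replicates):
        cfg = scenario_config("null", n_patients,
                              seed=int(rng.integers(2**31)))
        bundle, _ = simulate_claims(cfg)
        est = _initiation_estimate(bundle)
        if est is not None:
            ps.append(est[2])
    ps = np.array(ps)
    return {"n_fitted": len(ps), "rejection_rate": float(np.mean(ps < alpha))}


def cox_effect_recovery(n_replicates: int = 300, n_patients: int = 1000,
                        calib_replicates: int = 25, calib_factor: int = 10,
                        seed: int = 0) -> dict:
    """Mean log-HR at study size vs the ensemble truth from a 10x-size
    calibration run, plus 95% CI coverage of that truth."""
    rng = np.random.default_rng(seed)
    z975 = 1.959963984540054

    calib = []
    for _ in range(calib_replicates):
        cfg = scenario_config("effect", n_patients * calib_factor,
                              seed=int(rng.integers(2**31)))
        bundle, _ = simulate_claims(cfg)
        est = _initiation_estimate(bundle)
        if est is not None:
            calib.append(est[0])
    truth = float(np.mean(calib))

    logs, ses = [], []
    for _ in range(n_replicates):
        cfg = scenario_config("effect", n_patients,
                              seed=int(rng.integers(2**31)))
        bundle, _ = simulate_claims(cfg)
        est = _initiation_estimate(bundle)
        if est is not None:
            logs.append(est[0])
            ses.append(est[1])
    logs, ses = np.array(logs), np.array(ses)
    coverage = float(np.mean((logs - z975 * ses <= truth)
                             & (truth <= logs + z975 * ses)))
    return {"ensemble_truth_logHR": truth, "n_fitted": len(logs),
            "mean_logHR": float(np.mean(logs)),
            "bias": float(np.mean(logs) - truth), "ci_coverage": coverage}


# ---------------------------------------------------------------------------
# ZINB count component: size and recovery


def zinb_null_size(n_replicates: int = 500, n: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> dict:
    """Wald rejection rate of the count-part exposure term when the true rate
    ratio is 1 (no exposure effect) with 80% structural zeros."""
    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(n_replicates):
        df = simulate_zinb_outcomes(n, rng, rate_ratio=1.0,
                                    structural_zero_frac=0.8)
        try:
            fit = fit_count_model(df, zero_inflated=True)
        except ModelError:
            continue
        if fit.converged:
            p = fit.term("exposed", "count").p
            if np.isfinite(p):
                ps.append(p)
    ps = np.array(ps)
    return {"n_fitted": len(ps), "rejection_rate": float(np.mean(ps < alpha))}


def zinb_recovery(n_replicates: int = 100, n: int = 6000, seed: int = 0,
                  rate_ratio: float = 0.88,
                  structural_zero_frac: float = 0.8) -> dict:
    """Parameter recovery at the reference setting: 80% structural zeros,
    count-part rate ratio 0.88."""
    rng = np.random.default_rng(seed)
    rrs, zero_gaps = [], []
    for _ in range(n_replicates):
        df = simulate_zinb_outcomes(n, rng, rate_ratio=rate_ratio,
                                    structural_zero_frac=structural_zero_frac)
        try:
            fit = fit_count_model(df, zero_inflated=True)
        except ModelError:
            continue
        if not fit.converged:
            continue
        rrs.append(fit.term("exposed", "count").estimate)
        empirical = float((df["os_days"] == 0).mean())
        zero_gaps.append(zinb_marginal_zero_fraction(fit) - empirical)
    return {"n_fitted": len(rrs),
            "mean_rate_ratio": float(np.mean(rrs)),
            "rate_ratio_error": float(np.mean(rrs) - rate_ratio),
            "mean_abs_zero_gap": float(np.mean(np.abs(zero_gaps))),
            "mean_zero_gap": float(np.mean(zero_gaps))}


# ---------------------------------------------------------------------------
# Conditional logistic closed form


def clogit_closed_form_check(n_tables: int = 200, seed: int = 0) -> dict:
    """Random 1:1 binary tables: fitted OR vs the discordant ratio n10/n01."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_done = 0
    while n_done < n_tables:
        n10 = int(rng.integers(1, 40))
        n01 = int(rng.integers(1, 40))
        n11 = int(rng.integers(0, 20))
        n00 = int(rng.integers(0, 20))
        rows = []
        pid = 0
        for count, (ye, yu) in [(n11, (1, 1)), (n00, (0, 0)),
                                (n10, (1, 0)), (n01, (0, 1))]:
            for _ in range(count):
                rows.append((pid, "exposed", ye))
                rows.append((pid, "unexposed", yu))
                pid += 1
        tbl = pd.DataFrame(rows, columns=["pair_id", "arm", "any_os"])
        fit = fit_conditional_logistic(tbl)
        worst = max(worst, abs(fit.term("exposed").estimate - n10 / n01))
        n_done += 1
    return {"n_tables": n_done, "max_abs_or_diff": worst}


# ---------------------------------------------------------------------------
# Digit-preference detection


def digit_preference_detection(n_replicates: int = 100, seed: int = 0,
                               digit_pref_prob: float = 0.5,
                               n_patients: int = 1000,
                               n_resamples: int = 500) -> dict:
    """Fraction of simulated cohorts whose OS durations are flagged (p<0.05)."""
    rng = np.random.default_rng(seed)
    flags = []
    for _ in range(n_replicates):
        cfg = scenario_config("null", n_patients,
                              seed=int(rng.integers(2**31)))
        cfg.digit_pref_prob = digit_pref_prob
        bundle, _ = simulate_claims(cfg)
        durations = bundle.prescriptions.loc[
            bundle.prescriptions["drug_class"] == OS,
            "days_supplied"].to_numpy()
        if len(durations) == 0:
            continue
        prof = digit_preference_profile(durations, n_resamples=n_resamples,
                                        seed=rng)
        flags.append(prof.p_value < 0.05)
    return {"n_replicates": len(flags), "flag_rate": float(np.mean(flags))}


# ---------------------------------------------------------------------------
# Matching validity: independent predicate sweep over raw tables


def matching_validity_check(n_patients: int = 1000, seed: int = 0,
                            lookback_days: int = 365) -> dict:
    """Re-verify every emitted pair straight from the raw claims tables."""
    cfg = scenario_config("confounded_null", n_patients, seed=seed)
    bundle, _ = simulate_claims(cfg)
    data = prepare_study_data(bundle)
    exposed = identify_new_users(data.bundle, data.anchors)
    pairs, _ = match_pairs(data.bundle, data.anchors, exposed, seed=seed + 1)

    b = data.bundle
    pat = b.patients.set_index("patient_id")
    statin = b.prescriptions[b.prescriptions["drug_class"] == STATIN]
    ra = b.diagnoses[b.diagnoses["condition"] == "RA"]

    def first_ra(pid):
        d = ra.loc[ra["patient_id"] == pid, "claim_date"]
        return int(d.min()) if len(d) else None

    violations = 0
    for row in pairs.itertuples():
        t = int(row.index_day)
        for pid, is_exposed in [(row.exposed_id, True),
                                (row.unexposed_id, False)]:
            s = statin.loc[statin["patient_id"] == pid, "dispense_date"]
            if is_exposed:
                ok = len(s) > 0 and int(s.min()) == t
            else:
                ok = not ((s >= t - lookback_days) & (s <= t)).any()
            fra = first_ra(pid)
            ok &= fra is not None and fra < t
            ok &= int(pat.loc[pid, "enroll_start"]) <= t - lookback_days
            ok &= int(pat.loc[pid, "enroll_end"]) > t
            ok &= int(b.age_on([pid], [fra])[0]) > 20
            ok &= pat.loc[pid, "sex"] == row.sex
            ok &= int(b.age_on([pid], [t])[0]) == row.age_years
            violations += not ok
    members = pairs["exposed_id"].tolist() + pairs["unexposed_id"].tolist()
    reuse = len(members) - len(set(members))
    return {"n_pairs": len(pairs), "violations": violations + reuse}
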