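"""Matched new-user cohort design with prescription-amount outcomes.

New users of statins (first-ever dispensing after a 365-day clean membership
lookback) are matched 1:1, on the exposed patient's statin index date, to
patients with no statin record in the prior year, by sex and exact integer
age.  After a 90-day run-in (by which a patient can be considered fully
exposed), outcomes are measured over a 365-day observation window:

* ``any_os``  — any oral-steroid (OS) dispensing in the window (binary);
* ``os_days`` — days under OS therapy in the window (count; the model offset
  is the log of realised follow-up).

Unexposed patients are censored if they initiate statins during follow-up
(crossover censoring); they are not re-enrolled as exposed in the same run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import baseline_covariates
from .episodes import days_on_drug_in_window
from .simulate import OS, STATIN

DEFAULT_LOOKBACK_DAYS = 365
DEFAULT_RUN_IN_DAYS = 90
DEFAULT_WINDOW_DAYS = 365
MIN_AGE_AT_RA = 20  # excludes juvenile arthritis


def _statin_dates_by_patient(bundle) -> dict[str, np.ndarray]:
    rx = bundle.prescriptions[bundle.prescriptions["drug_class"] == STATIN]
    return {pid: np.sort(g["dispense_date"].to_numpy())
            for pid, g in rx.groupby("patient_id", sort=False)}


def identify_new_users(bundle, anchors: pd.DataFrame,
                       lookback_days: int = DEFAULT_LOOKBACK_DAYS
                       ) -> pd.DataFrame:
    """Exposed candidates: incident statin users within an RA cohort.

    A patient qualifies if their first-ever statin dispensing comes at least
    ``lookback_days`` after enrollment start (so the initiation is genuinely
    new and pre-exposure history is observable), their first RA claim precedes
    it, and they were over ``MIN_AGE_AT_RA`` at the first RA claim.

    Returns ``(patient_id, index_day, sex, age_at_index)``.
    """
    statin_dates = _statin_dates_by_patient(bundle)
    if not statin_dates:
        return pd.DataFrame(columns=["patient_id", "index_day", "sex",
                                     "age_at_index"])
    first = pd.Series({pid: int(d[0]) for pid, d in statin_dates.items()},
                      name="index_day")
    pat = bundle.patients.set_index("patient_id")
    anc = anchors.set_index("patient_id")
    df = first.to_frame().join(pat[["sex", "enroll_start"]]).join(
        anc[["ra_index"]])
    df = df[df["ra_index"].notna()]
    ok = ((df["index_day"] - df["enroll_start"] >= lookback_days)
          & (df["ra_index"] < df["index_day"]))
    df = df[ok]
    age_at_ra = bundle.age_on(df.index, df["ra_index"].to_numpy())
    df = df[age_at_ra > MIN_AGE_AT_RA]
    out = df.reset_index().rename(columns={"index": "patient_id"})
    out["age_at_index"] = bundle.age_on(out["patient_id"],
                                        out["index_day"].to_numpy())
    return out[["patient_id", "index_day", "sex", "age_at_index"]]


def match_pairs(bundle, anchors: pd.DataFrame, exposed: pd.DataFrame,
                seed: int | np.random.Generator = 0,
                lookback_days: int = DEFAULT_LOOKBACK_DAYS,
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """1:1 exact sex/age matching on the exposed patient's statin index date.

    Exposed patients are processed in randomised order; for each, an
    unexposed candidate is drawn uniformly at random (without replacement)
    from patients who, at that index date, have no statin dispensing in the
    prior ``lookback_days`` (a past user who stopped over a year before still
    qualifies), at least ``lookback_days`` of membership, an RA claim before
    the index, were over ``MIN_AGE_AT_RA`` at first RA claim, and match sex
    and integer age exactly.  A patient used as an unexposed match is not
    later re-enrolled as exposed.

    Returns ``(pairs, dropped)`` where ``pairs`` has one row per matched pair
    and ``dropped`` logs exposed patients left unmatched with a reason.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pat = bundle.patients.set_index("patient_id")
    anc = anchors.set_index("patient_id")

    all_ids = pat.index.to_numpy()
    enroll_start = pat["enroll_start"].to_numpy()
    enroll_end = pat["enroll_end"].to_numpy()
    sex = pat["sex"].to_numpy()
    ra_index = anc["ra_index"].reindex(pat.index).to_numpy(dtype=float)
    age_at_ra = np.where(np.isnan(ra_index), -1.0,
                         bundle.age_on(pat.index,
                                       np.nan_to_num(ra_index)))

    statin_dates = _statin_dates_by_patient(bundle)
    # per-patient sorted statin date arrays, empty when none
    sdates = [statin_dates.get(pid, np.empty(0, dtype=np.int64))
              for pid in pat.index]

    used: set[str] = set()
    pairs, dropped = [], []
    order = rng.permutation(len(exposed))
    for i in order:
        row = exposed.iloc[i]
        e_id, t = row["patient_id"], int(row["index_day"])
        if e_id in used:
            dropped.append((e_id, "already_used_as_unexposed"))
            continue
        e_sex, e_age = row["sex"], int(row["age_at_index"])

        n_recent = np.array([
            np.searchsorted(d, t, side="right")
            - np.searchsorted(d, t - lookback_days, side="left")
            for d in sdates])
        cand_age = bundle.age_on(pat.index, np.full(len(pat), t))
        ok = ((n_recent == 0)
              & (enroll_start <= t - lookback_days)
              & (enroll_end > t)
              & ~np.isnan(ra_index) & (ra_index < t)
              & (age_at_ra > MIN_AGE_AT_RA)
              & (sex == e_sex) & (cand_age == e_age)
              & (all_ids != e_id))
        candidates = [pid for pid in all_ids[ok] if pid not in used]
        if not candidates:
            dropped.append((e_id, "no_eligible_match"))
            continue
        u_id = candidates[int(rng.integers(len(candidates)))]
        used.add(e_id)
        used.add(u_id)
        pairs.append((e_id, u_id, t, e_sex, e_age))

    pairs_df = pd.DataFrame(pairs, columns=["exposed_id", "unexposed_id",
                                            "index_day", "sex", "age_years"])
    pairs_df.insert(0, "pair_id", np.arange(len(pairs_df)))
    dropped_df = pd.DataFrame(dropped, columns=["patient_id", "reason"])
    return pairs_df, dropped_df


def matched_outcomes(bundle, pairs: pd.DataFrame, os_episodes: pd.DataFrame,
                     run_in_days: int = DEFAULT_RUN_IN_DAYS,
                     window_days: int = DEFAULT_WINDOW_DAYS) -> pd.DataFrame:
    """Per-arm outcomes over the post-run-in observation window.

    The window is ``[index + run_in, index + run_in + window_days)``.
    Follow-up ends at the window end, enrollment end, or — unexposed arm only
    — the patient's own first statin dispensing after the index (crossover).
    ``any_os`` and ``os_days`` are evaluated on the realised follow-up;
    OS use during the run-in enters as the baseline covariate ``os_run_in``
    rather than as outcome.  Baseline covariates are ascertained strictly
    before the index date.
    """
    if len(pairs) == 0:
        return pd.DataFrame()
    enroll_end = bundle.patients.set_index("patient_id")["enroll_end"]
    os_rx = bundle.prescriptions[bundle.prescriptions["drug_class"] == OS]
    os_dates = {pid: np.sort(g["dispense_date"].to_numpy())
                for pid, g in os_rx.groupby("patient_id", sort=False)}
    statin_dates = _statin_dates_by_patient(bundle)
    eps_by = {pid: g for pid, g in os_episodes.groupby("patient_id",
                                                       sort=False)}
    empty_eps = pd.DataFrame(columns=["start", "end"])
    empty = np.empty(0, dtype=np.int64)

    rows = []
    for row in pairs.itertuples(index=False):
        t = int(row.index_day)
        w_start = t + run_in_days
        w_end = w_start + window_days
        for arm, pid in [("exposed", row.exposed_id),
                         ("unexposed", row.unexposed_id)]:
            fu_end = min(w_end, int(enroll_end.loc[pid]))
            if arm == "unexposed":
                d = statin_dates.get(pid, empty)
                k = np.searchsorted(d, t, side="right")
                if k < len(d):
                    fu_end = min(fu_end, int(d[k]))
            fu = max(0, fu_end - w_start)
            od = os_dates.get(pid, empty)
            any_os = bool(np.any((od >= w_start) & (od < fu_end))) if fu else False
            os_days = (days_on_drug_in_window(eps_by.get(pid, empty_eps),
                                              w_start, fu_end) if fu else 0)
            run_in_os = bool(np.any((od >= t) & (od < w_start)))
            rows.append((row.pair_id, pid, arm, arm == "exposed", t, fu,
                         any_os, os_days, run_in_os))

    out = pd.DataFrame(rows, columns=["pair_id", "patient_id", "arm",
                                      "exposed", "index_day", "followup_days",
                                      "any_os", "os_days", "os_run_in"])
    as_of = pd.Series(out["index_day"].to_numpy(), index=out["patient_id"])
    covs = baseline_covariates(bundle, as_of, inclusive=False)
    covs = covs.reset_index(drop=True)
    out = pd.concat([out.reset_index(drop=True), covs], axis=1)
    out["os_run_in"] = out["os_run_in"].astype(float)
    out["age_years"] = bundle.age_on(out["patient_id"],
                                     out["index_day"].to_numpy())
    return out
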