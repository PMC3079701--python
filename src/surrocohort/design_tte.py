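"""Unmatched two-sub-cohort time-to-event design with time-varying exposure.

At the RA index date (the time origin — RA is progressive, so a common
disease-anchored clock is essential) every patient falls into exactly one of
two sub-cohorts according to oral-steroid (OS) use in a ±30-day window around
the index:

* **sub-cohort I** — not on OS at index; outcome = time to *initiation* of OS
  therapy (first OS dispensing after the index);
* **sub-cohort II** — on OS at index; outcome = time to *cessation* of the
  qualifying OS episode (end of the first OS prescription not followed by
  another within the 45-day grace period).

Both outcomes are laid out as counting-process rows (start, stop, exposure,
event), split wherever the time-varying statin exposure changes, and analysed
with a Cox model stratified by age band at index.

Known caveat, inherited from the design itself: sub-cohort I events can only
occur after index+30 by construction while the clock starts at the index; no
immortal-time correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import baseline_covariates
from .episodes import exposure_timeline
from .simulate import OS, STATIN

#: Half-width of the OS-use window around the RA index that defines the
#: sub-cohorts (recorded prescription/diagnosis dates may be inexact).
DEFAULT_HALF_WINDOW = 30

#: Age bands at RA index used as Cox strata.  The source bands are printed as
#: 20-50, 51-70 and 70-88 with 70 appearing twice; age 70 is assigned to the
#: middle band here.  Ages outside [20, 88] fall into the nearest band.
AGE_BAND_EDGES = (50, 70)
AGE_BAND_LABELS = ("20-50", "51-70", "71-88")


def age_band(age) -> np.ndarray:
    """Age-stratum label(s) for age(s) in completed years."""
    age = np.asarray(age)
    idx = np.searchsorted(np.asarray(AGE_BAND_EDGES), age, side="left")
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def assign_subcohorts(os_episodes: pd.DataFrame, anchors: pd.DataFrame,
                      half_window: int = DEFAULT_HALF_WINDOW) -> pd.DataFrame:
    """Assign every anchored patient to sub-cohort I or II.

    A patient is in sub-cohort II iff some OS episode covers at least one day
    of the inclusive window ``[ra_index - half_window, ra_index + half_window]``;
    otherwise sub-cohort I.  The two sub-cohorts partition the cohort.
    """
    ra = anchors.set_index("patient_id")["ra_index"]
    merged = os_episodes.merge(anchors[["patient_id", "ra_index"]],
                               on="patient_id", how="inner")
    # episode [start, end) covers a day of [ra-hw, ra+hw] iff
    # start <= ra+hw and end > ra-hw
    hit = merged.loc[(merged["start"] <= merged["ra_index"] + half_window)
                     & (merged["end"] > merged["ra_index"] - half_window),
                     "patient_id"].unique()
    out = anchors[["patient_id"]].copy()
    out["subcohort"] = np.where(out["patient_id"].isin(set(hit)), "II", "I")
    return out


def _counting_rows(origin: int, end_day: int, statin_eps: pd.DataFrame,
                   event: bool) -> list[tuple[int, int, bool, bool]]:
    """Split [origin, end_day) at statin exposure changes; event on final row."""
    rows = []
    for a, b, exposed in exposure_timeline(statin_eps, origin, end_day):
        rows.append((a - origin, b - origin, exposed, False))
    if event:
        a, b, exposed, _ = rows[-1]
        rows[-1] = (a, b, exposed, True)
    return rows


def _episodes_by_patient(episodes: pd.DataFrame) -> dict:
    return {pid: grp for pid, grp in episodes.groupby("patient_id", sort=False)}


_EMPTY_EPS = pd.DataFrame(columns=["start", "end"])


def _assemble(bundle, anchors: pd.DataFrame, statin_eps_by: dict,
              followups: list[tuple[str, int, int, bool]]) -> pd.DataFrame:
    """Build the TTE record table for (pid, origin, end_day, event) follow-ups."""
    ids = [f[0] for f in followups]
    sub_anchors = anchors.set_index("patient_id").loc[ids]
    as_of = pd.Series(sub_anchors["ra_index"].to_numpy(), index=ids)
    covs = baseline_covariates(bundle, as_of, inclusive=True)
    covs["incident_flag"] = sub_anchors["incident_flag"].astype(float).to_numpy()
    covs["ra_year"] = bundle.calendar_year(sub_anchors["ra_index"].to_numpy())
    strata = age_band(bundle.age_on(ids, sub_anchors["ra_index"].to_numpy()))

    out_rows = []
    for (pid, origin, end_day, event), stratum in zip(followups, strata):
        eps = statin_eps_by.get(pid, _EMPTY_EPS)
        for a, b, exposed, ev in _counting_rows(origin, end_day, eps, event):
            out_rows.append((pid, stratum, a, b, float(exposed), ev))
    records = pd.DataFrame(out_rows, columns=["patient_id", "stratum",
                                              "t_start", "t_stop",
                                              "statin_exposed", "event"])
    records = records.merge(covs, left_on="patient_id", right_index=True,
                            how="left")
    records["event"] = records["event"].astype(bool)
    return records


def build_initiation_dataset(bundle, anchors: pd.DataFrame,
                             assignments: pd.DataFrame,
                             statin_episodes: pd.DataFrame,
                             half_window: int = DEFAULT_HALF_WINDOW,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counting-process dataset for time to OS initiation (sub-cohort I).

    Follow-up runs from the RA index to the first OS dispensing after it
    (event) or enrollment end (censored), split at every statin exposure
    change; all times are days since RA index.  By the sub-cohort definition
    the event can only fall strictly after index + ``half_window``.

    Returns ``(records, exclusions)``; patients with zero follow-up are
    excluded and logged.
    """
    ids_I = assignments.loc[assignments["subcohort"] == "I", "patient_id"]
    sub = anchors[anchors["patient_id"].isin(set(ids_I))]
    enroll_end = bundle.patients.set_index("patient_id")["enroll_end"]
    os_rx = bundle.prescriptions[bundle.prescriptions["drug_class"] == OS]
    os_dates = {pid: np.sort(g["dispense_date"].to_numpy())
                for pid, g in os_rx.groupby("patient_id", sort=False)}
    statin_by = _episodes_by_patient(statin_episodes)

    followups, excl = [], []
    for pid, ra in zip(sub["patient_id"], sub["ra_index"]):
        dates = os_dates.get(pid)
        first_os = None
        if dates is not None:
            k = np.searchsorted(dates, ra, side="right")
            if k < len(dates):
                first_os = int(dates[k])
        e_end = int(enroll_end.loc[pid])
        event = first_os is not None and first_os <= e_end
        end_day = min(first_os, e_end) if event else e_end
        if end_day - ra <= 0:
            excl.append((pid, "non_positive_followup"))
            continue
        followups.append((pid, int(ra), end_day, event))

    exclusions = pd.DataFrame(excl, columns=["patient_id", "reason"])
    if not followups:
        return pd.DataFrame(), exclusions
    return _assemble(bundle, anchors, statin_by, followups), exclusions


def build_cessation_dataset(bundle, anchors: pd.DataFrame,
                            assignments: pd.DataFrame,
                            os_episodes: pd.DataFrame,
                            statin_episodes: pd.DataFrame,
                            half_window: int = DEFAULT_HALF_WINDOW,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counting-process dataset for time to OS cessation (sub-cohort II).

    The qualifying episode is the earliest OS episode overlapping the ±window;
    the event is its end (days since RA index) when the end is a genuine
    cessation, censoring at enrollment end otherwise.  Episodes whose end does
    not fall after the index (possible through the window's lookback) yield
    non-positive follow-up and are excluded with a log entry.
    """
    ids_II = assignments.loc[assignments["subcohort"] == "II", "patient_id"]
    sub = anchors[anchors["patient_id"].isin(set(ids_II))]
    os_by = _episodes_by_patient(os_episodes)
    statin_by = _episodes_by_patient(statin_episodes)

    followups, excl = [], []
    for pid, ra in zip(sub["patient_id"], sub["ra_index"]):
        eps = os_by.get(pid)
        if eps is None:
            excl.append((pid, "no_qualifying_episode"))
            continue
        mask = ((eps["start"] <= ra + half_window)
                & (eps["end"] > ra - half_window))
        if not mask.any():
            excl.append((pid, "no_qualifying_episode"))
            continue
        ep = eps.loc[mask].iloc[0]
        end_day = int(ep["end"])
        if end_day - ra <= 0:
            excl.append((pid, "non_positive_followup"))
            continue
        followups.append((pid, int(ra), end_day, bool(ep["ceased"])))

    exclusions = pd.DataFrame(excl, columns=["patient_id", "reason"])
    if not followups:
        return pd.DataFrame(), exclusions
    return _assemble(bundle, anchors, statin_by, followups), exclusions
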