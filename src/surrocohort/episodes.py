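"""Continuous-therapy episodes and exposure timelines from dispensing records.

A drug treatment *episode* is a maximal run of pharmacy coverage: dispensing
supplies are laid end to end (early refills queue — "stockpiling"), and a new
episode starts only when the gap from the end of covered supply to the next
dispensing exceeds the grace period.  The grace comparison is inclusive: a
refill exactly ``grace_days`` after supply exhaustion continues the episode,
reading "within N days" inclusively.

All day intervals are half-open ``[start, end)``: ``end`` is the first
uncovered day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Grace period for oral-steroid cessation: therapy ends at the end of the
#: first prescription not followed by another within 45 days.
DEFAULT_GRACE_DAYS = 45


@dataclass(frozen=True)
class DrugEpisode:
    """One continuous-therapy interval for one patient and drug class.

    ``ceased`` is True when ``end`` is a genuine cessation (a supply gap longer
    than the grace period, or the final dispensing running out), False when the
    episode was truncated by the censoring day (enrollment end) — cessation
    analyses must censor there rather than count an artifactual event.
    """

    patient_id: str
    drug_class: str
    start: int
    end: int
    n_dispensings: int
    ceased: bool


def episode_intervals(dates: np.ndarray, supplies: np.ndarray,
                      grace_days: int) -> list[tuple[int, int, int]]:
    """Merge dispensings into (start, end, n_dispensings) coverage intervals.

    Supplies stockpile: a dispensing before the current supply runs out
    extends coverage by its full length (``end = max(end, date) + supply``).
    A dispensing more than ``grace_days`` after coverage ends opens a new
    interval.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    if len(dates) == 0:
        return []
    order = np.argsort(dates, kind="stable")
    dates = np.asarray(dates)[order]
    supplies = np.asarray(supplies)[order]
    out = []
    start = int(dates[0])
    end = start + int(supplies[0])
    n = 1
    for d, s in zip(dates[1:], supplies[1:]):
        d, s = int(d), int(s)
        if d <= end + grace_days:
            end = max(end, d) + s
            n += 1
        else:
            out.append((start, end, n))
            start, end, n = d, d + s, 1
    out.append((start, end, n))
    return out


def build_drug_episodes(dispensings: pd.DataFrame, grace_days: int,
                        censor_day: int | None = None) -> list[DrugEpisode]:
    """Build sorted, disjoint episodes for one patient and drug class.

    Parameters
    ----------
    dispensings : rows with ``patient_id``, ``drug_class``, ``dispense_date``,
        ``days_supplied`` for a single patient+drug (cleaned).
    grace_days : maximum supply gap, inclusive, within one episode.
    censor_day : if given, episodes are truncated at this day (typically
        enrollment end) and the truncated episode is flagged ``ceased=False``.
    """
    if len(dispensings) == 0:
        return []
    pid = dispensings["patient_id"].iloc[0]
    drug = dispensings["drug_class"].iloc[0]
    episodes = []
    for start, end, n in episode_intervals(
            dispensings["dispense_date"].to_numpy(),
            dispensings["days_supplied"].to_numpy(), grace_days):
        ceased = True
        if censor_day is not None and end >= censor_day:
            end = int(censor_day)
            ceased = False
        if censor_day is not None and start >= censor_day:
            continue  # dispensed on/after the censoring day: no observable coverage
        episodes.append(DrugEpisode(pid, drug, start, end, n, ceased))
    return episodes


def build_all_episodes(bundle, drug_class: str,
                       grace_days: int = DEFAULT_GRACE_DAYS,
                       censor_at_enrollment_end: bool = True) -> pd.DataFrame:
    """Episodes for every patient for one drug class, as a table.

    Returns a DataFrame ``(patient_id, drug_class, start, end, n_dispensings,
    ceased)`` sorted by patient and start — the exportable audit layout.
    """
    rx = bundle.prescriptions
    rx = rx[rx["drug_class"] == drug_class]
    enroll_end = bundle.patients.set_index("patient_id")["enroll_end"]
    rows = []
    for pid, grp in rx.groupby("patient_id", sort=True):
        censor = int(enroll_end.loc[pid]) if censor_at_enrollment_end else None
        for ep in build_drug_episodes(grp, grace_days, censor):
            rows.append((ep.patient_id, ep.drug_class, ep.start, ep.end,
                         ep.n_dispensings, ep.ceased))
    return pd.DataFrame(rows, columns=["patient_id", "drug_class", "start",
                                       "end", "n_dispensings", "ceased"])


def exposure_timeline(episodes, origin: int, end: int
                      ) -> list[tuple[int, int, bool]]:
    """Partition ``[origin, end)`` into alternating exposed/unexposed intervals.

    A day is exposed iff it is covered by some episode.  Consecutive output
    intervals abut exactly and alternate status; their lengths sum to
    ``end - origin`` (person-time conservation).

    ``episodes`` may be a list of :class:`DrugEpisode` or a DataFrame with
    ``start``/``end`` columns.
    """
    if origin >= end:
        raise ValueError(f"origin ({origin}) must be < end ({end})")
    if isinstance(episodes, pd.DataFrame):
        spans = list(zip(episodes["start"].to_numpy(),
                         episodes["end"].to_numpy()))
    else:
        spans = [(ep.start, ep.end) for ep in episodes]
    # clip to window, drop empties, merge any abutting/overlapping coverage
    spans = sorted((max(int(s), origin), min(int(e), end))
                   for s, e in spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    out: list[tuple[int, int, bool]] = []
    cursor = origin
    for s, e in merged:
        if s > cursor:
            out.append((cursor, s, False))
        out.append((s, e, True))
        cursor = e
    if cursor < end:
        out.append((cursor, end, False))
    return out


def days_on_drug_in_window(episodes, window_start: int, window_end: int) -> int:
    """Total covered days within ``[window_start, window_end)``.

    Episodes are disjoint by construction, so the clipped lengths add.
    """
    if window_start > window_end:
        raise ValueError("window_start must be <= window_end")
    if isinstance(episodes, pd.DataFrame):
        starts = episodes["start"].to_numpy()
        ends = episodes["end"].to_numpy()
    else:
        starts = np.array([ep.start for ep in episodes])
        ends = np.array([ep.end for ep in episodes])
    if len(starts) == 0:
        return 0
    clipped = (np.minimum(ends, window_end)
               - np.maximum(starts, window_start)).clip(min=0)
    return int(clipped.sum())
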