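"""Claims data model: relational bundle of patients, diagnoses and prescriptions.

A :class:`ClaimsBundle` is the universal input to every study design in this
package.  Internally all dates are integer day offsets from a fixed epoch
(half-open intervals, day units); calendar dates appear only at the I/O
boundary, where the three tables are plain comma-separated files with ISO-8601
dates.

Condition and drug-class codes are opaque strings supplied by the user (or the
simulator); no claims coding system (ICD/NDC) is interpreted here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Epoch for integer day offsets.  Chosen as the start of the calendar window
#: typical of the claims extracts this package targets; any date works, the
#: epoch only anchors I/O conversion.
EPOCH = pd.Timestamp("1992-01-01")

#: Days in "6 months" used for the incident-case flag.  The rule is a strict
#: inequality: a patient is an incident case iff the gap between enrollment
#: start and the first RA claim exceeds this many days.
INCIDENT_GAP_DAYS = 183

#: Average length of a calendar year in days, used to convert day offsets to
#: calendar years and integer ages.
DAYS_PER_YEAR = 365.2425

PATIENT_COLUMNS = ["patient_id", "sex", "birth_year", "enroll_start",
                   "enroll_end", "coverage", "plan"]
DIAGNOSIS_COLUMNS = ["patient_id", "claim_date", "condition"]
PRESCRIPTION_COLUMNS = ["patient_id", "drug_class", "dispense_date",
                        "days_supplied"]

_DATE_COLUMNS = {"enroll_start", "enroll_end", "claim_date", "dispense_date"}


class ClaimsInputError(OSError):
    """A claims table file is missing or unreadable."""


class ClaimsValidationError(ValueError):
    """A claims table violates the documented schema or referential integrity."""


@dataclass
class ClaimsBundle:
    """Relational container of claims tables, dates as integer day offsets.

    Attributes
    ----------
    patients : DataFrame with :data:`PATIENT_COLUMNS`; one row per patient,
        ``patient_id`` unique, ``enroll_start <= enroll_end`` (enrollment is
        the half-open day interval ``[enroll_start, enroll_end)``).
    diagnoses : DataFrame with :data:`DIAGNOSIS_COLUMNS`.
    prescriptions : DataFrame with :data:`PRESCRIPTION_COLUMNS`.
    epoch : calendar date corresponding to day 0.
    """

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    epoch: pd.Timestamp = field(default=EPOCH)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> "ClaimsBundle":
        """Check schema, uniqueness and referential integrity; return self.

        Raises :class:`ClaimsValidationError` naming the offending table and
        row on the first violation found.
        """
        for name, df, cols in [("patients", self.patients, PATIENT_COLUMNS),
                               ("diagnoses", self.diagnoses, DIAGNOSIS_COLUMNS),
                               ("prescriptions", self.prescriptions,
                                PRESCRIPTION_COLUMNS)]:
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ClaimsValidationError(
                    f"{name}: missing column(s) {missing}")
        pid = self.patients["patient_id"]
        if pid.duplicated().any():
            dup = pid[pid.duplicated()].iloc[0]
            raise ClaimsValidationError(
                f"patients: duplicate patient_id {dup!r}")
        bad = self.patients["enroll_start"] > self.patients["enroll_end"]
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ClaimsValidationError(
                f"patients: enroll_start > enroll_end at row {row}")
        known = set(pid)
        for name, df in [("diagnoses", self.diagnoses),
                         ("prescriptions", self.prescriptions)]:
            orphan = ~df["patient_id"].isin(known)
            if orphan.any():
                row = int(np.flatnonzero(orphan.to_numpy())[0])
                raise ClaimsValidationError(
                    f"{name}: row {row} references unknown patient_id "
                    f"{df['patient_id'].iloc[row]!r}")
        return self

    # -- convenience lookups -------------------------------------------------

    def calendar_year(self, days) -> np.ndarray:
        """Calendar year of the given day offset(s)."""
        days = np.asarray(days)
        ts = self.epoch + pd.to_timedelta(days.ravel(), unit="D")
        return np.asarray(ts.year).reshape(days.shape)

    def age_on(self, patient_ids, days) -> np.ndarray:
        """Completed age in years of each patient on the given day.

        Birth dates are only known to the year, so age is the calendar-year
        difference — the finest granularity the data supports.
        """
        by = (self.patients.set_index("patient_id")["birth_year"]
              .reindex(patient_ids).to_numpy())
        return self.calendar_year(np.asarray(days)) - by


# ---------------------------------------------------------------------------
# I/O


def _to_days(series: pd.Series, table: str, epoch: pd.Timestamp) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ClaimsValidationError(
            f"{table}: unparseable date {series.iloc[row]!r} at row {row}")
    return ((parsed - epoch).dt.days).astype(np.int64)


def _read_table(path: str | os.PathLike, columns: list[str],
                epoch: pd.Timestamp) -> pd.DataFrame:
    if not os.path.exists(path):
        raise ClaimsInputError(f"claims table not found: {path}")
    df = pd.read_csv(path, dtype={"patient_id": str})
    name = os.path.basename(str(path))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ClaimsValidationError(f"{name}: missing column(s) {missing}")
    df = df[columns].copy()
    for col in columns:
        if col in _DATE_COLUMNS:
            df[col] = _to_days(df[col], name, epoch)
    if "days_supplied" in df.columns:
        try:
            df["days_supplied"] = df["days_supplied"].astype(np.int64)
        except (TypeError, ValueError):
            raise ClaimsValidationError(f"{name}: non-numeric days_supplied")
    if "birth_year" in df.columns:
        df["birth_year"] = df["birth_year"].astype(np.int64)
    return df


def read_claims_bundle(patients_path, diagnoses_path, prescriptions_path,
                       epoch: pd.Timestamp = EPOCH) -> ClaimsBundle:
    """Read and validate a claims bundle from three delimited text files.

    Each file is comma-separated with a header row and the columns of the
    corresponding table; dates are ISO-8601.  Referential integrity (every
    claim's patient present in the patients table) is enforced.
    """
    bundle = ClaimsBundle(
        patients=_read_table(patients_path, PATIENT_COLUMNS, epoch),
        diagnoses=_read_table(diagnoses_path, DIAGNOSIS_COLUMNS, epoch),
        prescriptions=_read_table(prescriptions_path, PRESCRIPTION_COLUMNS,
                                  epoch),
        epoch=epoch,
    )
    return bundle.validate()


def write_claims_bundle(bundle: ClaimsBundle, out_dir: str | os.PathLike
                        ) -> dict[str, str]:
    """Write a bundle to ``patients.csv``/``diagnoses.csv``/``prescriptions.csv``.

    Inverse of :func:`read_claims_bundle` (round trip is the identity on any
    valid bundle).  Returns the paths written.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, df in [("patients", bundle.patients),
                     ("diagnoses", bundle.diagnoses),
                     ("prescriptions", bundle.prescriptions)]:
        out = df.copy()
        for col in out.columns:
            if col in _DATE_COLUMNS:
                out[col] = (bundle.epoch
                            + pd.to_timedelta(out[col], unit="D")
                            ).dt.strftime("%Y-%m-%d")
        path = os.path.join(out_dir, f"{name}.csv")
        out.to_csv(path, index=False)
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Cleaning and study anchors


def clean_prescriptions(bundle: ClaimsBundle, max_days: int = 365
                        ) -> tuple[ClaimsBundle, pd.DataFrame]:
    """Drop impossible prescription records; return (clean bundle, rejection log).

    Removed, with reason codes:

    - ``nonpositive_supply`` — days_supplied <= 0
    - ``exceeds_max``        — days_supplied > ``max_days``
    - ``outside_enrollment`` — dispense_date outside the owning patient's
      enrollment span ``[enroll_start, enroll_end)``

    Real claims extracts contain all three, so they are cleaned rather than
    treated as errors.  Cleaning is total and idempotent.
    """
    rx = bundle.prescriptions
    pat = bundle.patients.set_index("patient_id")
    start = pat["enroll_start"].reindex(rx["patient_id"]).to_numpy()
    end = pat["enroll_end"].reindex(rx["patient_id"]).to_numpy()
    supply = rx["days_supplied"].to_numpy()
    date = rx["dispense_date"].to_numpy()

    reason = np.full(len(rx), "", dtype=object)
    reason[(date < start) | (date >= end)] = "outside_enrollment"
    reason[supply > max_days] = "exceeds_max"
    reason[supply <= 0] = "nonpositive_supply"

    bad = reason != ""
    log = rx.loc[bad].copy()
    log["reason"] = reason[bad]
    cleaned = replace(bundle, prescriptions=rx.loc[~bad].reset_index(drop=True))
    return cleaned, log.reset_index(drop=True)


def derive_study_anchors(bundle: ClaimsBundle, ra_code: str = "RA"
                         ) -> pd.DataFrame:
    """Per-patient RA index date and incident-case flag.

    The first RA diagnosis claim is the proxy for RA diagnosis (the RA index
    date, the time origin of the unmatched design).  The incident flag marks
    patients whose index falls more than :data:`INCIDENT_GAP_DAYS` days after
    enrollment start — a long claims-free run-up makes the first claim a
    plausible disease onset rather than a prevalent case carried in.

    Returns a DataFrame ``(patient_id, ra_index, incident_flag)`` with one row
    per patient having at least one RA claim; other patients are omitted.
    """
    ra = bundle.diagnoses[bundle.diagnoses["condition"] == ra_code]
    idx = ra.groupby("patient_id", sort=False)["claim_date"].min()
    anchors = idx.rename("ra_index").reset_index()
    start = (bundle.patients.set_index("patient_id")["enroll_start"]
             .reindex(anchors["patient_id"]).to_numpy())
    anchors["incident_flag"] = (
        anchors["ra_index"].to_numpy() - start) > INCIDENT_GAP_DAYS
    return anchors
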