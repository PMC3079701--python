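"""Baseline covariate ascertainment from claims history.

Both designs adjust for pre-index co-morbidities (diagnosis claims) and
co-medications (pharmacy claims) plus demographics and insurance descriptors.
Ascertainment is "any record on or before the index day" (or strictly before,
per design); no fixed lookback window is imposed beyond the enrollment span.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _any_claim_by(claims: pd.DataFrame, date_col: str, code_col: str,
                  as_of: pd.Series, inclusive: bool, prefix: str,
                  exclude: set[str]) -> pd.DataFrame:
    """Indicator frame (index = as_of.index) of any claim per code by the index day."""
    cutoff = as_of.reindex(claims["patient_id"]).to_numpy()
    date = claims[date_col].to_numpy()
    keep = (date <= cutoff) if inclusive else (date < cutoff)
    keep &= ~np.isnan(cutoff)
    sub = claims.loc[keep]
    codes = sorted(c for c in claims[code_col].unique() if c not in exclude)
    out = pd.DataFrame(0.0, index=as_of.index,
                       columns=[f"{prefix}{c}" for c in codes])
    if len(sub):
        flags = (sub.groupby(["patient_id", code_col]).size().unstack(
            fill_value=0) > 0)
        for c in codes:
            if c in flags.columns:
                got = flags.index[flags[c]]
                out.loc[out.index.intersection(got), f"{prefix}{c}"] = 1.0
    return out


def baseline_covariates(bundle, as_of: pd.Series, inclusive: bool = True,
                        os_class: str = "OS", statin_class: str = "statin",
                        ) -> pd.DataFrame:
    """Baseline covariates for the patients in ``as_of`` (patient_id -> index day).

    Columns: ``female``, ``coverage_full``, ``plan_ppo``, ``prior_os`` (any OS
    dispensing by the index day), one ``cond_*`` indicator per non-RA condition
    code present in the bundle and one ``drug_*`` indicator per drug class
    other than the surrogate (OS) and exposure (statin) drugs.
    """
    pat = bundle.patients.set_index("patient_id").reindex(as_of.index)
    out = pd.DataFrame(index=as_of.index)
    out["female"] = (pat["sex"] == "F").astype(float)
    out["coverage_full"] = (pat["coverage"] == "full").astype(float)
    out["plan_ppo"] = (pat["plan"] == "PPO").astype(float)

    conds = _any_claim_by(bundle.diagnoses, "claim_date", "condition", as_of,
                          inclusive, "cond_", exclude={"RA"})
    drugs = _any_claim_by(bundle.prescriptions, "dispense_date", "drug_class",
                          as_of, inclusive, "drug_", exclude={os_class,
                                                             statin_class})
    os_rx = bundle.prescriptions[bundle.prescriptions["drug_class"] == os_class]
    prior = _any_claim_by(os_rx, "dispense_date", "drug_class", as_of,
                          inclusive, "prior_", exclude=set())
    out["prior_os"] = (prior[f"prior_{os_class}"]
                       if f"prior_{os_class}" in prior.columns else 0.0)
    return pd.concat([out, conds, drugs], axis=1)
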