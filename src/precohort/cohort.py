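"""Initial cohort selection from claims tables.

Implements the standard pharmacoepidemiologic cohort designs over the
three-table claims model:

* **new-user design** — a patient's index date is their first-ever
  prescription of any target drug; follow-up starts at first exposure,
  avoiding prevalent-user bias;
* **prevalent-user design** — the index date is the first target
  prescription occurring after the run-in period, regardless of earlier
  exposure history.

Inclusion requires a qualifying prescription, at least ``run_in_days`` of
observable history before index (history starts at the patient's earliest
claim of any kind), a minimum age at index, at least one required diagnosis
dated at or before index, and the patient being alive at index.

The returned cohort table has one row per included patient with columns
``ID``, ``DATEIndex``, ``STARTDATE``, ``DAYS_BEFORE_INDEX`` and
``TREATMENT`` (the matched target ATC code at index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims import ClaimsDataset, SchemaError

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["ID", "DATEIndex", "STARTDATE", "DAYS_BEFORE_INDEX", "TREATMENT"]


@dataclass
class CohortCriteria:
    """Inclusion and exclusion criteria for the initial cohort."""

    target_atc_prefixes: list[str]
    required_icd_prefixes: list[str] = field(default_factory=list)
    design: str = "new_user"
    run_in_days: int = 365
    min_age_years: int = 18

    def __post_init__(self) -> None:
        if self.design not in ("new_user", "prevalent_user"):
            raise ValueError(f"unknown design {self.design!r}")
        if not self.target_atc_prefixes:
            raise ValueError("target_atc_prefixes must be non-empty")
        if self.run_in_days < 0 or self.min_age_years < 0:
            raise ValueError("run_in_days and min_age_years must be >= 0")


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame({
        "ID": pd.Series(dtype="int64"),
        "DATEIndex": pd.Series(dtype="datetime64[ns]"),
        "STARTDATE": pd.Series(dtype="datetime64[ns]"),
        "DAYS_BEFORE_INDEX": pd.Series(dtype="int64"),
        "TREATMENT": pd.Series(dtype="string"),
    })


def build_cohort(dataset: ClaimsDataset, criteria: CohortCriteria) -> pd.DataFrame:
    """Select the initial study cohort from a claims dataset.

    Returns the cohort table described in the module docstring, sorted by
    ``ID``.  If no patient qualifies the result is empty (with a logged
    warning), not an error.

    Determinism on ties: when several target prescriptions share the index
    date, the treatment code is the lexicographically smallest matching ATC
    code; under the new-user design, patients whose first exposure day
    carries *distinct* target prefixes are excluded as ambiguous.
    """
    rx = dataset.prescriptions
    dx = dataset.diagnoses
    ins = dataset.insurants

    prefixes = tuple(criteria.target_atc_prefixes)
    matches = rx[rx["ATC"].astype(str).str.startswith(prefixes)]
    if matches.empty:
        logger.warning("no prescriptions match target prefixes %s", prefixes)
        return _empty_cohort()

    # Earliest claim of any kind per patient ("first entry in the data set").
    first_claim = (
        pd.concat([rx[["ID", "DATE"]], dx[["ID", "DATE"]]])
        .groupby("ID")["DATE"].min()
    )

    first_match = matches.groupby("ID")["DATE"].min()
    if criteria.design == "new_user":
        index_date = first_match
    else:  # prevalent_user: first match at or after the end of the run-in
        threshold = first_claim.reindex(first_match.index) + pd.to_timedelta(
            criteria.run_in_days, unit="D"
        )
        eligible = matches.merge(
            threshold.rename("THRESH"), left_on="ID", right_index=True
        )
        eligible = eligible[eligible["DATE"] >= eligible["THRESH"]]
        index_date = eligible.groupby("ID")["DATE"].min()

    cand = index_date.rename("DATEIndex").reset_index()
    cand["STARTDATE"] = cand["ID"].map(first_claim)
    cand["DAYS_BEFORE_INDEX"] = (cand["DATEIndex"] - cand["STARTDATE"]).dt.days

    # Treatment at index: matching codes dispensed on the index date.
    at_index = matches.merge(cand[["ID", "DATEIndex"]], on="ID")
    at_index = at_index[at_index["DATE"] == at_index["DATEIndex"]]
    treatment = at_index.groupby("ID")["ATC"].min()
    cand["TREATMENT"] = cand["ID"].map(treatment).astype("string")

    if criteria.design == "new_user" and len(prefixes) > 1:
        def n_prefixes(codes: pd.Series) -> int:
            matched = {p for c in codes for p in prefixes if str(c).startswith(p)}
            return len(matched)

        ambiguous = at_index.groupby("ID")["ATC"].apply(n_prefixes) > 1
        ambiguous_ids = set(ambiguous.index[ambiguous])
        if ambiguous_ids:
            logger.info(
                "excluding %d patients on distinct target drugs at first exposure",
                len(ambiguous_ids),
            )
        cand = cand[~cand["ID"].isin(ambiguous_ids)]

    demo = ins.set_index("ID")
    birth = cand["ID"].map(demo["DATEOFBIRTH"])
    death = cand["ID"].map(demo["DATEOFDEATH"])
    age_at_index = cand["DATEIndex"].dt.year - birth

    keep = (
        (cand["DAYS_BEFORE_INDEX"] >= criteria.run_in_days)
        & (age_at_index >= criteria.min_age_years)
        & (death.isna() | (death >= cand["DATEIndex"]))
    )

    if criteria.required_icd_prefixes:
        req = tuple(criteria.required_icd_prefixes)
        req_dx = dx[dx["ICD"].astype(str).str.startswith(req)]
        first_req = req_dx.groupby("ID")["DATE"].min()
        keep &= cand["ID"].map(first_req) <= cand["DATEIndex"]

    cohort = cand[keep.fillna(False)].sort_values("ID").reset_index(drop=True)
    cohort = cohort[COHORT_COLUMNS]
    if cohort.empty:
        logger.warning("no patient satisfies the cohort criteria")
    else:
        logger.info("cohort built: %d patients", len(cohort))
    return cohort


def search_in_table(source: pd.DataFrame, key_variable: str, reference_ids) -> pd.DataFrame:
    """Rows of ``source`` whose ``key_variable`` value occurs in ``reference_ids``.

    A semi-join preserving the original row order — the workhorse for
    subsetting claims tables to a cohort or precision-cohort ID set.
    """
    if key_variable not in source.columns:
        raise SchemaError(f"column {key_variable!r} not in source table")
    return source[source[key_variable].isin(set(reference_ids))]


def records_after_index(
    source: pd.DataFrame, cohort: pd.DataFrame, inclusive: bool = True
) -> pd.DataFrame:
    """Claims of cohort members dated at/after (or strictly after) their index.

    Rows for patients absent from the cohort are dropped (count logged).
    ``source`` needs ``ID`` and ``DATE`` columns.
    """
    for col in ("ID", "DATE"):
        if col not in source.columns:
            raise SchemaError(f"column {col!r} not in source table")
    index_by_id = cohort.set_index("ID")["DATEIndex"]
    idx = source["ID"].map(index_by_id)
    dropped = int(idx.isna().sum())
    if dropped:
        logger.info("records_after_index: dropped %d rows outside the cohort", dropped)
    keep = (source["DATE"] >= idx) if inclusive else (source["DATE"] > idx)
    return source[keep.fillna(False)]
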