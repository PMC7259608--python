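"""Shared fixtures: one default simulated dataset per session plus toys."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from precohort import (
    ClaimsDataset,
    CohortCriteria,
    SimConfig,
    build_cohort,
    build_features,
    simulate_dataset,
)

DEFAULT_CRITERIA = CohortCriteria(
    target_atc_prefixes=["B01AE07", "B01AF01"],
    required_icd_prefixes=["I48"],
)


@pytest.fixture(scope="session")
def default_dataset() -> ClaimsDataset:
    """The full designed population under the default configuration."""
    return simulate_dataset(SimConfig())


@pytest.fixture(scope="session")
def default_cohort(default_dataset):
    return build_cohort(default_dataset, DEFAULT_CRITERIA)


@pytest.fixture(scope="session")
def default_matrix(default_dataset, default_cohort):
    return build_features(default_dataset, default_cohort)


@pytest.fixture(scope="session")
def small_dataset() -> ClaimsDataset:
    """A proportionally scaled-down population for loop-heavy oracles."""
    return simulate_dataset(SimConfig().scaled(1000, seed=7))


def toy_dataset(
    insurants_rows: list[tuple],
    prescriptions_rows: list[tuple],
    diagnoses_rows: list[tuple],
    window: tuple[str, str] = ("2010-01-01", "2016-12-31"),
) -> ClaimsDataset:
    """Hand-built dataset from (id, sex, birth, death) / (id, code, date) rows."""
    ins = pd.DataFrame(insurants_rows, columns=["ID", "SEX", "DATEOFBIRTH", "DATEOFDEATH"])
    ins["DATEOFDEATH"] = pd.to_datetime(ins["DATEOFDEATH"])
    ins["SEX"] = ins["SEX"].astype("string")
    rx = pd.DataFrame(prescriptions_rows, columns=["ID", "ATC", "DATE"])
    dx = pd.DataFrame(diagnoses_rows, columns=["ID", "ICD", "DATE"])
    for df in (rx, dx):
        df["DATE"] = pd.to_datetime(df["DATE"])
    rx["ATC"] = rx["ATC"].astype("string")
    dx["ICD"] = dx["ICD"].astype("string")
    return ClaimsDataset(
        ins, rx, dx, (pd.Timestamp(window[0]), pd.Timestamp(window[1]))
    )


def day(offset: int, start: str = "2010-01-01") -> pd.Timestamp:
    return pd.Timestamp(start) + pd.Timedelta(days=offset)


def random_claims_dataset(rng: np.random.Generator, n_patients: int = 8) -> ClaimsDataset:
    """Small random-but-valid dataset for round-trip style properties."""
    start, end = pd.Timestamp("2012-01-01"), pd.Timestamp("2014-12-31")
    n_days = (end - start).days
    ins_rows, rx_rows, dx_rows = [], [], []
    for pid in range(1, n_patients + 1):
        death_day = int(rng.integers(30, n_days + 1)) if rng.random() < 0.3 else None
        last = death_day if death_day is not None else n_days
        ins_rows.append((
            pid,
            "female" if rng.random() < 0.5 else "male",
            int(rng.integers(1925, 1980)),
            start + pd.Timedelta(days=death_day) if death_day is not None else pd.NaT,
        ))
        for _ in range(int(rng.integers(0, 4))):
            rx_rows.append((pid, f"C0{rng.integers(1, 10)}AA01",
                            start + pd.Timedelta(days=int(rng.integers(0, last + 1)))))
        for _ in range(int(rng.integers(0, 4))):
            dx_rows.append((pid, f"I{rng.integers(10, 70)}.{rng.integers(0, 10)}",
                            start + pd.Timedelta(days=int(rng.integers(0, last + 1)))))
    if not rx_rows:
        rx_rows.append((1, "C01AA01", start))
    if not dx_rows:
        dx_rows.append((1, "I10.0", start))
    return toy_dataset(ins_rows, rx_rows, dx_rows, ("2012-01-01", "2014-12-31"))
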