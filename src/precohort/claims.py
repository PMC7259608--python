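"""Claims-data model: three linked tables and their validation.

Administrative claims data arrive as separate tables from separate billing
sources.  This module fixes a minimal three-table layout:

* ``INSURANTS``     — ``ID, SEX, DATEOFBIRTH, DATEOFDEATH`` (birth as a bare
  calendar year; death empty when the patient is alive at the end of the
  observation window),
* ``PRESCRIPTIONS`` — ``ID, ATC, DATE`` (outpatient drug dispensations coded
  with the Anatomical Therapeutic Chemical classification),
* ``DIAGNOSES``     — ``ID, ICD, DATE`` (ICD-10 coded diagnoses).

Tables are plain CSV with a header row and ISO-8601 dates; in memory they are
pandas DataFrames bundled into a :class:`ClaimsDataset` together with the
observation window.  Durations throughout the package are whole days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

INSURANT_COLUMNS = ["ID", "SEX", "DATEOFBIRTH", "DATEOFDEATH"]
PRESCRIPTION_COLUMNS = ["ID", "ATC", "DATE"]
DIAGNOSIS_COLUMNS = ["ID", "ICD", "DATE"]
SEX_VALUES = ("female", "male")

INSURANT_FILE = "INSURANTS.csv"
PRESCRIPTION_FILE = "PRESCRIPTIONS.csv"
DIAGNOSIS_FILE = "DIAGNOSES.csv"


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong shape."""


class DateParseError(ValueError):
    """A date field could not be parsed; the message names table and row."""


class ValidationError(ValueError):
    """A dataset violates one of the claims-model invariants."""


@dataclass
class ClaimsDataset:
    """The three linked claims tables plus the observation window.

    ``insurants`` has one row per patient; ``prescriptions`` and
    ``diagnoses`` have one row per claim and reference patients by ``ID``.
    ``observation_window`` is the closed ``(start, end)`` date interval the
    records are drawn from; survivors are administratively censored at its
    end.
    """

    insurants: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    observation_window: tuple[pd.Timestamp, pd.Timestamp]

    @property
    def n_patients(self) -> int:
        return len(self.insurants)

    def patient_ids(self) -> pd.Index:
        return pd.Index(self.insurants["ID"])


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table}: missing required column {col!r}")


def _parse_date_column(
    raw: pd.Series, table: str, column: str, date_format: str
) -> pd.Series:
    """Parse a string column to datetimes, pointing at the first bad row."""
    as_str = raw.astype("string").str.strip()
    nonempty = as_str.notna() & (as_str != "")
    parsed = pd.to_datetime(as_str.where(nonempty), format=date_format, errors="coerce")
    bad = nonempty & parsed.isna()
    if bad.any():
        pos = int(bad[bad].index[0])
        raise DateParseError(
            f"{table}: unparseable date {raw.iloc[pos]!r} in column {column}, "
            f"data row {pos + 1}"
        )
    return parsed


def read_claims_tables(
    directory: str | Path | None = None,
    *,
    insurants: str | Path | None = None,
    prescriptions: str | Path | None = None,
    diagnoses: str | Path | None = None,
    delimiter: str = ",",
    date_format: str = "%Y-%m-%d",
    observation_window: tuple | None = None,
    validate: bool = True,
) -> ClaimsDataset:
    """Read the three claims tables from CSV files.

    Either pass ``directory`` holding the conventionally named files
    (``INSURANTS.csv``, ``PRESCRIPTIONS.csv``, ``DIAGNOSES.csv``) or the
    three paths explicitly.  ``observation_window`` defaults to the span of
    the observed record dates.

    Raises ``FileNotFoundError`` for a missing file, :class:`SchemaError`
    for a missing column, :class:`DateParseError` for an unparseable date
    and :class:`ValidationError` when ``validate`` is true and an invariant
    fails.
    """
    if directory is not None:
        directory = Path(directory)
        insurants = insurants or directory / INSURANT_FILE
        prescriptions = prescriptions or directory / PRESCRIPTION_FILE
        diagnoses = diagnoses or directory / DIAGNOSIS_FILE
    if insurants is None or prescriptions is None or diagnoses is None:
        raise ValueError("pass a directory or all three table paths")

    for path in (insurants, prescriptions, diagnoses):
        if not Path(path).exists():
            raise FileNotFoundError(f"claims table not found: {path}")

    ins = pd.read_csv(insurants, sep=delimiter, dtype={"SEX": "string"})
    rx = pd.read_csv(prescriptions, sep=delimiter, dtype={"ATC": "string"})
    dx = pd.read_csv(diagnoses, sep=delimiter, dtype={"ICD": "string"})

    _require_columns(ins, INSURANT_COLUMNS, "INSURANTS")
    _require_columns(rx, PRESCRIPTION_COLUMNS, "PRESCRIPTIONS")
    _require_columns(dx, DIAGNOSIS_COLUMNS, "DIAGNOSES")

    ins = ins.copy()
    ins["ID"] = ins["ID"].astype("int64")
    ins["DATEOFBIRTH"] = ins["DATEOFBIRTH"].astype("int64")
    ins["DATEOFDEATH"] = _parse_date_column(
        ins["DATEOFDEATH"], "INSURANTS", "DATEOFDEATH", date_format
    )
    rx = rx.copy()
    rx["ID"] = rx["ID"].astype("int64")
    rx["DATE"] = _parse_date_column(rx["DATE"], "PRESCRIPTIONS", "DATE", date_format)
    dx = dx.copy()
    dx["ID"] = dx["ID"].astype("int64")
    dx["DATE"] = _parse_date_column(dx["DATE"], "DIAGNOSES", "DATE", date_format)

    if observation_window is None:
        dates = pd.concat([rx["DATE"], dx["DATE"], ins["DATEOFDEATH"]]).dropna()
        if dates.empty:
            raise ValueError(
                "no dated records: pass observation_window explicitly"
            )
        observation_window = (dates.min(), dates.max())
    window = (pd.Timestamp(observation_window[0]), pd.Timestamp(observation_window[1]))

    dataset = ClaimsDataset(ins, rx, dx, window)
    logger.info(
        "loaded claims tables: %d insurants, %d prescriptions, %d diagnoses",
        len(ins), len(rx), len(dx),
    )
    if validate:
        violations = validate_dataset(dataset)
        if violations:
            raise ValidationError(
                "invalid claims dataset:\n" + "\n".join(violations[:20])
            )
    return dataset


def write_claims_tables(
    dataset: ClaimsDataset, directory: str | Path, *, delimiter: str = ","
) -> dict[str, Path]:
    """Write the three tables as CSV under ``directory``; returns the paths.

    Absent death dates serialize as empty fields, so
    ``read_claims_tables(write_claims_tables(d))`` round-trips the tables.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "insurants": directory / INSURANT_FILE,
        "prescriptions": directory / PRESCRIPTION_FILE,
        "diagnoses": directory / DIAGNOSIS_FILE,
    }
    ins = dataset.insurants.copy()
    ins["DATEOFDEATH"] = ins["DATEOFDEATH"].dt.strftime("%Y-%m-%d")
    ins.to_csv(paths["insurants"], sep=delimiter, index=False)
    for key, df in (("prescriptions", dataset.prescriptions), ("diagnoses", dataset.diagnoses)):
        out = df.copy()
        out["DATE"] = out["DATE"].dt.strftime("%Y-%m-%d")
        out.to_csv(paths[key], sep=delimiter, index=False)
    return paths


def validate_dataset(dataset: ClaimsDataset) -> list[str]:
    """Check every claims-model invariant; return human-readable violations.

    An empty list means the dataset is consistent.  Each violation names the
    table, the offending row (by 0-based position) and the broken rule.
    """
    out: list[str] = []
    ins, rx, dx = dataset.insurants, dataset.prescriptions, dataset.diagnoses
    start, end = dataset.observation_window

    dup = ins["ID"].duplicated(keep="first")
    for pos in ins.index[dup]:
        out.append(f"INSURANTS row {pos}: duplicate patient ID {ins.at[pos, 'ID']}")

    bad_sex = ~ins["SEX"].isin(SEX_VALUES)
    for pos in ins.index[bad_sex]:
        out.append(f"INSURANTS row {pos}: SEX must be one of {SEX_VALUES}")

    has_death = ins["DATEOFDEATH"].notna()
    born_late = has_death & (ins["DATEOFBIRTH"] >= ins["DATEOFDEATH"].dt.year)
    for pos in ins.index[born_late]:
        out.append(
            f"INSURANTS row {pos}: birth year {ins.at[pos, 'DATEOFBIRTH']} not "
            "before death year"
        )

    known = set(ins["ID"])
    # duplicates already reported above; keep the map well-defined regardless
    death_by_id = ins.drop_duplicates("ID").set_index("ID")["DATEOFDEATH"]
    for table, df, code_col in (("PRESCRIPTIONS", rx, "ATC"), ("DIAGNOSES", dx, "ICD")):
        orphan = ~df["ID"].isin(known)
        for pos in df.index[orphan]:
            out.append(f"{table} row {pos}: ID {df.at[pos, 'ID']} not in INSURANTS")
        empty_code = df[code_col].isna() | (df[code_col].astype("string").str.len() == 0)
        for pos in df.index[empty_code]:
            out.append(f"{table} row {pos}: empty {code_col} code")
        outside = (df["DATE"] < start) | (df["DATE"] > end)
        for pos in df.index[outside]:
            out.append(
                f"{table} row {pos}: date {df.at[pos, 'DATE'].date()} outside "
                f"observation window {start.date()}..{end.date()}"
            )
        death = df["ID"].map(death_by_id)
        post_mortem = death.notna() & (df["DATE"] > death)
        for pos in df.index[post_mortem]:
            out.append(
                f"{table} row {pos}: record dated {df.at[pos, 'DATE'].date()} "
                f"after patient {df.at[pos, 'ID']}'s death"
            )
    return out
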