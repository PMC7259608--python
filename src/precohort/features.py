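"""Mixed-type similarity variables per cohort member.

Patient similarity is computed over a small set of typed variables — age at
index, sex, drug-class exposure indicators, and Elixhauser comorbidity-group
indicators — extracted from the raw claims tables for every cohort member.
The comorbidity grouper is a deliberately minimal, editable ICD-10 prefix
map (packaged as ``data/elixhauser_map.csv``) covering the groups the
example workflow needs, not the full published 31-group algorithm.

By default only records dated at or before a patient's index date
contribute, so similarity reflects the pre-treatment state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

ElixhauserMap = dict[str, tuple[str, ...]]

KINDS = ("continuous", "binary", "categorical")
RULES = ("age_at_index", "sex", "atc_prefix", "icd_prefix", "elixhauser")

ELIXHAUSER_CORE_GROUPS = (
    "hypertension_uncomplicated",
    "diabetes_uncomplicated",
    "solid_tumor",
    "metastatic_cancer",
    "depression",
)


class FeatureSpecError(ValueError):
    """A feature variable cannot be resolved against the claims data."""


@dataclass(frozen=True)
class FeatureVariable:
    """One similarity variable: its name, scale type and extraction rule.

    ``rule`` is one of ``age_at_index``, ``sex``, ``atc_prefix``,
    ``icd_prefix`` or ``elixhauser``; ``param`` carries the code prefix or
    group name for the latter three.
    """

    name: str
    kind: str
    rule: str
    param: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise FeatureSpecError(f"{self.name}: unknown kind {self.kind!r}")
        if self.rule not in RULES:
            raise FeatureSpecError(f"{self.name}: unknown rule {self.rule!r}")
        if self.rule in ("atc_prefix", "icd_prefix", "elixhauser") and not self.param:
            raise FeatureSpecError(f"{self.name}: rule {self.rule!r} needs a param")


@dataclass
class FeatureSpec:
    """Ordered list of similarity variables with unique names."""

    variables: list[FeatureVariable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise FeatureSpecError(f"duplicate variable names in {names}")

    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def kind_of(self, name: str) -> str:
        for v in self.variables:
            if v.name == name:
                return v.kind
        raise KeyError(name)

    def continuous_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == "continuous"]


@dataclass
class FeatureMatrix:
    """Per-patient feature rows plus range metadata for normalization.

    ``data`` is indexed by patient ID and column-aligned to ``spec``;
    ``ranges`` maps each continuous variable to its observed ``(min, max)``
    over this reference cohort (empty when the cohort is empty).
    """

    data: pd.DataFrame
    spec: FeatureSpec
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def default_feature_spec(
    elixhauser_groups: tuple[str, ...] = ELIXHAUSER_CORE_GROUPS,
) -> FeatureSpec:
    """Age, sex, C07/C09 exposure and the core comorbidity indicators.

    Treatment assignment is deliberately not a similarity variable: the
    tool's index patients are treatment-naive cases for whom the choice of
    arm is the question, so similarity must not condition on it.
    """
    variables = [
        FeatureVariable("age", "continuous", "age_at_index"),
        FeatureVariable("sex", "categorical", "sex"),
        FeatureVariable("C07", "binary", "atc_prefix", "C07"),
        FeatureVariable("C09", "binary", "atc_prefix", "C09"),
    ]
    variables += [
        FeatureVariable(g, "binary", "elixhauser", g) for g in elixhauser_groups
    ]
    return FeatureSpec(variables)


def load_default_elixhauser_map() -> ElixhauserMap:
    """Load the packaged minimal ICD-10 prefix map for comorbidity groups."""
    with resources.files("precohort.data").joinpath("elixhauser_map.csv").open() as fh:
        table = pd.read_csv(fh, dtype="string")
    out: dict[str, list[str]] = {}
    for group, prefix in zip(table["GROUP"], table["ICD_PREFIX"]):
        out.setdefault(str(group), []).append(str(prefix).upper())
    return {g: tuple(p) for g, p in out.items()}


def map_elixhauser(icd_codes, elix_map: ElixhauserMap) -> set[str]:
    """Comorbidity groups matched by any of the given ICD codes.

    A group is present iff some code starts with one of its prefixes.
    """
    codes = [str(c) for c in icd_codes]
    return {
        group
        for group, prefixes in elix_map.items()
        if any(code.startswith(prefixes) for code in codes)
    }


def _history(df: pd.DataFrame, cohort: pd.DataFrame, history: str) -> pd.DataFrame:
    merged = df.merge(cohort[["ID", "DATEIndex"]], on="ID", how="inner")
    if history == "before_index_only":
        merged = merged[merged["DATE"] <= merged["DATEIndex"]]
    elif history != "all":
        raise ValueError(f"history must be 'before_index_only' or 'all', got {history!r}")
    return merged


def build_features(
    dataset,
    cohort: pd.DataFrame,
    spec: FeatureSpec | None = None,
    elix_map: ElixhauserMap | None = None,
    history: str = "before_index_only",
) -> FeatureMatrix:
    """Extract one typed feature row per cohort member.

    ``cohort`` is a cohort table as produced by
    :func:`precohort.cohort.build_cohort` (needs ``ID`` and ``DATEIndex``).
    Indicator variables are 1 iff a qualifying record exists in the chosen
    history window; age is index year minus birth year (births are stored
    as bare years).  Range metadata is computed over the returned matrix.
    """
    spec = spec or default_feature_spec()
    elix_map = elix_map if elix_map is not None else load_default_elixhauser_map()

    ids = cohort["ID"].to_numpy()
    ins = dataset.insurants.set_index("ID")
    rx = _history(dataset.prescriptions, cohort, history)
    dx = _history(dataset.diagnoses, cohort, history)

    atc = rx["ATC"].astype(str)
    icd = dx["ICD"].astype(str)
    index_year = pd.Series(
        cohort["DATEIndex"].dt.year.to_numpy(), index=ids
    )

    columns: dict[str, pd.Series] = {}
    for var in spec.variables:
        if var.rule == "age_at_index":
            col = index_year - ins["DATEOFBIRTH"].reindex(ids)
            col = col.astype(float)
        elif var.rule == "sex":
            col = ins["SEX"].reindex(ids).astype(object)
        elif var.rule == "atc_prefix":
            having = set(rx.loc[atc.str.startswith(var.param), "ID"])
            col = pd.Series([int(i in having) for i in ids], index=ids)
        elif var.rule == "icd_prefix":
            having = set(dx.loc[icd.str.startswith(var.param), "ID"])
            col = pd.Series([int(i in having) for i in ids], index=ids)
        elif var.rule == "elixhauser":
            prefixes = elix_map.get(var.param)
            if prefixes is None:
                raise FeatureSpecError(
                    f"{var.name}: group {var.param!r} not in the Elixhauser map"
                )
            having = set(dx.loc[icd.str.startswith(prefixes), "ID"])
            col = pd.Series([int(i in having) for i in ids], index=ids)
        col.index = pd.Index(ids, name="ID")
        columns[var.name] = col

    data = pd.DataFrame(columns, index=pd.Index(ids, name="ID"))
    ranges = {}
    if len(data):
        for name in spec.continuous_names():
            ranges[name] = (float(data[name].min()), float(data[name].max()))
    return FeatureMatrix(data=data, spec=spec, ranges=ranges)
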