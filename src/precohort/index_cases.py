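"""Index-case construction and the two packaged example patients.

An index case is the patient a treatment decision is being made for.  Such
a patient is typically *not* in the claims dataset — they are standing in
front of the prescriber — so a case is supplied directly as a feature row
built from their known profile: birth year, sex, diagnosis codes and
current medication.

Two example patients ship with the package, both female, both newly
diagnosed with atrial fibrillation and in need of an anticoagulant:

* **patient_1** — born 1935; colorectal cancer (``C26.0``) and
  uncomplicated hypertension (``I10.0``); on a renin-angiotensin agent
  (ATC ``C09``);
* **patient_2** — born 1948; diet-controlled type-2 diabetes (``E11.9``)
  and recurrent depression (``F33.8``); no regular medication.
"""

from __future__ import annotations

from .features import (
    ElixhauserMap,
    FeatureSpec,
    default_feature_spec,
    load_default_elixhauser_map,
    map_elixhauser,
)


def index_case_from_profile(
    birth_year: int,
    sex: str,
    icd_codes: list[str],
    atc_codes: list[str],
    as_of_year: int,
    spec: FeatureSpec | None = None,
    elix_map: ElixhauserMap | None = None,
) -> dict:
    """Resolve a patient profile into a feature row matching ``spec``.

    Each spec variable is evaluated against the supplied codes exactly as
    :func:`precohort.features.build_features` evaluates claims records, so
    the case row is comparable with cohort rows.
    """
    spec = spec or default_feature_spec()
    elix_map = elix_map if elix_map is not None else load_default_elixhauser_map()
    groups = map_elixhauser(icd_codes, elix_map)
    row: dict = {}
    for var in spec.variables:
        if var.rule == "age_at_index":
            row[var.name] = float(as_of_year - birth_year)
        elif var.rule == "sex":
            row[var.name] = sex
        elif var.rule == "atc_prefix":
            row[var.name] = int(any(str(c).startswith(var.param) for c in atc_codes))
        elif var.rule == "icd_prefix":
            row[var.name] = int(any(str(c).startswith(var.param) for c in icd_codes))
        elif var.rule == "elixhauser":
            row[var.name] = int(var.param in groups)
    return row


EXAMPLE_PROFILES: dict[str, dict] = {
    "patient_1": {
        "birth_year": 1935,
        "sex": "female",
        "icd_codes": ["C26.0", "I10.0"],
        "atc_codes": ["C09AA05"],
    },
    "patient_2": {
        "birth_year": 1948,
        "sex": "female",
        "icd_codes": ["E11.9", "F33.8"],
        "atc_codes": [],
    },
}


def example_index_cases(
    as_of_year: int = 2016,
    spec: FeatureSpec | None = None,
    elix_map: ElixhauserMap | None = None,
) -> dict[str, dict]:
    """Feature rows for the two packaged example patients."""
    return {
        name: index_case_from_profile(
            as_of_year=as_of_year, spec=spec, elix_map=elix_map, **profile
        )
        for name, profile in EXAMPLE_PROFILES.items()
    }
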