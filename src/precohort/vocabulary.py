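"""Synthetic ATC / ICD-10 code pools for the claims simulator.

Real claims extracts draw their co-medication and diagnosis codes from the
population actually observed by the insurer.  No such source ships with this
package, so the simulator draws from the synthetic vocabularies below: small,
fixed pools of plausibly formatted codes spanning the common drug classes and
ICD-10 chapters.

Composition constraints (kept deliberately, see the methods note):

* the two anticoagulant study drugs (``B01AE07``, ``B01AF01``) and the
  atrial-fibrillation codes (``I48.*``) never appear in the pools, so the
  simulator's designed ID ranges alone determine who carries them;
* the diagnosis pool contains blocks that map onto the packaged Elixhauser
  comorbidity groups (hypertension ``I10``, diabetes ``E11``, solid tumour
  ``C18``/``C20``/``C25``/``C26``, metastatic cancer ``C78``/``C79``,
  depression ``F32``/``F33``) sized so that roughly 15–30 % of heavy
  utilizers acquire each group by chance — including the four codes the
  packaged example patients carry (``C26.0``, ``I10.0``, ``E11.9``,
  ``F33.8``);
* beta blockers (``C07``) and renin-angiotensin agents (``C09``) are present
  so background patients can pick them up as ordinary co-medication.
"""

from __future__ import annotations

# ~40 ATC 5-level families x 5 substance suffixes = 200 codes
_ATC_FAMILIES = [
    "A02BC", "A03FA", "A06AD", "A10BA", "A10BB", "A11CC", "A12AX",
    "B01AC", "B03BA", "C01DA", "C03CA", "C03DA", "C07AB", "C07AG",
    "C08CA", "C09AA", "C09CA", "C10AA", "D07AC", "G04CA", "H02AB",
    "H03AA", "J01CA", "J01DB", "J01MA", "L04AX", "M01AB", "M01AE",
    "M04AA", "N02AX", "N02BB", "N02BE", "N03AX", "N05BA", "N06AB",
    "N06AX", "R03AC", "R03BB", "R06AE", "S01ED",
]

# Diagnosis blocks feeding the Elixhauser comorbidity groups.
_ICD_HYPERTENSION = [f"I10.{d}" for d in range(10)]
_ICD_DIABETES = ["E11.2", "E11.3", "E11.5", "E11.7", "E11.8", "E11.9"]
_ICD_SOLID_TUMOR = ["C18.0", "C18.9", "C20.0", "C25.9", "C26.0"]
_ICD_METASTATIC = ["C78.0", "C79.5"]
_ICD_DEPRESSION = ["F32.0", "F32.1", "F32.9", "F33.1", "F33.8"]

# Filler chapters; none collide with the Elixhauser prefixes or with I48.
_ICD_FILLER_PREFIXES = [
    "A09", "B34", "D50", "E03", "E78", "F41", "G43", "G47", "H25",
    "H52", "H91", "I25", "I50", "I63", "I70", "I83", "J06", "J20",
    "J44", "J45", "K21", "K29", "K52", "K57", "K80", "L30", "M17",
    "M25", "M47", "M54", "M79", "N18", "N39", "R10", "R42", "R51",
    "R63", "T78", "Z12", "Z96",
]


def default_atc_vocabulary() -> list[str]:
    """200 synthetic ATC codes; excludes the study anticoagulants."""
    return [f"{family}{i:02d}" for family in _ATC_FAMILIES for i in range(1, 6)]


def default_icd_vocabulary() -> list[str]:
    """~300 synthetic ICD-10 codes; excludes atrial fibrillation (I48)."""
    filler = [f"{p}.{d}" for p in _ICD_FILLER_PREFIXES for d in range(7)]
    return (
        _ICD_HYPERTENSION
        + _ICD_DIABETES
        + _ICD_SOLID_TUMOR
        + _ICD_METASTATIC
        + _ICD_DEPRESSION
        + filler
    )


AF_CODES = [f"I48.{d}" for d in range(5)]
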