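"""Synthetic claims-data generator with exponential survival times.

Generates a :class:`~precohort.claims.ClaimsDataset` mimicking a statutory
health-insurance extract.  The design is block-structured by patient ID:

* IDs ``1..drug_a_id_max`` each redeem 1–10 prescriptions of drug A
  (default ``B01AE07``, dabigatran);
* IDs ``drug_a_id_max+1..af_id_max`` each redeem 1–10 prescriptions of
  drug B (default ``B01AF01``, rivaroxaban);
* all IDs up to ``af_id_max`` additionally receive 1–10 beta-blocker
  (``C07``) and 1–20 renin-angiotensin (``C09``) prescriptions, 2–5 further
  co-medications, 2–5 atrial-fibrillation diagnoses (``I48.*``) and 1–20
  further diagnoses, all drawn from the synthetic vocabularies;
* the remaining IDs carry background co-medication and diagnoses only.

Death dates come from inverse-transform sampling of an exponential
proportional-hazards model: ``T = -ln(U) / (lambda0 * exp(x'beta))`` with a
baseline hazard per day and a linear predictor over age, the two study
drugs, the C07/C09 drug classes, four Elixhauser comorbidity groups, and
drug-by-covariate interaction terms.  Survival is measured from the
patient's first study-drug prescription (or the window start for background
patients); times running past the observation window end are
administratively censored, i.e. the death date is absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims import ClaimsDataset
from .features import load_default_elixhauser_map, map_elixhauser
from .vocabulary import AF_CODES, default_atc_vocabulary, default_icd_vocabulary


class ConfigError(ValueError):
    """The simulator configuration violates one of its invariants."""


DEFAULT_DRUG_A = "B01AE07"
DEFAULT_DRUG_B = "B01AF01"


def default_coefficients(
    drug_a_code: str = DEFAULT_DRUG_A, drug_b_code: str = DEFAULT_DRUG_B
) -> dict[str, float]:
    """Default log-hazard effect sizes for the survival linear predictor.

    No canonical values exist for these terms; the defaults are chosen so
    the two arms trade places across patient profiles: drug A is protective
    for older and diabetic patients while drug B is protective for
    hypertensive women — so similarity-trimmed cohorts built around
    different index patients can genuinely favor different arms.  Age enters
    centered and scaled as ``(age - 70) / 10``; ``female`` is an indicator.
    """
    a, b = drug_a_code, drug_b_code
    return {
        "age": 0.3,
        a: 0.0,
        b: 0.0,
        "C07": 0.05,
        "C09": 0.05,
        "hypertension_uncomplicated": 0.2,
        "diabetes_uncomplicated": 0.3,
        "solid_tumor": 0.5,
        "metastatic_cancer": 1.0,
        f"{a}:age": -0.3,
        f"{a}:diabetes": -1.8,
        f"{a}:hypertension": 1.8,
        f"{a}:female": 0.1,
        f"{b}:age": 0.3,
        f"{b}:diabetes": 1.8,
        f"{b}:hypertension": -1.8,
        f"{b}:female": -0.1,
    }


@dataclass
class SimConfig:
    """Full parameterization of the synthetic claims generator.

    Counts are inclusive ``(low, high)`` ranges per patient.  The defaults
    reproduce the designed example population: 10,000 insurants of whom the
    first 6,148 carry atrial fibrillation and a study anticoagulant (IDs
    1–3233 drug A, 3234–6148 drug B).
    """

    n_patients: int = 10_000
    af_id_max: int = 6148
    drug_a_id_max: int = 3233
    drug_a_code: str = DEFAULT_DRUG_A
    drug_b_code: str = DEFAULT_DRUG_B
    target_rx_range: tuple[int, int] = (1, 10)
    comed_prefixes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"C07": (1, 10), "C09": (1, 20)}
    )
    extra_comed_range: tuple[int, int] = (2, 5)
    extra_diag_range: tuple[int, int] = (1, 20)
    af_diag_range: tuple[int, int] = (2, 5)
    birth_year_range: tuple[int, int] = (1930, 1950)
    baseline_hazard: float = 0.0005  # deaths per day at x'beta = 0
    coefficients: dict[str, float] = field(default_factory=default_coefficients)
    atc_vocabulary: list[str] = field(default_factory=default_atc_vocabulary)
    icd_vocabulary: list[str] = field(default_factory=default_icd_vocabulary)
    observation_window: tuple[str, str] = ("2009-01-01", "2016-12-31")
    seed: int = 2020

    def validate(self) -> None:
        if not (0 < self.drug_a_id_max <= self.af_id_max <= self.n_patients):
            raise ConfigError(
                "need 0 < drug_a_id_max <= af_id_max <= n_patients, got "
                f"{self.drug_a_id_max}, {self.af_id_max}, {self.n_patients}"
            )
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        ranges = [
            self.target_rx_range, self.extra_comed_range,
            self.extra_diag_range, self.af_diag_range, self.birth_year_range,
            *self.comed_prefixes.values(),
        ]
        for lo, hi in ranges:
            if lo > hi:
                raise ConfigError(f"count range ({lo}, {hi}) has low > high")
        missing = [t for t in self._required_terms() if t not in self.coefficients]
        if missing:
            raise ConfigError(f"coefficients missing terms: {missing}")

    def _required_terms(self) -> list[str]:
        a, b = self.drug_a_code, self.drug_b_code
        terms = ["age", a, b, "C07", "C09",
                 "hypertension_uncomplicated", "diabetes_uncomplicated",
                 "solid_tumor", "metastatic_cancer"]
        for drug in (a, b):
            terms += [f"{drug}:{v}" for v in ("age", "diabetes", "hypertension", "female")]
        return terms

    def scaled(self, n_patients: int, seed: int | None = None) -> "SimConfig":
        """A proportionally shrunk copy, for quick runs at smaller n."""
        ratio = n_patients / self.n_patients
        return replace(
            self,
            n_patients=n_patients,
            af_id_max=max(2, round(self.af_id_max * ratio)),
            drug_a_id_max=max(1, round(self.drug_a_id_max * ratio)),
            seed=self.seed if seed is None else seed,
        )


def simulate_survival_time(
    linear_predictor: float, baseline_hazard: float, u: float
) -> float:
    """Survival time in days by inverting the exponential survival function.

    ``T = -ln(u) / (baseline_hazard * exp(linear_predictor))`` for a uniform
    draw ``u`` in the open interval (0, 1); strictly positive.
    """
    if not 0.0 < u < 1.0:
        raise ValueError(f"u must lie strictly in (0, 1), got {u}")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    return -math.log(u) / (baseline_hazard * math.exp(linear_predictor))


def _int_in(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def simulate_dataset(config: SimConfig | None = None) -> ClaimsDataset:
    """Generate a synthetic claims dataset under ``config``.

    Deterministic: a single seeded generator drives all draws in fixed
    order (sexes, then birth years, then per-patient blocks in ascending ID
    order), so identical configs yield identical datasets.  Record dates
    falling after a patient's simulated death are redrawn uniformly between
    the window start and the death date, keeping the dataset free of
    post-mortem claims without disturbing per-patient record counts.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    start = pd.Timestamp(cfg.observation_window[0])
    end = pd.Timestamp(cfg.observation_window[1])
    n_days = (end - start).days
    day_years = pd.date_range(start, end).year.to_numpy()

    elix_map = load_default_elixhauser_map()
    atc_pool = np.asarray(cfg.atc_vocabulary, dtype=object)
    icd_pool = np.asarray(cfg.icd_vocabulary, dtype=object)
    af_pool = np.asarray(AF_CODES, dtype=object)
    class_pools = {
        prefix: atc_pool[np.char.startswith(atc_pool.astype(str), prefix)]
        for prefix in cfg.comed_prefixes
    }
    for prefix, pool in class_pools.items():
        if len(pool) == 0:
            raise ConfigError(f"ATC vocabulary has no codes with prefix {prefix}")

    n = cfg.n_patients
    sexes = np.where(rng.integers(0, 2, size=n) == 0, "female", "male")
    birth_years = rng.integers(
        cfg.birth_year_range[0], cfg.birth_year_range[1] + 1, size=n
    )

    rx_ids: list[np.ndarray] = []
    rx_codes: list[np.ndarray] = []
    rx_days: list[np.ndarray] = []
    dx_ids: list[np.ndarray] = []
    dx_codes: list[np.ndarray] = []
    dx_days: list[np.ndarray] = []
    death_days = np.full(n, -1, dtype=np.int64)  # -1 = censored / alive

    coef = cfg.coefficients
    for i in range(1, n + 1):
        designed = i <= cfg.af_id_max
        if designed:
            target = cfg.drug_a_code if i <= cfg.drug_a_id_max else cfg.drug_b_code
            n_target = _int_in(rng, cfg.target_rx_range)
            class_codes = [
                rng.choice(class_pools[p], size=_int_in(rng, r))
                for p, r in cfg.comed_prefixes.items()
            ]
        else:
            target, n_target, class_codes = None, 0, []
        comed = rng.choice(atc_pool, size=_int_in(rng, cfg.extra_comed_range))
        if designed:
            p_codes = np.concatenate(
                [np.full(n_target, target, dtype=object), *class_codes, comed]
            )
        else:
            p_codes = comed
        p_days = rng.integers(0, n_days + 1, size=len(p_codes))

        if designed:
            af = rng.choice(af_pool, size=_int_in(rng, cfg.af_diag_range))
            extra_dx = rng.choice(icd_pool, size=_int_in(rng, cfg.extra_diag_range))
            d_codes = np.concatenate([af, extra_dx])
        else:
            d_codes = rng.choice(icd_pool, size=_int_in(rng, cfg.extra_diag_range))
        d_days = rng.integers(0, n_days + 1, size=len(d_codes))

        # Covariates for the survival linear predictor.
        origin = int(p_days[:n_target].min()) if n_target else 0
        age_c = (day_years[origin] - birth_years[i - 1] - 70) / 10.0
        groups = map_elixhauser(set(d_codes.tolist()), elix_map)
        has_c07 = any(str(c).startswith("C07") for c in p_codes)
        has_c09 = any(str(c).startswith("C09") for c in p_codes)

        lp = coef["age"] * age_c
        lp += coef["C07"] * has_c07 + coef["C09"] * has_c09
        for g in ("hypertension_uncomplicated", "diabetes_uncomplicated",
                  "solid_tumor", "metastatic_cancer"):
            lp += coef[g] * (g in groups)
        if target is not None:
            lp += coef[target]
            lp += coef[f"{target}:age"] * age_c
            lp += coef[f"{target}:diabetes"] * ("diabetes_uncomplicated" in groups)
            lp += coef[f"{target}:hypertension"] * ("hypertension_uncomplicated" in groups)
            lp += coef[f"{target}:female"] * (sexes[i - 1] == "female")

        t = simulate_survival_time(lp, cfg.baseline_hazard, float(rng.random()))
        death = origin + int(t)
        if death <= n_days:
            death_days[i - 1] = death
            # no claims after death: redraw offending dates before the death day
            late = p_days > death
            if late.any():
                p_days[late] = rng.integers(0, death + 1, size=int(late.sum()))
            late = d_days > death
            if late.any():
                d_days[late] = rng.integers(0, death + 1, size=int(late.sum()))

        rx_ids.append(np.full(len(p_codes), i, dtype=np.int64))
        rx_codes.append(p_codes)
        rx_days.append(p_days)
        dx_ids.append(np.full(len(d_codes), i, dtype=np.int64))
        dx_codes.append(d_codes)
        dx_days.append(d_days)

    def _dates(day_chunks: list[np.ndarray]) -> pd.Series:
        days = np.concatenate(day_chunks)
        return start + pd.to_timedelta(days, unit="D")

    prescriptions = pd.DataFrame({
        "ID": np.concatenate(rx_ids),
        "ATC": pd.array(np.concatenate(rx_codes), dtype="string"),
        "DATE": _dates(rx_days),
    })
    diagnoses = pd.DataFrame({
        "ID": np.concatenate(dx_ids),
        "ICD": pd.array(np.concatenate(dx_codes), dtype="string"),
        "DATE": _dates(dx_days),
    })
    deaths = pd.Series(
        np.where(death_days >= 0, death_days, 0), dtype="int64"
    )
    death_dates = start + pd.to_timedelta(deaths, unit="D")
    insurants = pd.DataFrame({
        "ID": np.arange(1, n + 1, dtype=np.int64),
        "SEX": pd.array(sexes, dtype="string"),
        "DATEOFBIRTH": birth_years.astype(np.int64),
        "DATEOFDEATH": death_dates.where(death_days >= 0),
    })
    return ClaimsDataset(insurants, prescriptions, diagnoses, (start, end))
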