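"""End-to-end pipeline: data -> cohort -> similarity -> survival comparison.

:func:`run_workflow` chains the package's stages for one or more index
cases and writes every intermediate artifact to disk:

1. load claims CSV tables or simulate a synthetic dataset;
2. build the initial cohort (new-user design by default);
3. extract similarity features for all cohort members;
4. per index case: scale chart against the initial cohort, similarity
   trimming to the precision cohort, scale chart against the precision
   cohort, and a Kaplan–Meier comparison of the treatment arms with a
   per-arm survival summary.

A manifest (JSON) lists every produced file with its row count, and the
fully resolved configuration is echoed to the output directory so a run
can be reproduced exactly.  Identical config + seed gives identical
artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .claims import ClaimsDataset, read_claims_tables, write_claims_tables
from .cohort import CohortCriteria, build_cohort, search_in_table
from .features import FeatureMatrix, build_features, default_feature_spec
from .index_cases import EXAMPLE_PROFILES, index_case_from_profile
from .similarity import DistanceConfig, find_similar
from .simulate import SimConfig, simulate_dataset
from .survival import curve_table, derive_survival_records, km_by_arm, plot_km
from .viz import draw_scale_chart, summarize_reference

logger = logging.getLogger(__name__)

DEFAULT_TARGETS = ["B01AE07", "B01AF01"]


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class WorkflowConfig:
    """Everything a reproducible pipeline run needs.

    Exactly one data source: ``data_dir`` with the three claims CSVs, or
    ``simulator`` settings for a synthetic dataset.  ``index_cases`` maps a
    case name to a profile (``birth_year``, ``sex``, ``icd_codes``,
    ``atc_codes``); the packaged example patients are used by default.
    """

    output_dir: str = "precohort_out"
    data_dir: str | None = None
    simulator: SimConfig | None = None
    criteria: CohortCriteria = field(default_factory=lambda: CohortCriteria(
        target_atc_prefixes=list(DEFAULT_TARGETS),
        required_icd_prefixes=["I48"],
    ))
    distance: DistanceConfig = field(default_factory=DistanceConfig)
    index_cases: dict = field(default_factory=lambda: dict(EXAMPLE_PROFILES))
    as_of_year: int | None = None  # age reference year; default: window end
    seed: int | None = None

    def __post_init__(self) -> None:
        if (self.data_dir is None) == (self.simulator is None):
            if self.data_dir is None:
                self.simulator = SimConfig()
            else:
                raise ValueError("configure data_dir or simulator, not both")


def load_workflow_config(path: str | Path) -> WorkflowConfig:
    """Build a :class:`WorkflowConfig` from a YAML file.

    Nested sections ``simulator``, ``criteria`` and ``distance`` take the
    corresponding dataclass field names; omitted values keep defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    for key in ("output_dir", "data_dir", "index_cases", "as_of_year", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "simulator" in raw:
        sim = dict(raw["simulator"])
        for tup_key in ("observation_window",):
            if tup_key in sim:
                sim[tup_key] = tuple(sim[tup_key])
        kwargs["simulator"] = SimConfig(**sim)
    if "criteria" in raw:
        kwargs["criteria"] = CohortCriteria(**raw["criteria"])
    if "distance" in raw:
        kwargs["distance"] = DistanceConfig(**raw["distance"])
    return WorkflowConfig(**kwargs)


def _dump_config(config: WorkflowConfig, out: Path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    resolved = clean(config)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=False)


def _csv(df, path: Path) -> dict:
    df.to_csv(path, index=False)
    return {"path": str(path), "rows": int(len(df))}


def run_workflow(config: WorkflowConfig) -> dict:
    """Run the full pipeline; returns the manifest (also written as JSON)."""
    t0 = time.perf_counter()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "cases": {}, "files": []}

    def record(entry: dict) -> None:
        manifest["files"].append(entry)

    try:
        if config.data_dir is not None:
            dataset = read_claims_tables(config.data_dir)
        else:
            sim = config.simulator
            if config.seed is not None:
                sim = dataclasses.replace(sim, seed=config.seed)
            dataset = simulate_dataset(sim)
            for name, path in write_claims_tables(dataset, out / "data").items():
                record({"path": str(path), "rows": None})
        manifest["stages"]["data"] = {"n_patients": dataset.n_patients}
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(f"stage 'data' failed: {exc}") from exc

    try:
        cohort = build_cohort(dataset, config.criteria)
        record(_csv(cohort, out / "cohort.csv"))
        manifest["stages"]["cohort"] = {"n": int(len(cohort))}
        if cohort.empty:
            manifest["stages"]["stopped"] = (
                "cohort is empty under the configured criteria; relax them"
            )
            logger.warning(manifest["stages"]["stopped"])
            _finalize(manifest, config, out, t0)
            return manifest
    except WorkflowError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(f"stage 'cohort' failed: {exc}") from exc

    try:
        spec = default_feature_spec()
        matrix = build_features(dataset, cohort, spec)
        features_csv = matrix.data.reset_index()
        record(_csv(features_csv, out / "features.csv"))
    except Exception as exc:  # noqa: BLE001
        raise WorkflowError(f"stage 'features' failed: {exc}") from exc

    as_of_year = config.as_of_year or int(dataset.observation_window[1].year)
    for name, profile in config.index_cases.items():
        case_dir = out / name
        case_dir.mkdir(exist_ok=True)
        try:
            case = index_case_from_profile(as_of_year=as_of_year, spec=spec, **profile)
            chart = draw_scale_chart(
                summarize_reference(matrix, case),
                case_dir / "scale_chart_initial.png",
                title=f"{name} vs initial cohort (n={len(matrix)})",
            )
            record({"path": str(chart), "rows": None})

            result = find_similar(matrix, case, config.distance)
            record(_csv(result.distances.iloc[: len(result.selected_ids)],
                        case_dir / "precision_ids.csv"))

            sub = FeatureMatrix(
                matrix.data.loc[result.selected_ids], spec, matrix.ranges
            )
            chart = draw_scale_chart(
                summarize_reference(sub, case),
                case_dir / "scale_chart_precision.png",
                title=f"{name} vs precision cohort (n={len(sub)})",
            )
            record({"path": str(chart), "rows": None})

            precision_cohort = search_in_table(cohort, "ID", result.selected_ids)
            records = derive_survival_records(dataset, precision_cohort)
            curves = km_by_arm(records)
            km_path = plot_km(
                curves, case_dir / "km_plot.png",
                title=f"overall survival, precision cohort of {name}",
            )
            record({"path": str(km_path), "rows": None})
            record(_csv(pd.concat([curve_table(c) for c in curves]),
                        case_dir / "km_curves.csv"))

            horizon = float(np.median(records["TIME"]))
            summary = {
                "n_precision": len(result.selected_ids),
                "cutoff_distance": result.cutoff,
                "horizon_days": horizon,
                "survival_at_horizon": {
                    c.arm: c.survival_at(horizon) for c in curves
                },
            }
            summary["recommended_arm"] = max(
                summary["survival_at_horizon"],
                key=lambda a: summary["survival_at_horizon"][a],
            )
            manifest["cases"][name] = summary
        except Exception as exc:  # noqa: BLE001
            raise WorkflowError(f"stage 'case:{name}' failed: {exc}") from exc

    _finalize(manifest, config, out, t0)
    return manifest


def _finalize(manifest: dict, config: WorkflowConfig, out: Path, t0: float) -> None:
    manifest["elapsed_seconds"] = round(time.perf_counter() - t0, 2)
    _dump_config(config, out)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("workflow finished in %.1fs", manifest["elapsed_seconds"])
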