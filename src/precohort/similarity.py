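"""Mixed-type patient similarity: Gower and HEOM distances, trimming, PAM.

Claims-derived feature rows mix continuous, binary and categorical
variables, which the two implemented dissimilarities handle natively:

* **Gower** — per-variable contributions are the range-normalized absolute
  difference for continuous variables and a mismatch indicator for
  categorical/binary ones, combined as a weighted mean over the variables
  observed in both rows; always in [0, 1].  Binary variables are treated
  symmetrically by default; Gower's original asymmetric coefficient
  (double-zero pairs dropped from the denominator) is available via
  ``binary_handling="asymmetric"``.
* **HEOM** (Heterogeneous Euclidean-Overlap Metric) — the Euclidean
  combination of the same per-variable pieces, with any missing value
  scoring the maximal per-variable distance of 1.

A precision cohort is derived either by **nearest-fraction trimming**
(keep the ``floor(fraction * N)`` patients closest to the index case) or by
**partitioning around medoids** (PAM, BUILD + SWAP) and keeping the index
case's cluster.  All tie-breaks are by ascending patient ID so results are
reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .features import FeatureMatrix, FeatureSpec

logger = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """Every variable is missing in one of the rows of a pair."""


class EmptySelectionError(ValueError):
    """The requested fraction selects zero patients."""


@dataclass
class DistanceConfig:
    """How to measure similarity and how to trim the cohort."""

    metric: str = "gower"
    mode: str = "nearest_fraction"
    fraction: float = 0.10
    k: int | None = None
    weights: dict[str, float] | None = None
    binary_handling: str = "symmetric"

    def __post_init__(self) -> None:
        if self.metric not in ("gower", "heom"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mode not in ("nearest_fraction", "cluster"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must lie in (0, 1]")
        if self.mode == "cluster" and (self.k is None or self.k < 1):
            raise ValueError("cluster mode needs k >= 1")
        if self.binary_handling not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown binary_handling {self.binary_handling!r}")


@dataclass
class SimilarityResult:
    """Distances to the index case and the trimmed precision-cohort IDs.

    ``distances`` is sorted ascending by distance (ties by ID);
    ``selected_ids`` is the precision cohort; ``cutoff`` the largest
    distance-to-index among the selected patients.
    """

    distances: pd.DataFrame  # columns ID, DISTANCE
    selected_ids: list[int]
    cutoff: float


def _width(bounds: tuple[float, float]) -> float:
    return float(bounds[1]) - float(bounds[0])


def _contrib(a, b, kind: str, width: float | None, name: str):
    """Per-variable distance contribution and missingness mask (broadcasts)."""
    if kind == "continuous":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        missing = np.isnan(a) | np.isnan(b)
        if width is None:
            raise KeyError(f"no range metadata for continuous variable {name!r}")
        if width == 0:
            logger.warning("variable %r has zero range; contributes 0", name)
            d = np.zeros(np.broadcast(a, b).shape)
        else:
            d = np.abs(np.where(missing, 0.0, a - b)) / width
    else:
        a = np.asarray(a, dtype=object)
        b = np.asarray(b, dtype=object)
        missing = pd.isna(a) | pd.isna(b)
        d = (a != b) & ~missing
        d = d.astype(float)
    return d, missing


def _row_pair_frames(a: Mapping, b: Mapping, spec: FeatureSpec):
    names = spec.names()
    fa = pd.DataFrame([{n: a.get(n) if hasattr(a, "get") else a[n] for n in names}])
    fb = pd.DataFrame([{n: b.get(n) if hasattr(b, "get") else b[n] for n in names}])
    return fa, fb


def _gower(
    frame: pd.DataFrame,
    other: pd.DataFrame | Mapping,
    spec: FeatureSpec,
    ranges: dict[str, tuple[float, float]],
    weights: dict[str, float] | None,
    binary_handling: str,
) -> np.ndarray:
    weights = weights or {}
    num = np.zeros(len(frame))
    den = np.zeros(len(frame))
    for var in spec.variables:
        a = frame[var.name].to_numpy()
        b = other[var.name] if not isinstance(other, pd.DataFrame) else other[var.name].to_numpy()
        width = _width(ranges[var.name]) if var.kind == "continuous" else None
        d, missing = _contrib(a, b, var.kind, width, var.name)
        include = ~missing
        if binary_handling == "asymmetric" and var.kind == "binary":
            both_zero = (np.asarray(a, dtype=object) == 0) & (np.asarray(b, dtype=object) == 0)
            include &= ~both_zero
        w = float(weights.get(var.name, 1.0))
        num += w * d * include
        den += w * include
    if np.any(den == 0):
        raise UndefinedDistanceError(
            "no commonly observed variables for at least one pair"
        )
    return num / den


def _heom(
    frame: pd.DataFrame,
    other: pd.DataFrame | Mapping,
    spec: FeatureSpec,
    ranges: dict[str, tuple[float, float]],
) -> np.ndarray:
    total = np.zeros(len(frame))
    for var in spec.variables:
        a = frame[var.name].to_numpy()
        b = other[var.name] if not isinstance(other, pd.DataFrame) else other[var.name].to_numpy()
        width = _width(ranges[var.name]) if var.kind == "continuous" else None
        d, missing = _contrib(a, b, var.kind, width, var.name)
        d = np.where(missing, 1.0, d)  # missing scores maximal difference
        total += d * d
    return np.sqrt(total)


def gower_distance(
    a: Mapping,
    b: Mapping,
    spec: FeatureSpec,
    ranges: dict[str, tuple[float, float]],
    weights: dict[str, float] | None = None,
    binary_handling: str = "symmetric",
) -> float:
    """Gower dissimilarity between two feature rows; in [0, 1]."""
    fa, fb = _row_pair_frames(a, b, spec)
    return float(_gower(fa, fb, spec, ranges, weights, binary_handling)[0])


def heom_distance(
    a: Mapping,
    b: Mapping,
    spec: FeatureSpec,
    ranges: dict[str, tuple[float, float]],
) -> float:
    """HEOM dissimilarity between two feature rows; nonnegative."""
    fa, fb = _row_pair_frames(a, b, spec)
    return float(_heom(fa, fb, spec, ranges)[0])


def _extended_ranges(
    matrix: FeatureMatrix, case: Mapping
) -> dict[str, tuple[float, float]]:
    """Range metadata widened to cover an index case outside the cohort."""
    out = dict(matrix.ranges)
    for name in matrix.spec.continuous_names():
        v = case[name] if not hasattr(case, "get") else case.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            continue
        lo, hi = out[name]
        out[name] = (min(lo, float(v)), max(hi, float(v)))
    return out


def distances_to_case(
    matrix: FeatureMatrix, case: Mapping, config: DistanceConfig
) -> np.ndarray:
    """Distance from every matrix row to the index case, in row order."""
    ranges = _extended_ranges(matrix, case)
    case_row = {n: (case.get(n) if hasattr(case, "get") else case[n]) for n in matrix.spec.names()}
    if config.metric == "gower":
        return _gower(matrix.data, case_row, matrix.spec, ranges,
                      config.weights, config.binary_handling)
    return _heom(matrix.data, case_row, matrix.spec, ranges)


def pairwise_distances(matrix: FeatureMatrix, config: DistanceConfig) -> np.ndarray:
    """Full symmetric distance matrix over the feature rows."""
    n = len(matrix)
    spec, ranges = matrix.spec, matrix.ranges
    weights = config.weights or {}
    if config.metric == "gower":
        num = np.zeros((n, n)); den = np.zeros((n, n))
    else:
        total = np.zeros((n, n))
    for var in spec.variables:
        col = matrix.data[var.name].to_numpy()
        width = _width(ranges[var.name]) if var.kind == "continuous" else None
        d, missing = _contrib(col[:, None], col[None, :], var.kind, width, var.name)
        if config.metric == "gower":
            include = ~missing
            if config.binary_handling == "asymmetric" and var.kind == "binary":
                zero = np.asarray(col, dtype=object) == 0
                include &= ~(zero[:, None] & zero[None, :])
            w = float(weights.get(var.name, 1.0))
            num += w * d * include
            den += w * include
        else:
            total += np.where(missing, 1.0, d) ** 2
    if config.metric == "gower":
        if np.any(den == 0):
            raise UndefinedDistanceError("some pair shares no observed variable")
        return num / den
    return np.sqrt(total)


def _pam(D: np.ndarray, k: int) -> tuple[list[int], np.ndarray, float]:
    """PAM on a precomputed distance matrix; returns (medoid positions,
    assignment by position, total cost).  Deterministic: ties resolve to the
    lowest row position throughout."""
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of points {n}")

    # BUILD: greedy seeding minimizing total distance to the nearest medoid.
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        best_j, best_cost = -1, np.inf
        for j in range(n):
            if j in medoids:
                continue
            cost = float(np.minimum(nearest, D[:, j]).sum())
            if cost < best_cost - 1e-12:
                best_j, best_cost = j, cost
        medoids.append(best_j)
        nearest = np.minimum(nearest, D[:, best_j])
        medoids.sort()
        nearest = D[:, medoids].min(axis=1)

    # SWAP: steepest descent over single medoid<->non-medoid exchanges.
    while True:
        med = np.asarray(sorted(medoids))
        dist_to_meds = D[:, med]                      # n x k
        order = np.argsort(dist_to_meds, axis=1)
        nearest_d = np.take_along_axis(dist_to_meds, order[:, :1], axis=1)[:, 0]
        if k > 1:
            second_d = np.take_along_axis(dist_to_meds, order[:, 1:2], axis=1)[:, 0]
        else:
            second_d = np.full(D.shape[0], np.inf)
        nearest_m = med[order[:, 0]]

        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(med):
            loses = nearest_m == m
            base = np.where(loses, second_d, nearest_d)
            for h in range(n):
                if h in medoids:
                    continue
                new_d = np.minimum(base, D[:, h])
                delta = float(new_d.sum() - nearest_d.sum())
                if delta < best_delta:
                    best_delta, best_swap = delta, (m, h)
        if best_swap is None:
            break
        m, h = best_swap
        medoids.remove(m)
        medoids.append(h)
        medoids.sort()

    med = np.asarray(sorted(medoids))
    assignment = med[np.argmin(D[:, med], axis=1)]
    cost = float(D[np.arange(n), assignment].sum())
    return list(med), assignment, cost


def pam_cluster(
    matrix: FeatureMatrix, k: int, config: DistanceConfig | None = None
) -> tuple[list[int], pd.Series, float]:
    """Partition the feature rows around ``k`` medoids.

    Returns medoid patient IDs, a Series mapping patient ID to its medoid's
    patient ID, and the total within-cluster distance.
    """
    config = config or DistanceConfig(metric="gower", mode="cluster", k=k)
    D = pairwise_distances(matrix, config)
    med_pos, assign_pos, cost = _pam(D, k)
    ids = matrix.data.index.to_numpy()
    assignment = pd.Series(ids[assign_pos], index=matrix.data.index, name="MEDOID")
    return [int(ids[p]) for p in med_pos], assignment, cost


def find_similar(
    matrix: FeatureMatrix, index_case: Mapping, config: DistanceConfig | None = None
) -> SimilarityResult:
    """Trim a reference cohort to the patients most similar to an index case.

    In ``nearest_fraction`` mode the ``floor(fraction * N)`` closest
    patients are selected (distance ties at the cutoff broken by ascending
    ID).  In ``cluster`` mode the rows are PAM-partitioned and the members
    of the cluster whose medoid is nearest to the index case are selected
    (the case itself does not participate in the clustering).
    """
    if len(matrix) == 0:
        raise ValueError("feature matrix is empty")
    config = config or DistanceConfig()
    ids = matrix.data.index.to_numpy()
    dist = distances_to_case(matrix, index_case, config)
    order = np.lexsort((ids, dist))
    table = pd.DataFrame({"ID": ids[order], "DISTANCE": dist[order]})

    if config.mode == "nearest_fraction":
        m = int(config.fraction * len(matrix))
        if m == 0:
            raise EmptySelectionError(
                f"fraction {config.fraction} of {len(matrix)} patients selects "
                "nobody; increase the fraction"
            )
        selected = table["ID"].iloc[:m].astype(int).tolist()
        cutoff = float(table["DISTANCE"].iloc[m - 1])
    else:
        medoid_ids, assignment, _ = pam_cluster(matrix, config.k, config)
        med_rows = FeatureMatrix(
            matrix.data.loc[medoid_ids], matrix.spec, matrix.ranges
        )
        med_dist = distances_to_case(med_rows, index_case, config)
        best = medoid_ids[int(np.argmin(med_dist))]  # argmin: lowest-ID tie-break
        selected = sorted(int(i) for i in assignment.index[assignment == best])
        sel_set = set(selected)
        cutoff = float(table.loc[table["ID"].isin(sel_set), "DISTANCE"].max())
    return SimilarityResult(distances=table, selected_ids=selected, cutoff=cutoff)
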