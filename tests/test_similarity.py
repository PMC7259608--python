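"""Distance metrics, nearest-fraction trimming and PAM clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from precohort import (
    DistanceConfig,
    FeatureMatrix,
    FeatureSpec,
    FeatureVariable,
    distances_to_case,
    find_similar,
    gower_distance,
    heom_distance,
    pairwise_distances,
    pam_cluster,
)
from precohort.similarity import EmptySelectionError, UndefinedDistanceError, _pam

MIXED_SPEC = FeatureSpec([
    FeatureVariable("age", "continuous", "age_at_index"),
    FeatureVariable("sex", "categorical", "sex"),
    FeatureVariable("flag", "binary", "atc_prefix", "C07"),
])
MIXED_RANGES = {"age": (0.0, 10.0)}


def mixed_matrix(rows: list[dict], spec=MIXED_SPEC) -> FeatureMatrix:
    df = pd.DataFrame(rows, index=pd.Index(range(1, len(rows) + 1), name="ID"))
    ranges = {
        n: (float(df[n].min()), float(df[n].max())) for n in spec.continuous_names()
    }
    return FeatureMatrix(df, spec, ranges)


class TestGower:
    def test_identical_rows_distance_zero(self):
        a = {"age": 4.0, "sex": "female", "flag": 1}
        assert gower_distance(a, dict(a), MIXED_SPEC, MIXED_RANGES) == 0.0

    def test_single_continuous_range_normalized(self):
        spec = FeatureSpec([FeatureVariable("x", "continuous", "age_at_index")])
        d = gower_distance({"x": 2.0}, {"x": 7.0}, spec, {"x": (0.0, 10.0)})
        assert d == pytest.approx(0.5)

    def test_mixed_average_over_variables(self):
        spec = FeatureSpec([
            FeatureVariable("x", "continuous", "age_at_index"),
            FeatureVariable("b", "binary", "sex"),
        ])
        d = gower_distance({"x": 2.0, "b": 1}, {"x": 7.0, "b": 1}, spec, {"x": (0.0, 10.0)})
        assert d == pytest.approx(0.25)  # (0.5 + 0) / 2

    def test_weights_reweight_contributions(self):
        spec = FeatureSpec([
            FeatureVariable("x", "continuous", "age_at_index"),
            FeatureVariable("b", "binary", "sex"),
        ])
        d = gower_distance({"x": 2.0, "b": 1}, {"x": 7.0, "b": 0}, spec,
                           {"x": (0.0, 10.0)}, weights={"x": 3.0, "b": 1.0})
        assert d == pytest.approx((3 * 0.5 + 1 * 1.0) / 4)

    def test_missing_variable_excluded_from_denominator(self):
        a = {"age": np.nan, "sex": "female", "flag": 1}
        b = {"age": 3.0, "sex": "female", "flag": 0}
        assert gower_distance(a, b, MIXED_SPEC, MIXED_RANGES) == pytest.approx(0.5)

    def test_all_missing_pair_is_undefined(self):
        spec = FeatureSpec([FeatureVariable("x", "continuous", "age_at_index")])
        with pytest.raises(UndefinedDistanceError):
            gower_distance({"x": np.nan}, {"x": 1.0}, spec, {"x": (0.0, 1.0)})

    def test_zero_range_variable_contributes_zero(self, caplog):
        spec = FeatureSpec([
            FeatureVariable("x", "continuous", "age_at_index"),
            FeatureVariable("b", "binary", "sex"),
        ])
        with caplog.at_level("WARNING"):
            d = gower_distance({"x": 5.0, "b": 1}, {"x": 5.0, "b": 0}, spec,
                               {"x": (5.0, 5.0)})
        assert d == pytest.approx(0.5)

    def test_asymmetric_binary_drops_double_zero_pairs(self):
        spec = FeatureSpec([
            FeatureVariable("b1", "binary", "sex"),
            FeatureVariable("b2", "binary", "sex"),
        ])
        a, b = {"b1": 0, "b2": 1}, {"b1": 0, "b2": 0}
        assert gower_distance(a, b, spec, {}) == pytest.approx(0.5)
        assert gower_distance(a, b, spec, {}, binary_handling="asymmetric") == 1.0


class TestHeom:
    def test_identical_rows_distance_zero(self):
        a = {"age": 4.0, "sex": "male", "flag": 0}
        assert heom_distance(a, dict(a), MIXED_SPEC, MIXED_RANGES) == 0.0

    def test_single_nominal_mismatch_scores_one(self):
        a = {"age": 4.0, "sex": "male", "flag": 0}
        b = {"age": 4.0, "sex": "female", "flag": 0}
        assert heom_distance(a, b, MIXED_SPEC, MIXED_RANGES) == 1.0

    def test_two_maximal_differences_give_sqrt2(self):
        a = {"age": 0.0, "sex": "male", "flag": 0}
        b = {"age": 10.0, "sex": "female", "flag": 0}
        assert heom_distance(a, b, MIXED_SPEC, MIXED_RANGES) == pytest.approx(np.sqrt(2))

    def test_missing_scores_maximal_difference(self):
        a = {"age": np.nan, "sex": "male", "flag": 0}
        b = {"age": 4.0, "sex": "male", "flag": 0}
        assert heom_distance(a, b, MIXED_SPEC, MIXED_RANGES) == 1.0

    def test_reduces_to_euclidean_on_unit_range_continuous(self):
        rng = np.random.default_rng(5)
        names = ["a", "b", "c"]
        spec = FeatureSpec([FeatureVariable(n, "continuous", "age_at_index") for n in names])
        ranges = {n: (0.0, 1.0) for n in names}
        for _ in range(50):
            x, y = rng.random(3), rng.random(3)
            d = heom_distance(dict(zip(names, x)), dict(zip(names, y)), spec, ranges)
            assert d == pytest.approx(np.linalg.norm(x - y))


def random_mixed_rows(rng, n):
    return [
        {"age": float(rng.integers(0, 11)),
         "sex": rng.choice(["female", "male", "other"]),
         "flag": int(rng.integers(0, 2))}
        for _ in range(n)
    ]


@pytest.mark.parametrize("metric", ["gower", "heom"])
def test_metric_axioms_on_random_rows(metric):
    """Nonnegativity, symmetry, identity; Gower bounded by 1."""
    rng = np.random.default_rng(42)
    rows = random_mixed_rows(rng, 60)
    fn = gower_distance if metric == "gower" else heom_distance
    for a, b in zip(rows[::2], rows[1::2]):
        dab = fn(a, b, MIXED_SPEC, MIXED_RANGES)
        dba = fn(b, a, MIXED_SPEC, MIXED_RANGES)
        assert dab >= 0 and dab == pytest.approx(dba)
        assert fn(a, dict(a), MIXED_SPEC, MIXED_RANGES) == 0.0
        if metric == "gower":
            assert dab <= 1.0


row_strategy = st.fixed_dictionaries({
    "age": st.one_of(st.floats(0, 10), st.just(float("nan"))),
    "sex": st.sampled_from(["female", "male", "other"]),
    "flag": st.integers(0, 1),
})


@settings(max_examples=150, derandomize=True)
@given(a=row_strategy, b=row_strategy)
def test_metric_axioms_hold_for_arbitrary_rows(a, b):
    """Symmetry, identity and bounds hold for any mixed row pair, missing
    values included (Gower needs one commonly observed variable)."""
    for fn in (gower_distance, heom_distance):
        dab = fn(a, b, MIXED_SPEC, MIXED_RANGES)
        assert dab >= 0
        assert dab == pytest.approx(fn(b, a, MIXED_SPEC, MIXED_RANGES))
        if fn is gower_distance:
            assert dab <= 1.0 + 1e-12
    complete = {**a, "age": 4.0}
    assert gower_distance(complete, dict(complete), MIXED_SPEC, MIXED_RANGES) == 0.0
    assert heom_distance(complete, dict(complete), MIXED_SPEC, MIXED_RANGES) == 0.0


def test_pairwise_matrix_consistent_with_pair_function():
    rng = np.random.default_rng(3)
    m = mixed_matrix(random_mixed_rows(rng, 12))
    for metric in ("gower", "heom"):
        D = pairwise_distances(m, DistanceConfig(metric=metric))
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)
        fn = gower_distance if metric == "gower" else heom_distance
        for i, j in [(0, 5), (2, 9), (4, 11)]:
            expected = fn(m.data.iloc[i].to_dict(), m.data.iloc[j].to_dict(),
                          m.spec, m.ranges)
            assert D[i, j] == pytest.approx(expected)


def test_distances_invariant_under_row_partitioning():
    """Computing distances block-by-block must equal the single pass."""
    rng = np.random.default_rng(8)
    m = mixed_matrix(random_mixed_rows(rng, 40))
    case = {"age": 5.0, "sex": "female", "flag": 1}
    cfg = DistanceConfig()
    full = distances_to_case(m, case, cfg)
    parts = []
    for chunk in np.array_split(np.arange(40), 7):
        sub = FeatureMatrix(m.data.iloc[chunk], m.spec, m.ranges)
        parts.append(distances_to_case(sub, case, cfg))
    assert np.allclose(full, np.concatenate(parts))


class TestNearestFraction:
    def test_paper_scale_fraction_count(self):
        rng = np.random.default_rng(0)
        m = mixed_matrix(random_mixed_rows(rng, 3513))
        case = {"age": 5.0, "sex": "female", "flag": 1}
        result = find_similar(m, case, DistanceConfig(fraction=0.10))
        assert len(result.selected_ids) == 351

    def test_fraction_one_selects_everyone(self):
        rng = np.random.default_rng(1)
        m = mixed_matrix(random_mixed_rows(rng, 37))
        case = {"age": 5.0, "sex": "male", "flag": 0}
        for metric in ("gower", "heom"):
            result = find_similar(m, case, DistanceConfig(metric=metric, fraction=1.0))
            assert sorted(result.selected_ids) == list(m.data.index)

    def test_exact_match_row_selected_first(self):
        rows = [{"age": 9.0, "sex": "male", "flag": 0},
                {"age": 5.0, "sex": "female", "flag": 1},
                {"age": 0.0, "sex": "male", "flag": 1}]
        m = mixed_matrix(rows)
        result = find_similar(m, dict(rows[1]), DistanceConfig(fraction=0.34))
        assert result.selected_ids == [2]
        assert result.cutoff == 0.0

    def test_zero_selection_raises_with_advice(self):
        m = mixed_matrix(random_mixed_rows(np.random.default_rng(2), 5))
        with pytest.raises(EmptySelectionError, match="fraction"):
            find_similar(m, {"age": 1.0, "sex": "male", "flag": 0},
                         DistanceConfig(fraction=0.1))

    @pytest.mark.parametrize("seed", range(6))
    def test_selection_matches_sorting_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        m = mixed_matrix(random_mixed_rows(rng, 50))  # integer ages force ties
        case = {"age": float(rng.integers(0, 11)),
                "sex": "female", "flag": int(rng.integers(0, 2))}
        cfg = DistanceConfig(fraction=0.25)
        result = find_similar(m, case, cfg)
        dist = distances_to_case(m, case, cfg)
        oracle = sorted(zip(dist, m.data.index))[: int(0.25 * 50)]
        assert result.selected_ids == [pid for _, pid in oracle]

    def test_index_case_outside_range_keeps_gower_bounded(self):
        m = mixed_matrix(random_mixed_rows(np.random.default_rng(4), 20))
        case = {"age": 99.0, "sex": "female", "flag": 1}  # far outside (0, 10)
        d = distances_to_case(m, case, DistanceConfig())
        assert np.all((0 <= d) & (d <= 1))


def brute_force_pam_cost(D, k):
    n = D.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestPam:
    def test_k_equals_n_zero_cost(self):
        m = mixed_matrix(random_mixed_rows(np.random.default_rng(0), 6))
        medoids, assignment, cost = pam_cluster(m, k=6)
        assert cost == 0.0
        assert sorted(medoids) == list(m.data.index)
        # every point sits at distance zero from its medoid (ties on
        # duplicate rows resolve to the lowest-ID medoid)
        D = pairwise_distances(m, DistanceConfig(mode="cluster", k=6))
        pos = {pid: i for i, pid in enumerate(m.data.index)}
        for pid, med in assignment.items():
            assert D[pos[pid], pos[med]] == 0.0

    def test_k_one_matches_exhaustive_medoid(self):
        rng = np.random.default_rng(1)
        m = mixed_matrix(random_mixed_rows(rng, 9))
        D = pairwise_distances(m, DistanceConfig(metric="gower", mode="cluster", k=1))
        medoids, _, cost = pam_cluster(m, k=1)
        assert cost == pytest.approx(D.sum(axis=0).min())
        assert medoids[0] == m.data.index[int(np.argmin(D.sum(axis=0)))]

    def test_two_separated_clouds_recovered_optimally(self):
        spec = FeatureSpec([FeatureVariable("x", "continuous", "age_at_index")])
        vals = [0.0, 0.1, 0.2, 0.3, 0.4, 9.0, 9.1, 9.2, 9.3, 9.4]
        df = pd.DataFrame({"x": vals}, index=pd.Index(range(1, 11), name="ID"))
        m = FeatureMatrix(df, spec, {"x": (0.0, 9.4)})
        medoids, assignment, cost = pam_cluster(m, k=2)
        D = pairwise_distances(m, DistanceConfig(mode="cluster", k=2))
        assert cost == pytest.approx(brute_force_pam_cost(D, 2))
        assert set(assignment[df["x"] < 5]) != set(assignment[df["x"] > 5])

    def test_k_exceeding_n_rejected(self):
        m = mixed_matrix(random_mixed_rows(np.random.default_rng(2), 3))
        with pytest.raises(ValueError):
            pam_cluster(m, k=4)

    @pytest.mark.parametrize("seed", range(8))
    def test_converged_solution_is_single_swap_optimal(self, seed):
        """After SWAP terminates, no medoid/non-medoid exchange lowers the
        cost — the algorithm's convergence guarantee."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(1, 4))
        D = rng.random((n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        medoids, _, cost = _pam(D, k)
        for m in medoids:
            for h in range(n):
                if h in medoids:
                    continue
                swapped = [h if x == m else x for x in medoids]
                assert D[:, swapped].min(axis=1).sum() >= cost - 1e-9

    def test_cluster_mode_selects_index_cases_cluster(self):
        spec = FeatureSpec([FeatureVariable("x", "continuous", "age_at_index")])
        vals = [0.0, 0.2, 0.4, 9.0, 9.2, 9.4]
        df = pd.DataFrame({"x": vals}, index=pd.Index(range(1, 7), name="ID"))
        m = FeatureMatrix(df, spec, {"x": (0.0, 9.4)})
        cfg = DistanceConfig(mode="cluster", k=2)
        near_low = find_similar(m, {"x": 0.1}, cfg)
        near_high = find_similar(m, {"x": 9.1}, cfg)
        assert sorted(near_low.selected_ids) == [1, 2, 3]
        assert sorted(near_high.selected_ids) == [4, 5, 6]
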