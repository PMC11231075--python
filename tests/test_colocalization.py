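"""Pairwise/higher-order colocalization scores and differential statistics."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mpxcoloc import (
    AssortativityConfig,
    ScoreField,
    colocalization_matrix,
    differential,
    dots_from_p,
    higher_order_colocalization,
    multisite_similarity,
    pairwise_colocalization,
    permutation_null,
    positive_node_set,
    wilcoxon_rank_sum,
)
from mpxcoloc.colocalization import differential_table, records_to_table

from conftest import exact_rank_sum_oracle, multisite_inclusion_exclusion, rank_then_pearson


def adjusted(values, marker="CD50", cell="c1", nodes=None):
    if nodes is None:
        nodes = tuple(f"a{i}" for i in range(len(values)))
    return ScoreField(cell, marker, tuple(nodes), np.asarray(values, float), "adjusted")


class TestPairwise:
    def test_identical_fields_score_one(self):
        x = adjusted([0.1, -0.2, 0.3, 0.0])
        y = adjusted([0.1, -0.2, 0.3, 0.0], marker="CD44")
        assert pairwise_colocalization(x, y) == pytest.approx(1.0)

    def test_all_zero_field_scores_exactly_zero(self):
        x = adjusted([0.1, -0.2, 0.3])
        z = adjusted([0.0, 0.0, 0.0], marker="CD44")
        assert pairwise_colocalization(x, z) == 0.0

    def test_rank_identical_fields_score_one(self):
        x = adjusted([0.1, 0.3, 0.2, -0.4])
        y = adjusted([1.0, 3.0, 2.0, -5.0], marker="CD44")
        assert pairwise_colocalization(x, y) == pytest.approx(1.0)

    def test_reversed_ranks_score_minus_one(self):
        x = adjusted([1.0, 2.0, 3.0, 4.0])
        y = adjusted([4.0, 3.0, 2.0, 1.0], marker="CD44")
        assert pairwise_colocalization(x, y) == pytest.approx(-1.0)

    def test_misaligned_nodes_rejected(self):
        x = adjusted([0.1, 0.2])
        y = adjusted([0.1, 0.2], marker="CD44", nodes=("b0", "b1"))
        with pytest.raises(ValueError, match="misaligned"):
            pairwise_colocalization(x, y)
        with pytest.raises(ValueError, match="cells"):
            pairwise_colocalization(x, adjusted([0.1, 0.2], marker="CD44", cell="c2"))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_rank_then_pearson_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        # integer draws guarantee ties
        x = rng.integers(-3, 4, size=n).astype(float)
        y = rng.integers(-3, 4, size=n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            pytest.skip("constant draw")
        got = pairwise_colocalization(adjusted(x), adjusted(y, marker="CD44"))
        assert got == pytest.approx(rank_then_pearson(x, y), abs=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_strictly_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        base = pairwise_colocalization(adjusted(x), adjusted(y, marker="CD44"))
        warped = pairwise_colocalization(
            adjusted(np.exp(3 * x)), adjusted(y**3 + 2 * y, marker="CD44")
        )
        assert warped == pytest.approx(base, abs=1e-12)


class TestMatrix:
    def _scores(self):
        rng = np.random.default_rng(0)
        return {
            m: adjusted(rng.normal(size=6), marker=m)
            for m in ("CD50", "CD162", "CD44")
        }

    def test_three_markers_give_three_records(self):
        records = colocalization_matrix(self._scores())
        assert len(records) == 3
        assert all(r.order == 2 for r in records)

    def test_single_marker_gives_empty_list(self):
        assert colocalization_matrix(self._scores(), ["CD50"]) == []

    def test_records_are_symmetric_and_sorted(self):
        scores = self._scores()
        records = {r.markers: r.score for r in colocalization_matrix(scores)}
        assert records[("CD162", "CD50")] == pytest.approx(
            pairwise_colocalization(scores["CD162"], scores["CD50"])
        )
        assert all(m == tuple(sorted(m)) for m in records)


class TestPositiveNodeSet:
    def test_strictly_positive_selection(self):
        x = adjusted([0.2, -0.1, 0.0, 0.5], nodes=("a", "b", "c", "d"))
        assert positive_node_set(x) == {"a", "d"}

    def test_all_zero_field_gives_empty_set(self):
        assert positive_node_set(adjusted([0.0, 0.0])) == set()


class TestMultisiteSimilarity:
    def test_t2_equals_sorensen(self):
        a, b = {1, 2, 3}, {2, 3, 4}
        got = multisite_similarity([a, b])
        assert got == pytest.approx(2 / 3)
        assert got == pytest.approx(2 * len(a & b) / (len(a) + len(b)))

    def test_identical_sets_score_one(self):
        s = {1, 2}
        assert multisite_similarity([s, s, s]) == pytest.approx(1.0)

    @pytest.mark.parametrize("t", [2, 3, 4])
    def test_disjoint_sets_score_zero(self, t):
        sets = [{10 * i, 10 * i + 1} for i in range(t)]
        assert multisite_similarity(sets) == 0.0

    def test_empty_family_scores_zero(self):
        assert multisite_similarity([set(), set(), set()]) == 0.0

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            multisite_similarity([{1, 2}])

    @pytest.mark.parametrize("seed", range(10))
    def test_closed_form_equals_inclusion_exclusion_long_form(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(2, 5))
        sets = [
            set(rng.choice(12, size=rng.integers(0, 9), replace=False).tolist())
            for _ in range(t)
        ]
        long_form = multisite_inclusion_exclusion(sets)
        size_sum = sum(len(s) for s in sets)
        closed = (
            Fraction(0)
            if size_sum == 0
            else Fraction(t, t - 1) * (1 - Fraction(len(set().union(*sets)), size_sum))
        )
        assert long_form == closed  # exact integer arithmetic
        assert multisite_similarity(sets) == pytest.approx(float(closed), abs=1e-12)
        assert 0.0 <= multisite_similarity(sets) <= 1.0


class TestHigherOrder:
    def test_k2_reduces_to_sorensen(self):
        scores = {
            "CD50": adjusted([0.5, 0.2, -0.1, 0.0]),
            "CD44": adjusted([0.3, -0.2, 0.4, 0.0], marker="CD44"),
        }
        rec = higher_order_colocalization(scores, ("CD50", "CD44"))
        a, b = {"a0", "a1"}, {"a0", "a2"}
        assert rec.score == pytest.approx(2 * len(a & b) / (len(a) + len(b)))

    def test_filtered_marker_lowers_the_score(self):
        x = adjusted([0.5, 0.2, 0.1])
        y = adjusted([0.4, 0.3, 0.2], marker="CD44")
        z = adjusted([0.0, 0.0, 0.0], marker="CD37")
        pair = multisite_similarity([positive_node_set(x), positive_node_set(y)])
        rec = higher_order_colocalization({"CD50": x, "CD44": y, "CD37": z},
                                          ("CD50", "CD44", "CD37"))
        assert rec.score < pair
        assert rec.order == 3


class TestWilcoxon:
    def test_fully_separated_three_vs_three(self):
        # smallest attainable two-sided p with 3 vs 3 and no ties
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        p = wilcoxon_rank_sum([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p > 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_path_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        a = rng.integers(0, 6, size=n1).astype(float)  # ties likely
        b = rng.integers(0, 6, size=n2).astype(float)
        assert wilcoxon_rank_sum(a, b) == pytest.approx(
            exact_rank_sum_oracle(a, b), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_path_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.normal(size=6)
        b = rng.normal(size=5)
        _, p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert wilcoxon_rank_sum(a, b) == pytest.approx(p_scipy, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=60).astype(float)
        b = rng.integers(1, 6, size=60).astype(float)
        _, p_scipy = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic")
        assert wilcoxon_rank_sum(a, b) == pytest.approx(float(p_scipy))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestDifferential:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.5, 0), (0.011, 0), (0.01, 1), (0.005, 1), (0.0011, 1),
            (0.001, 2), (0.0005, 2), (0.00011, 2),
            (0.0001, 3), (0.00005, 3), (1e-300, 3),
        ],
    )
    def test_dots_mapping_boundaries(self, p, expected):
        assert dots_from_p(p) == expected

    def test_identical_samples(self):
        r = differential([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], ("CD50", "CD44"))
        assert r.mean_diff == 0.0
        assert r.p_value > 0.01
        assert r.dots == 0

    def test_separated_samples(self):
        r = differential([1, 2, 3], [4, 5, 6], ("CD50", "CD44"))
        assert r.mean_diff == pytest.approx(-3.0)
        assert r.p_value == pytest.approx(0.1)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2 cells"):
            differential([1.0], [1.0, 2.0], ("CD50", "CD44"))

    def test_benjamini_hochberg_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        results = [
            differential(rng.normal(size=8), rng.normal(loc=mu, size=8), (f"M{i}", "X"))
            for i, mu in enumerate([0.0, 0.5, 1.0, 2.0, 3.0])
        ]
        df = differential_table(results, benjamini_hochberg=True)
        _, q_ref, _, _ = multipletests(df["p_value"], method="fdr_bh")
        np.testing.assert_allclose(df["q_value"], q_ref, atol=1e-12)


class TestPermutationNull:
    @pytest.fixture
    def scored_barbell(self):
        from conftest import barbell_anode
        from mpxcoloc import PanelManifest

        g = barbell_anode()
        counts = g.node_counts.copy()
        for iso in ("mIgG2b", "mIgG1", "mIgG2a"):
            counts[iso] = 0.2
        g.node_counts = counts
        panel = PanelManifest(
            markers=("CD50", "mIgG2b", "mIgG1", "mIgG2a"),
            isotype_markers=frozenset({"mIgG2b", "mIgG1", "mIgG2a"}),
        )
        cfg = AssortativityConfig(vertex_threshold=3)
        return g, panel, cfg

    def test_zero_permutations_return_observed(self, scored_barbell):
        g, panel, cfg = scored_barbell
        from mpxcoloc import adjusted_local_assortativity

        observed = adjusted_local_assortativity(g, "CD50", cfg, panel)
        corrected = permutation_null(g, "CD50", cfg, panel, n_perm=0, seed=1)
        np.testing.assert_array_equal(corrected.values, observed.values)

    def test_same_seed_reproduces_corrected_field(self, scored_barbell):
        g, panel, cfg = scored_barbell
        c1 = permutation_null(g, "CD50", cfg, panel, n_perm=10, seed=42)
        c2 = permutation_null(g, "CD50", cfg, panel, n_perm=10, seed=42)
        np.testing.assert_array_equal(c1.values, c2.values)
        c3 = permutation_null(g, "CD50", cfg, panel, n_perm=10, seed=43)
        assert not np.array_equal(c1.values, c3.values)


def test_records_table_layout():
    recs = [
        higher_order_colocalization(
            {
                "CD50": adjusted([0.1, 0.2, -0.1]),
                "CD44": adjusted([0.2, 0.1, 0.3], marker="CD44"),
                "CD37": adjusted([0.3, -0.2, 0.1], marker="CD37"),
            },
            ("CD50", "CD44", "CD37"),
        )
    ]
    df = records_to_table(recs)
    assert list(df.columns) == ["cell_id", "markers", "order", "score"]
    assert df.loc[0, "markers"] == "CD37+CD44+CD50"
    assert df.loc[0, "order"] == 3
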