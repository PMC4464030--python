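import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miregnet.biclique import (
    MIRNA_TO_MRNA,
    MRNA_TO_MIRNA,
    Bicluster,
    _join_ids,
    _pair_objective,
    aggregate_bicliques,
    aggregate_pair,
    compactness,
    compute_direction_stats,
    extract_bicliques,
    initial_bicliques,
    jaccard,
    merge_directions,
    prune,
)
from miregnet.io import InteractionMatrix


def matrix_from(values, prefix=("m", "g")):
    values = np.asarray(values, dtype=float)
    mirnas = tuple(f"{prefix[0]}{i}" for i in range(values.shape[0]))
    genes = tuple(f"{prefix[1]}{j}" for j in range(values.shape[1]))
    return InteractionMatrix(mirnas, genes, values)


class TestCompactness:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[1, 1], [0, 0]], 0.5),
            ([[1.0, 0.5], [1.0, 0.5], [0.0, 0.0]], 0.5),  # 3x2 summing to 3
        ],
    )
    def test_block_means(self, values, expected):
        A = matrix_from(values)
        C = Bicluster("0", frozenset(A.genes), frozenset(A.mirnas))
        assert compactness(C, A) == pytest.approx(expected)

    def test_empty_dimension_rejected(self):
        A = matrix_from([[1.0]])
        with pytest.raises(ValueError):
            compactness(Bicluster("0", frozenset(), frozenset({"m0"})), A)


class TestJaccard:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [({"g1", "g2"}, {"g2", "g3"}, 1 / 3),
         ({"g1"}, {"g1"}, 1.0),
         ({"g1"}, {"g2"}, 0.0)],
    )
    def test_values(self, s1, s2, expected):
        assert jaccard(frozenset(s1), frozenset(s2)) == pytest.approx(expected)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(frozenset(), frozenset())

    @given(st.sets(st.integers(0, 10)), st.sets(st.integers(0, 10)))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_and_bounded(self, s1, s2):
        if not (s1 | s2):
            return
        v = jaccard(frozenset(s1), frozenset(s2))
        assert 0.0 <= v <= 1.0
        assert v == jaccard(frozenset(s2), frozenset(s1))


class TestDirectionStats:
    def test_hand_count_on_uniform_matrix(self, tiny_matrix):
        stats = compute_direction_stats(tiny_matrix, 0.5, MIRNA_TO_MRNA)
        assert stats.avg_opposite == 3
        assert stats.min_own == 3
        assert stats.abs_min_own == 3

    def test_outlier_trimming_discards_the_smallest_counts(self):
        # 999 miRNAs target 10 genes; 1 miRNA targets a single gene.
        # floor(0.0015 * 1000) = 1 count is discarded, so the trimmed
        # minimum skips the outlier while the absolute minimum keeps it.
        values = np.zeros((1000, 11))
        values[:999, :10] = 0.6
        values[999, 10] = 0.6
        stats = compute_direction_stats(matrix_from(values), 0.5, MIRNA_TO_MRNA)
        assert stats.min_own == 10
        assert stats.abs_min_own == 1

    def test_empty_reliable_graph_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="empty reliable graph"):
            compute_direction_stats(tiny_matrix, 0.7, MIRNA_TO_MRNA)

    def test_threshold_is_strict(self):
        A = matrix_from([[0.5]])
        with pytest.raises(ValueError):
            compute_direction_stats(A, 0.5, MIRNA_TO_MRNA)


class TestInitialBicliques:
    def test_each_seed_collects_its_reliable_partners(self):
        A = matrix_from([[0.9, 0.8, 0.1], [0.0, 0.0, 0.0]])
        out = initial_bicliques(A, 0.5, MIRNA_TO_MRNA)
        assert len(out) == 1   # m1 has no score > beta, contributes nothing
        assert out[0].genes == frozenset({"g0", "g1"})
        assert out[0].mirnas == frozenset({"m0"})

    def test_uniform_matrix_gives_full_rows(self, tiny_matrix):
        out = initial_bicliques(tiny_matrix, 0.5, MIRNA_TO_MRNA)
        assert len(out) == 3 and all(len(b.genes) == 3 for b in out)

    def test_raising_beta_never_adds_bicliques(self, tiny_matrix):
        n = [len(initial_bicliques(tiny_matrix, b, MIRNA_TO_MRNA))
             for b in (0.3, 0.59)]
        assert n[1] <= n[0]
        with pytest.raises(ValueError):
            compute_direction_stats(tiny_matrix, 0.61, MIRNA_TO_MRNA)


class TestAggregation:
    def test_aggregate_intersects_genes_and_unions_mirnas(self):
        C1 = Bicluster("1", frozenset("abc"), frozenset({"x"}))
        C2 = Bicluster("2", frozenset("bcd"), frozenset({"y"}))
        agg = aggregate_pair(C1, C2, MIRNA_TO_MRNA)
        assert agg.genes == frozenset("bc")
        assert agg.mirnas == frozenset({"x", "y"})
        assert agg.id == "1_2"

    def test_disjoint_gene_sets_are_never_admissible(self, tiny_matrix):
        stats = compute_direction_stats(tiny_matrix, 0.5, MIRNA_TO_MRNA)
        C1 = Bicluster("1", frozenset({"g1"}), frozenset({"m1"}))
        C2 = Bicluster("2", frozenset({"g2"}), frozenset({"m2"}))
        assert _pair_objective(C1, C2, stats, tiny_matrix) is None

    def _oracle_trace(self, bicliques, stats, A):
        """Exhaustive per-step argmax of jaccard x q with the same tie-break."""
        active = {b.id: b for b in bicliques}
        chosen = []
        while True:
            best = None
            for i1, i2 in itertools.combinations(sorted(active), 2):
                res = _pair_objective(active[i1], active[i2], stats, A)
                if res is None:
                    continue
                score, agg = res
                jid = _join_ids(i1, i2)
                if (
                    best is None
                    or score > best[0]
                    or (score == best[0] and jid < best[1])
                ):
                    best = (score, jid, i1, i2, agg)
            if best is None:
                return chosen
            _, _, i1, i2, agg = best
            chosen.append(frozenset((i1, i2)))
            del active[i1], active[i2]
            active[agg.id] = agg

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_steps_match_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        A = matrix_from(rng.random((8, 8)) * 0.999)
        stats = compute_direction_stats(A, 0.3, MIRNA_TO_MRNA)
        init = initial_bicliques(A, 0.3, MIRNA_TO_MRNA)
        trace: list = []
        aggregate_bicliques(init, stats, A, trace=trace)
        assert trace == self._oracle_trace(init, stats, A)

    def test_aggregates_are_bicliques_on_thresholded_graph(self, planted_fixture):
        A, _ = planted_fixture
        beta = 0.5
        for direction in (MIRNA_TO_MRNA, MRNA_TO_MIRNA):
            stats = compute_direction_stats(A, beta, direction)
            out = aggregate_bicliques(
                initial_bicliques(A, beta, direction), stats, A
            )
            for b in out:
                for m in b.mirnas:
                    for g in b.genes:
                        assert A.score(m, g) > beta

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        A = matrix_from(rng.random((6, 6)) * 0.999)
        stats = compute_direction_stats(A, 0.3, MIRNA_TO_MRNA)
        init = initial_bicliques(A, 0.3, MIRNA_TO_MRNA)
        fwd = aggregate_bicliques(init, stats, A)
        rev = aggregate_bicliques(list(reversed(init)), stats, A)
        assert [b.id for b in fwd] == [b.id for b in rev]


class TestPruneAndMerge:
    def test_small_bicliques_are_pruned(self):
        b1 = Bicluster("1", frozenset({"g1", "g2"}), frozenset({"m1"}))
        b2 = Bicluster("2", frozenset({"g1", "g2"}), frozenset({"m2", "m3"}))
        kept, isolated = prune([b1, b2], abs_min_mirna=2, abs_min_mrna=1)
        assert [b.id for b in kept] == ["2"]
        assert isolated["mirnas"] == ["m1"]

    def test_all_pass_means_no_isolated(self):
        b = Bicluster("1", frozenset({"g1"}), frozenset({"m1"}))
        kept, isolated = prune([b], 1, 1)
        assert kept == [b]
        assert isolated == {"mirnas": [], "genes": []}

    def test_merge_directions_collapses_exact_duplicates_only(self):
        a = Bicluster("1", frozenset({"g1", "g2"}), frozenset({"m1"}))
        dup = Bicluster("9", frozenset({"g1", "g2"}), frozenset({"m1"}))
        subset = Bicluster("2", frozenset({"g1"}), frozenset({"m1"}))
        other = Bicluster("3", frozenset({"g3"}), frozenset({"m3"}))
        merged = merge_directions([a, subset], [dup, other])
        ids = {b.id for b in merged}
        assert ids == {"1_9", "2", "3"}


class TestExtractBicliques:
    def test_recovers_planted_modules(self, planted_fixture):
        A, truth = planted_fixture
        kept, isolated = extract_bicliques(A, 0.5)
        assert len(kept) == len(truth)
        assert not isolated["mirnas"] and not isolated["genes"]
        found = {(b.mirnas, b.genes) for b in kept}
        for tm, tg in truth:
            assert (frozenset(tm), frozenset(tg)) in found

    def test_retained_interactions_monotone_in_beta(self, planted_fixture):
        A, _ = planted_fixture
        counts = [int((A.values > b).sum()) for b in (0.3, 0.4, 0.5)]
        assert counts[0] >= counts[1] >= counts[2]
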