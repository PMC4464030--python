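import numpy as np
import pytest

from miregnet.biclique import Bicluster, extract_bicliques
from miregnet.hierarchy import (
    Embeddings,
    build_hierarchy,
    detect_overlap_pair,
    embed_objects,
    merge_candidates,
    merge_level,
    overlap_pass,
)
from miregnet.io import InteractionMatrix
from miregnet.simulate import PlantedDesign, planted_matrix

from conftest import super_module_matrix


def matrix_from(values):
    values = np.asarray(values, dtype=float)
    return InteractionMatrix(
        tuple(f"m{i}" for i in range(values.shape[0])),
        tuple(f"g{j}" for j in range(values.shape[1])),
        values,
    )


class TestEmbeddings:
    def test_mirna_embeddings_are_matrix_rows(self):
        A = matrix_from([[0.0, 0.7, 0.0], [0.2, 0.0, 0.9]])
        emb = embed_objects(A, "mirnas")
        assert len(emb["m0"]) == 3
        assert emb["m0"][1] == 0.7

    def test_gene_embeddings_are_matrix_columns(self):
        A = matrix_from([[0.0, 0.7], [0.2, 0.0]])
        emb = embed_objects(A, "genes")
        assert np.array_equal(emb["g0"], [0.0, 0.2])

    def test_zero_row_gives_zero_vector(self):
        A = matrix_from([[0.0, 0.0], [0.5, 0.5]])
        assert not embed_objects(A, "mirnas")["m0"].any()


def two_block_matrix(seed=0, hi=0.9, lo=0.1):
    rng = np.random.default_rng(seed)
    values = np.full((10, 20), lo) + rng.uniform(-0.05, 0.05, (10, 20))
    values[:5, :10] = hi + rng.uniform(-0.05, 0.05, (5, 10))
    values[5:, 10:] = hi + rng.uniform(-0.05, 0.05, (5, 10))
    return matrix_from(np.clip(values, 0, 1))


class TestOverlapDetection:
    def test_separable_blocks_are_left_unchanged(self):
        A = two_block_matrix()
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset(A.genes[:10]), frozenset(A.mirnas[:5]))
        C2 = Bicluster("2", frozenset(A.genes[10:]), frozenset(A.mirnas[5:]))
        n1, n2 = detect_overlap_pair(C1, C2, emb)
        assert n1.members == C1.members and n2.members == C2.members

    def test_object_profiled_like_the_other_bicluster_is_added_to_it(self):
        A = two_block_matrix()
        # m4 nominally belongs to C1 but its profile is C2's block profile
        values = A.values.copy()
        values[4, :] = 0.0
        values[4, 10:] = 0.9
        A = matrix_from(values)
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset(A.genes[:10]), frozenset(A.mirnas[:5]))
        C2 = Bicluster("2", frozenset(A.genes[10:]), frozenset(A.mirnas[5:]))
        _, n2 = detect_overlap_pair(C1, C2, emb)
        assert "m4" in n2.mirnas

    def test_identical_biclusters_rejected(self):
        A = two_block_matrix()
        emb = Embeddings.from_matrix(A)
        C = Bicluster("1", frozenset(A.genes[:10]), frozenset(A.mirnas[:5]))
        with pytest.raises(ValueError):
            detect_overlap_pair(C, C, emb)

    def test_overlap_pass_only_adds_members(self):
        A = two_block_matrix(seed=2)
        emb = Embeddings.from_matrix(A)
        level = [
            Bicluster("1", frozenset(A.genes[:10]), frozenset(A.mirnas[:5])),
            Bicluster("2", frozenset(A.genes[10:]), frozenset(A.mirnas[5:])),
        ]
        out = overlap_pass(level, emb, A)
        by_id = {b.id: b for b in out}
        for b in level:
            assert b.genes <= by_id[b.id].genes
            assert b.mirnas <= by_id[b.id].mirnas


class TestMergeCandidates:
    def test_identical_biclusters_are_candidates(self):
        A = two_block_matrix()
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset(A.genes[:10]), frozenset(A.mirnas[:5]))
        C2 = Bicluster("2", frozenset(A.genes[:10]), frozenset(A.mirnas[:5]))
        assert merge_candidates([C1, C2], emb) == {frozenset({"1", "2"})}

    def test_distant_singletons_are_not_candidates(self):
        A = matrix_from([[0.9, 0.0], [0.0, 0.9]])
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset({"g0"}), frozenset({"m0"}))
        C2 = Bicluster("2", frozenset({"g1"}), frozenset({"m1"}))
        assert merge_candidates([C1, C2], emb) == set()

    def test_boundary_distance_is_inclusive(self):
        # two singleton miRNA clusters at distance exactly 2*sigma'+2*sigma''
        # on the miRNA dimension: sigma = 0, so we use two-member clusters
        # whose centroid gap equals the sigma budget
        values = np.zeros((4, 1))
        values[:, 0] = [0.0, 0.2, 0.4, 0.6]
        A = matrix_from(values)
        emb = Embeddings.from_matrix(A)
        # centroids 0.1 and 0.5 -> dist 0.4; sigma = 0.1 each -> 2s+2s = 0.4
        C1 = Bicluster("1", frozenset({"g0"}), frozenset({"m0", "m1"}))
        C2 = Bicluster("2", frozenset({"g0"}), frozenset({"m2", "m3"}))
        assert frozenset({"1", "2"}) in merge_candidates([C1, C2], emb)


class TestMergeLevel:
    def test_union_passing_alpha_is_merged(self):
        A = matrix_from(np.ones((4, 4)))
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset(A.genes[:2]), frozenset(A.mirnas[:2]))
        C2 = Bicluster("2", frozenset(A.genes[2:]), frozenset(A.mirnas[2:]))
        nxt, links, merge_q = merge_level([C1, C2], A, alpha=0.3, embeddings=emb)
        assert len(nxt) == 1 and nxt[0].id == "1_2"
        assert merge_q["1_2"] == 1.0
        assert links == {"1": "1_2", "2": "1_2"}

    def test_union_q_equal_alpha_is_not_merged(self):
        A = matrix_from(np.full((2, 2), 0.5))
        emb = Embeddings.from_matrix(A)
        C1 = Bicluster("1", frozenset({"g0"}), frozenset({"m0"}))
        C2 = Bicluster("2", frozenset({"g1"}), frozenset({"m1"}))
        # identical embeddings force candidacy; union q = 0.5 exactly
        nxt, links, merge_q = merge_level([C1, C2], A, alpha=0.5, embeddings=emb)
        assert len(nxt) == 2 and not merge_q

    def test_best_of_multiple_candidacies_wins(self):
        # three mutual candidates; pair (1,2) has union q 0.8, (1,3) 0.6
        values = np.array(
            [[0.8, 0.8, 0.4], [0.8, 0.8, 0.4], [0.4, 0.4, 0.8]]
        )
        A = matrix_from(values)
        emb = Embeddings.from_matrix(A)
        bs = [
            Bicluster("1", frozenset({"g0"}), frozenset({"m0"})),
            Bicluster("2", frozenset({"g1"}), frozenset({"m1"})),
            Bicluster("3", frozenset({"g2"}), frozenset({"m2"})),
        ]
        nxt, links, merge_q = merge_level(bs, A, alpha=0.1, embeddings=emb)
        assert links["1"] == "1_2" and links["2"] == "1_2"
        assert links["3"] == "3"      # copied upward unchanged
        assert merge_q["1_2"] == pytest.approx(0.8)


class TestBuildHierarchy:
    def test_far_apart_modules_give_single_level(self):
        design = PlantedDesign.grid(n_modules=2, seed=4)
        A, _ = planted_matrix(design)
        step1, _ = extract_bicliques(A, 0.5)
        h = build_hierarchy(step1, A, alpha=0.3)
        assert h.n_levels == 1

    def test_all_ones_matrix_collapses_to_a_root(self):
        A = matrix_from(np.ones((4, 8)))
        emb = Embeddings.from_matrix(A)
        seeds = [
            Bicluster(str(k), frozenset(A.genes[2 * k: 2 * k + 2]),
                      frozenset([A.mirnas[k]]))
            for k in range(4)
        ]
        h = build_hierarchy(seeds, A, alpha=0.1, embeddings=emb)
        root_level = h.levels[-1]
        assert len(root_level) == 1
        assert root_level[0].members == set(A.mirnas) | set(A.genes)

    def test_two_super_modules_merge_into_two_parents(self):
        A, modules = super_module_matrix(seed=1)
        step1, _ = extract_bicliques(A, 0.5)
        assert len(step1) == 4
        h = build_hierarchy(step1, A, alpha=0.5)
        assert h.n_levels == 2
        assert len(h.levels[1]) == 2
        for b in h.levels[1]:
            assert len(b.mirnas) == 20 and len(b.genes) == 80

    def test_higher_alpha_never_gives_more_levels(self):
        for seed in range(5):
            A, _ = super_module_matrix(seed=seed)
            step1, _ = extract_bicliques(A, 0.5)
            lo = build_hierarchy(step1, A, alpha=0.1).n_levels
            hi = build_hierarchy(step1, A, alpha=0.5).n_levels
            assert hi <= lo

    def test_structural_invariants_hold(self):
        A, _ = super_module_matrix(seed=2)
        step1, _ = extract_bicliques(A, 0.5)
        h = build_hierarchy(step1, A, alpha=0.4)
        h.check_invariants()   # raises on violation
        for li, links in enumerate(h.parent_links):
            parents = {b.id: b for b in h.levels[li + 1]}
            for child in h.levels[li]:
                p = parents[links[child.id]]
                assert child.genes <= p.genes and child.mirnas <= p.mirnas

    def test_max_levels_below_one_rejected(self):
        A = matrix_from(np.ones((2, 2)))
        b = Bicluster("1", frozenset(A.genes), frozenset(A.mirnas))
        with pytest.raises(ValueError):
            build_hierarchy([b], A, alpha=0.5, max_levels=0)
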