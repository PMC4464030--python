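"""Overlap detection and iterative merging into a bicluster hierarchy.

Step 2 of the biclustering.  Objects are embedded by their score profiles:
a miRNA's coordinates are its row of the interaction matrix, a gene's its
column.  For every pair of biclusters at a level, a linear max-margin
separator is trained per dimension on the members exclusive to one side;
members it misclassifies plausibly belong to both biclusters and are added
to the one that did not contain them (batch semantics: additions are applied
after the full pass over all pairs, so the result is order-independent).

Two biclusters are merge candidates when their member centroids are close
on at least one dimension:

    dist(C', C'') - 2*sigma(C') - 2*sigma(C'') <= 0

with ``dist`` the Euclidean centroid distance and ``sigma`` the RMS radius
of a cluster.  A candidate pair is merged (component-wise union) only if
the union's compactness exceeds the quality threshold ``alpha``; a
bicluster involved in several passing candidacies takes only its maximum-q
merge.  Each round of overlap detection plus merging produces one hierarchy
level; unmerged biclusters are copied upward so every level is a complete
clustering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from .biclique import Bicluster, _join_ids, compactness
from .io import InteractionMatrix

logger = logging.getLogger(__name__)

MAX_LEVELS_DEFAULT = 10

GENE_DIM = "genes"
MIRNA_DIM = "mirnas"


@dataclass(frozen=True)
class SVMConfig:
    """Linear max-margin separator settings for overlap detection."""

    C: float = 1.0
    kernel: str = "linear"


def embed_objects(A: InteractionMatrix, dimension: str) -> dict[str, np.ndarray]:
    """Score-profile coordinates: rows for miRNAs, columns for genes."""
    if dimension == MIRNA_DIM:
        return {m: A.values[i, :].copy() for i, m in enumerate(A.mirnas)}
    if dimension == GENE_DIM:
        return {g: A.values[:, j].copy() for j, g in enumerate(A.genes)}
    raise ValueError(f"unknown dimension {dimension!r}")


@dataclass
class Embeddings:
    """Cached score-profile embeddings for both object kinds."""

    mirnas: dict[str, np.ndarray]
    genes: dict[str, np.ndarray]

    @classmethod
    def from_matrix(cls, A: InteractionMatrix) -> "Embeddings":
        return cls(embed_objects(A, MIRNA_DIM), embed_objects(A, GENE_DIM))

    def of(self, dimension: str) -> dict[str, np.ndarray]:
        return self.mirnas if dimension == MIRNA_DIM else self.genes


def _misclassified(
    excl1: list[str],
    excl2: list[str],
    coords: dict[str, np.ndarray],
    config: SVMConfig,
) -> tuple[set[str], set[str]]:
    """Objects on the wrong side of the separating hyperplane.

    Returns (members of side 1 classified as side 2, and vice versa).
    """
    X = np.vstack([coords[o] for o in excl1 + excl2])
    y = np.concatenate([np.zeros(len(excl1)), np.ones(len(excl2))])
    clf = SVC(C=config.C, kernel=config.kernel).fit(X, y)
    pred = clf.predict(X)
    wrong1 = {o for o, p in zip(excl1, pred[: len(excl1)]) if p == 1}
    wrong2 = {o for o, p in zip(excl2, pred[len(excl1):]) if p == 0}
    return wrong1, wrong2


def detect_overlap_pair(
    C1: Bicluster,
    C2: Bicluster,
    embeddings: Embeddings,
    svm_config: SVMConfig = SVMConfig(),
) -> tuple[Bicluster, Bicluster]:
    """Grow two biclusters by the objects a linear separator misclassifies.

    Per dimension, the separator is trained (and evaluated) on members
    exclusive to one bicluster; shared members are untouched.  A dimension
    with no exclusive members on either side is skipped.
    """
    if C1.genes == C2.genes and C1.mirnas == C2.mirnas:
        raise ValueError("cannot detect overlap of a bicluster with itself")
    add1: dict[str, set[str]] = {GENE_DIM: set(), MIRNA_DIM: set()}
    add2: dict[str, set[str]] = {GENE_DIM: set(), MIRNA_DIM: set()}
    for dim in (GENE_DIM, MIRNA_DIM):
        s1 = getattr(C1, dim)
        s2 = getattr(C2, dim)
        excl1 = sorted(s1 - s2)
        excl2 = sorted(s2 - s1)
        if not excl1 or not excl2:
            logger.debug(
                "overlap %s/%s: dimension %s has no exclusive members, skipped",
                C1.id, C2.id, dim,
            )
            continue
        wrong1, wrong2 = _misclassified(
            excl1, excl2, embeddings.of(dim), svm_config
        )
        add2[dim] |= wrong1   # C1 members resembling C2 join C2
        add1[dim] |= wrong2
    new1 = replace(
        C1, genes=C1.genes | add1[GENE_DIM], mirnas=C1.mirnas | add1[MIRNA_DIM]
    )
    new2 = replace(
        C2, genes=C2.genes | add2[GENE_DIM], mirnas=C2.mirnas | add2[MIRNA_DIM]
    )
    return new1, new2


def overlap_pass(
    level: list[Bicluster],
    embeddings: Embeddings,
    A: InteractionMatrix,
    svm_config: SVMConfig = SVMConfig(),
) -> list[Bicluster]:
    """One batch overlap-augmentation pass over all pairs of a level.

    Additions are computed against the input biclusters for every pair and
    applied afterwards, so the outcome does not depend on pair order.
    Compactness is refreshed for grown biclusters.
    """
    level = sorted(level, key=lambda b: b.id)
    additions: dict[str, dict[str, set[str]]] = {
        b.id: {GENE_DIM: set(), MIRNA_DIM: set()} for b in level
    }
    for C1, C2 in itertools.combinations(level, 2):
        if C1.genes == C2.genes and C1.mirnas == C2.mirnas:
            continue
        n1, n2 = detect_overlap_pair(C1, C2, embeddings, svm_config)
        additions[C1.id][GENE_DIM] |= n1.genes - C1.genes
        additions[C1.id][MIRNA_DIM] |= n1.mirnas - C1.mirnas
        additions[C2.id][GENE_DIM] |= n2.genes - C2.genes
        additions[C2.id][MIRNA_DIM] |= n2.mirnas - C2.mirnas
    out = []
    for b in level:
        add = additions[b.id]
        if add[GENE_DIM] or add[MIRNA_DIM]:
            b = replace(
                b,
                genes=b.genes | add[GENE_DIM],
                mirnas=b.mirnas | add[MIRNA_DIM],
            )
        out.append(b.with_compactness(A))
    return out


def _centroid_sigma(
    members: frozenset[str], coords: dict[str, np.ndarray]
) -> tuple[np.ndarray, float]:
    X = np.vstack([coords[o] for o in sorted(members)])
    centroid = X.mean(axis=0)
    sigma = float(np.sqrt(np.mean(np.sum((X - centroid) ** 2, axis=1))))
    return centroid, sigma


def merge_candidates(
    level: list[Bicluster], embeddings: Embeddings
) -> set[frozenset[str]]:
    """Pairs of biclusters close on at least one dimension (2-sigma rule)."""
    if len(level) < 2:
        return set()
    geom: dict[str, dict[str, tuple[np.ndarray, float]]] = {
        GENE_DIM: {}, MIRNA_DIM: {}
    }
    for b in level:
        geom[GENE_DIM][b.id] = _centroid_sigma(b.genes, embeddings.genes)
        geom[MIRNA_DIM][b.id] = _centroid_sigma(b.mirnas, embeddings.mirnas)
    out: set[frozenset[str]] = set()
    for C1, C2 in itertools.combinations(level, 2):
        for dim in (GENE_DIM, MIRNA_DIM):
            c1, s1 = geom[dim][C1.id]
            c2, s2 = geom[dim][C2.id]
            dist = float(np.linalg.norm(c1 - c2))
            if dist - 2.0 * s1 - 2.0 * s2 <= 0.0:
                out.add(frozenset((C1.id, C2.id)))
                break
    return out


def _union_bicluster(C1: Bicluster, C2: Bicluster, level: int) -> Bicluster:
    return Bicluster(
        id=_join_ids(C1.id, C2.id),
        genes=C1.genes | C2.genes,
        mirnas=C1.mirnas | C2.mirnas,
        level=level,
    )


def merge_level(
    level: list[Bicluster],
    A: InteractionMatrix,
    alpha: float,
    embeddings: Embeddings,
) -> tuple[list[Bicluster], dict[str, str], dict[str, float]]:
    """Merge candidate pairs whose union passes the quality constraint q > alpha.

    Each bicluster participates in at most one merge -- its maximum-q one
    (ties broken on the lexicographically smallest joined id).  Unmerged
    biclusters are copied to the next level unchanged with a self-parent
    link.  Returns (next level, child id -> parent id links, and the union
    compactness of each merged parent).
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    level = sorted(level, key=lambda b: b.id)
    by_id = {b.id: b for b in level}
    next_lvl = level[0].level + 1 if level else 1
    passing: list[tuple[float, str, str, str]] = []  # (q, joined, id1, id2)
    for pair in merge_candidates(level, embeddings):
        i1, i2 = sorted(pair)
        union = _union_bicluster(by_id[i1], by_id[i2], next_lvl)
        q = compactness(union, A)
        if q > alpha:
            passing.append((q, union.id, i1, i2))
    passing.sort(key=lambda t: (-t[0], t[1]))
    used: set[str] = set()
    parents: list[Bicluster] = []
    links: dict[str, str] = {}
    merge_q: dict[str, float] = {}
    for q, _, i1, i2 in passing:
        if i1 in used or i2 in used:
            continue
        used |= {i1, i2}
        parent = _union_bicluster(by_id[i1], by_id[i2], next_lvl)
        parent = replace(parent, compactness=q)
        parents.append(parent)
        links[i1] = parent.id
        links[i2] = parent.id
        merge_q[parent.id] = q
    for b in level:
        if b.id not in used:
            parents.append(replace(b, level=next_lvl))
            links[b.id] = b.id
    return sorted(parents, key=lambda b: b.id), links, merge_q


@dataclass
class Hierarchy:
    """Bottom-up levels of biclusters with child -> parent links per level."""

    levels: list[list[Bicluster]]
    parent_links: list[dict[str, str]]   # transition l -> l+1
    alpha: float
    beta: float | None = None
    isolated: dict[str, list[str]] = field(
        default_factory=lambda: {"mirnas": [], "genes": []}
    )
    #: union compactness of each merged parent at merge time, keyed by
    #: parent id per transition (a later overlap pass may grow the parent
    #: and so change its final compactness)
    merge_q: list[dict[str, float]] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def bicluster(self, bicluster_id: str) -> Bicluster | None:
        for lvl in self.levels:
            for b in lvl:
                if b.id == bicluster_id:
                    return b
        return None

    def check_invariants(self) -> None:
        """Structural guarantees, asserted on every built hierarchy.

        Merged (non-self-parent) biclusters have q > alpha; every child's
        member sets are subsets of its parent's; all compactness values lie
        in [0, 1].
        """
        for li, links in enumerate(self.parent_links):
            lvl = self.levels[li]
            by_parent: dict[str, list[Bicluster]] = {}
            for b in lvl:
                by_parent.setdefault(links[b.id], []).append(b)
            parent_level = {b.id: b for b in self.levels[li + 1]}
            merge_q = self.merge_q[li] if li < len(self.merge_q) else {}
            for pid, children in by_parent.items():
                parent = parent_level[pid]
                for ch in children:
                    if not (ch.genes <= parent.genes and ch.mirnas <= parent.mirnas):
                        raise AssertionError(
                            f"child {ch.id} not contained in parent {pid}"
                        )
                if len(children) > 1 and not merge_q.get(pid, 0.0) > self.alpha:
                    raise AssertionError(
                        f"merged bicluster {pid} violates q > alpha"
                    )
        for lvl in self.levels:
            for b in lvl:
                if b.compactness is not None and not (
                    0.0 <= b.compactness <= 1.0
                ):
                    raise AssertionError(f"compactness of {b.id} outside [0, 1]")


def build_hierarchy(
    step1_biclusters: list[Bicluster],
    A: InteractionMatrix,
    alpha: float,
    embeddings: Embeddings | None = None,
    max_levels: int = MAX_LEVELS_DEFAULT,
    svm_config: SVMConfig = SVMConfig(),
    beta: float | None = None,
) -> Hierarchy:
    """Iterate overlap detection and merging into a level hierarchy.

    Level 1 is the step-1 biclique set after the first overlap pass; each
    subsequent round applies one overlap pass and one merge pass.  Building
    stops when a merge pass merges nothing or *max_levels* is reached.
    """
    if max_levels < 1:
        raise ValueError("max_levels must be >= 1")
    if not step1_biclusters:
        raise ValueError("step-1 bicluster set is empty")
    if embeddings is None:
        embeddings = Embeddings.from_matrix(A)
    current = [replace(b, level=1) for b in step1_biclusters]
    levels: list[list[Bicluster]] = []
    links_per_level: list[dict[str, str]] = []
    merge_q_per_level: list[dict[str, float]] = []
    for lvl in range(1, max_levels + 1):
        current = overlap_pass(current, embeddings, A, svm_config)
        levels.append(current)
        if lvl == max_levels:
            break
        nxt, links, merge_q = merge_level(current, A, alpha, embeddings)
        if not merge_q:
            break
        links_per_level.append(links)
        merge_q_per_level.append(merge_q)
        logger.info(
            "level %d: %d biclusters -> %d at level %d",
            lvl, len(current), len(nxt), lvl + 1,
        )
        current = nxt
    h = Hierarchy(
        levels=levels,
        parent_links=links_per_level,
        alpha=alpha,
        beta=beta,
        merge_q=merge_q_per_level,
    )
    h.check_invariants()
    return h
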