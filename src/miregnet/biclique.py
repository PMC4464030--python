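"""Biclique seeding, greedy aggregation, pruning and direction merging.

Step 1 of the hierarchical biclustering: the weighted interaction matrix is
thresholded at the reliability cutoff ``beta`` (strictly: an interaction
counts only when its score is *greater than* ``beta``).  In each direction
(miRNA-to-gene and gene-to-miRNA) an initial biclique is seeded per object
-- e.g. one miRNA together with the set of genes it targets -- and pairs of
bicliques are then greedily aggregated: the aggregate intersects the seeded
side and unions the other, so every aggregate is again a biclique on the
thresholded graph.

Aggregation of ``C'`` and ``C''`` (miRNA-to-gene direction) requires

    |C'_r intersect C''_r| >= min_mrna    and
    |C'_c union C''_c|     <= avg_mirna

and among admissible pairs the one maximizing

    jaccard(C'_r, C''_r) * q(aggregate(C', C''), A)

is chosen, where the compactness ``q(C, A)`` is the mean score over the
``|C_r| x |C_c|`` block of ``A``.  Bicliques smaller than the absolute
minima from the direction statistics are pruned; uncovered objects are
reported as isolated/noise.  Finally the two directions' results are merged
with exact duplicates collapsed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable

from .io import InteractionMatrix

logger = logging.getLogger(__name__)

#: fraction of the smallest per-object degree counts discarded as outliers
#: when computing the outlier-proof minimum (three-sigma rule under an
#: assumed Gaussian degree distribution).
TRIM_FRACTION = 0.0015

MIRNA_TO_MRNA = "mirna_to_mrna"
MRNA_TO_MIRNA = "mrna_to_mirna"


@dataclass(frozen=True)
class Bicluster:
    """A pair (gene set C_r, miRNA set C_c) with cached compactness.

    The id records lineage: aggregating two bicliques joins their ids with
    an underscore, so e.g. "379_405" descends from seeds 379 and 405.
    """

    id: str
    genes: frozenset[str]
    mirnas: frozenset[str]
    level: int = 1
    compactness: float | None = None

    @property
    def members(self) -> frozenset[str]:
        return self.genes | self.mirnas

    def with_compactness(self, A: InteractionMatrix) -> "Bicluster":
        return replace(self, compactness=compactness(self, A))


def compactness(C: Bicluster, A: InteractionMatrix) -> float:
    """q(C, A): mean score over all |C_r| * |C_c| cells of the block."""
    if not C.genes or not C.mirnas:
        raise ValueError("bicluster has an empty dimension")
    return A.submatrix_mean(C.mirnas, C.genes)


def jaccard(s1: frozenset, s2: frozenset) -> float:
    """|S1 n S2| / |S1 u S2|."""
    union = s1 | s2
    if not union:
        raise ValueError("jaccard of two empty sets is undefined")
    return len(s1 & s2) / len(union)


@dataclass(frozen=True)
class DirectionStats:
    """Degree statistics of the beta-thresholded bipartite graph.

    For the miRNA-to-gene direction: ``avg_opposite`` is avg_mirna (average
    number of miRNAs targeting each gene), ``min_own`` is min_mrna (the
    outlier-proof minimum number of genes targeted per miRNA) and
    ``abs_min_own`` the absolute minimum.
    """

    direction: str
    beta: float
    avg_opposite: float
    min_own: int
    abs_min_own: int

    def __post_init__(self) -> None:
        if self.abs_min_own > self.min_own:
            raise ValueError("abs_min_own must be <= min_own")


def compute_direction_stats(
    A: InteractionMatrix, beta: float, direction: str
) -> DirectionStats:
    """Degree statistics on the graph of interactions with score > beta.

    Counts consider only objects with at least one retained interaction;
    the outlier-proof minimum discards the floor(0.0015 * n) smallest
    per-object counts before taking the minimum.
    """
    mask = A.values > beta
    if not mask.any():
        raise ValueError(f"empty reliable graph at beta={beta}")
    if direction == MIRNA_TO_MRNA:
        own_counts = mask.sum(axis=1)       # genes per miRNA
        opp_counts = mask.sum(axis=0)       # miRNAs per gene
    elif direction == MRNA_TO_MIRNA:
        own_counts = mask.sum(axis=0)
        opp_counts = mask.sum(axis=1)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    own = sorted(int(c) for c in own_counts if c > 0)
    opp = [int(c) for c in opp_counts if c > 0]
    trim = math.floor(TRIM_FRACTION * len(own))
    return DirectionStats(
        direction=direction,
        beta=beta,
        avg_opposite=sum(opp) / len(opp),
        min_own=own[trim],
        abs_min_own=own[0],
    )


def initial_bicliques(
    A: InteractionMatrix, beta: float, direction: str, start_id: int = 0
) -> list[Bicluster]:
    """One biclique per seed object: the object plus its beta-reliable partners.

    Ids are sequential integers (as strings) from *start_id*, assigned in
    lexicographic seed order.
    """
    mask = A.values > beta
    out: list[Bicluster] = []
    next_id = start_id
    if direction == MIRNA_TO_MRNA:
        for i, mirna in enumerate(A.mirnas):
            genes = frozenset(g for j, g in enumerate(A.genes) if mask[i, j])
            if genes:
                out.append(Bicluster(str(next_id), genes, frozenset([mirna])))
                next_id += 1
    elif direction == MRNA_TO_MIRNA:
        for j, gene in enumerate(A.genes):
            mirnas = frozenset(m for i, m in enumerate(A.mirnas) if mask[i, j])
            if mirnas:
                out.append(Bicluster(str(next_id), frozenset([gene]), mirnas))
                next_id += 1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return out


def _join_ids(id1: str, id2: str) -> str:
    return "_".join(sorted((id1, id2)))


def aggregate_pair(C1: Bicluster, C2: Bicluster, direction: str) -> Bicluster:
    """Aggregate two bicliques: intersect the seeded side, union the other."""
    if direction == MIRNA_TO_MRNA:
        genes, mirnas = C1.genes & C2.genes, C1.mirnas | C2.mirnas
    else:
        genes, mirnas = C1.genes | C2.genes, C1.mirnas & C2.mirnas
    return Bicluster(_join_ids(C1.id, C2.id), genes, mirnas)


def _pair_objective(
    C1: Bicluster, C2: Bicluster, stats: DirectionStats, A: InteractionMatrix
) -> tuple[float, Bicluster] | None:
    """Jaccard x compactness of the admissible aggregate, or None."""
    if stats.direction == MIRNA_TO_MRNA:
        own1, own2 = C1.genes, C2.genes
        other = C1.mirnas | C2.mirnas
    else:
        own1, own2 = C1.mirnas, C2.mirnas
        other = C1.genes | C2.genes
    inter = own1 & own2
    if len(inter) < stats.min_own or len(other) > stats.avg_opposite:
        return None
    agg = aggregate_pair(C1, C2, stats.direction)
    score = jaccard(own1, own2) * compactness(agg, A)
    return score, agg


def aggregate_bicliques(
    bicliques: Iterable[Bicluster],
    stats: DirectionStats,
    A: InteractionMatrix,
    trace: list[frozenset[str]] | None = None,
) -> list[Bicluster]:
    """Greedy aggregation until no admissible pair remains.

    At each step the admissible pair maximizing jaccard x q(aggregate) is
    replaced by its aggregate; ties break on the smallest joined id, making
    the result independent of input order.  Pair objectives are cached and
    only recomputed for pairs involving the newest aggregate.  When *trace*
    is given, the id pair chosen at each step is appended to it.
    """
    active: dict[str, Bicluster] = {b.id: b for b in bicliques}
    # cache: (id1, id2) sorted -> (score, aggregate)
    cache: dict[tuple[str, str], tuple[float, Bicluster]] = {}
    ids = sorted(active)
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            res = _pair_objective(active[ids[a_i]], active[ids[b_i]], stats, A)
            if res is not None:
                cache[(ids[a_i], ids[b_i])] = res
    while cache:
        key = max(cache, key=lambda k: (cache[k][0], _neg_lex(_join_ids(*k))))
        _, agg = cache[key]
        i1, i2 = key
        if trace is not None:
            trace.append(frozenset((i1, i2)))
        del active[i1], active[i2]
        cache = {
            k: v for k, v in cache.items() if i1 not in k and i2 not in k
        }
        for other_id, other in active.items():
            res = _pair_objective(agg, other, stats, A)
            if res is not None:
                cache[tuple(sorted((agg.id, other_id)))] = res
        active[agg.id] = agg
    return sorted(
        (b.with_compactness(A) for b in active.values()), key=lambda b: b.id
    )


class _neg_lex(str):
    """String wrapper with reversed ordering, for max() tie-breaking."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


def prune(
    bicliques: Iterable[Bicluster],
    abs_min_mirna: int,
    abs_min_mrna: int,
) -> tuple[list[Bicluster], dict[str, list[str]]]:
    """Drop bicliques below the absolute size minima; report isolated objects.

    An object of the input bicliques that appears in no kept bicluster is
    isolated/noise.  Returns (kept, {"mirnas": [...], "genes": [...]}).
    """
    if abs_min_mirna < 1 or abs_min_mrna < 1:
        raise ValueError("size thresholds must be >= 1")
    bicliques = list(bicliques)
    kept = [
        b
        for b in bicliques
        if len(b.mirnas) >= abs_min_mirna and len(b.genes) >= abs_min_mrna
    ]
    cov_m = set().union(*(b.mirnas for b in kept)) if kept else set()
    cov_g = set().union(*(b.genes for b in kept)) if kept else set()
    all_m = set().union(*(b.mirnas for b in bicliques)) if bicliques else set()
    all_g = set().union(*(b.genes for b in bicliques)) if bicliques else set()
    isolated = {
        "mirnas": sorted(all_m - cov_m),
        "genes": sorted(all_g - cov_g),
    }
    return sorted(kept, key=lambda b: b.id), isolated


def merge_directions(
    set1: Iterable[Bicluster], set2: Iterable[Bicluster]
) -> list[Bicluster]:
    """Union of the two directions' bicliques, exact duplicates collapsed.

    Bicliques with identical gene and miRNA sets collapse to one whose id
    joins the duplicates' ids.
    """
    by_members: dict[tuple[frozenset, frozenset], Bicluster] = {}
    for b in list(set1) + list(set2):
        key = (b.genes, b.mirnas)
        if key in by_members:
            prev = by_members[key]
            by_members[key] = replace(prev, id=_join_ids(prev.id, b.id))
        else:
            by_members[key] = b
    return sorted(by_members.values(), key=lambda b: b.id)


def extract_bicliques(
    A: InteractionMatrix, beta: float
) -> tuple[list[Bicluster], dict[str, list[str]]]:
    """Full step 1: both directions, aggregation, direction merge, pruning.

    Returns the pruned biclique set and the isolated-object report.  The
    absolute pruning minima come from the two directions' statistics:
    abs_min_mrna from the miRNA-to-gene direction, abs_min_mirna from the
    gene-to-miRNA direction.
    """
    stats_m2g = compute_direction_stats(A, beta, MIRNA_TO_MRNA)
    stats_g2m = compute_direction_stats(A, beta, MRNA_TO_MIRNA)
    b_m2g = initial_bicliques(A, beta, MIRNA_TO_MRNA)
    b_g2m = initial_bicliques(A, beta, MRNA_TO_MIRNA, start_id=len(b_m2g))
    agg_m2g = aggregate_bicliques(b_m2g, stats_m2g, A)
    agg_g2m = aggregate_bicliques(b_g2m, stats_g2m, A)
    merged = merge_directions(agg_m2g, agg_g2m)
    kept, isolated = prune(
        merged,
        abs_min_mirna=stats_g2m.abs_min_own,
        abs_min_mrna=stats_m2g.abs_min_own,
    )
    logger.info(
        "step1: beta=%.3g, %d+%d initial bicliques -> %d aggregated -> %d kept "
        "(%d isolated miRNAs, %d isolated genes)",
        beta, len(b_m2g), len(b_g2m), len(merged), len(kept),
        len(isolated["mirnas"]), len(isolated["genes"]),
    )
    return kept, isolated
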