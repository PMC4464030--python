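"""Functional-coherence ranking of biclusters via GO semantic similarity.

A good regulatory module should group genes that are functionally related.
Pairwise gene similarity is SimGIC, the IC-weighted Jaccard of the two
genes' GO term sets:

    SimGIC(x1, x2) = sum_{t in GO(x1) n GO(x2)} IC(t)
                     / sum_{t in GO(x1) u GO(x2)} IC(t)

For each bicluster ``C`` at a hierarchy level ``L`` we sample intra
similarities (gene pairs within ``C``) and inter similarities (a gene of
``C`` against genes of the other biclusters at ``L``), then test

    H0: mu0(C) = mu(L, C)    vs    H1: mu0(C) > mu(L, C)

with a one-tailed two-sample t-test (Welch, unequal variances).  The lower
the p-value, the more functionally coherent the bicluster relative to its
level.  Two rankings are produced, one per GO namespace: p_BP and p_MF.
Genes without usable annotation are excluded from the samples (not scored
0), and pair samples larger than a cap are uniformly subsampled (seeded)
to keep large biclusters tractable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .biclique import Bicluster
from .ontology import AnnotationStore

logger = logging.getLogger(__name__)

#: maximum number of gene pairs per similarity sample before subsampling.
PAIR_CAP_DEFAULT = 2000
#: reporting threshold for "significant" bicluster counts.
SIGNIFICANCE_LEVEL = 0.05


def simgic(g1: str, g2: str, store: AnnotationStore) -> float | None:
    """IC-weighted Jaccard of two genes' term sets; None when undefined."""
    t1 = store.closed.get(g1)
    t2 = store.closed.get(g2)
    if not t1 or not t2:
        return None
    ic = store.ic
    # sorted iteration keeps the float sums exactly symmetric in (g1, g2)
    union_ic = sum(ic.get(t, 0.0) for t in sorted(t1 | t2))
    if union_ic <= 0.0:
        return None
    inter_ic = sum(ic.get(t, 0.0) for t in sorted(t1 & t2))
    return inter_ic / union_ic


class _SimgicCache:
    """Memoized pairwise SimGIC for one annotation store."""

    def __init__(self, store: AnnotationStore) -> None:
        self.store = store
        self._cache: dict[tuple[str, str], float | None] = {}

    def __call__(self, g1: str, g2: str) -> float | None:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        if key not in self._cache:
            self._cache[key] = simgic(key[0], key[1], self.store)
        return self._cache[key]


def _subsample(pairs: list[tuple[str, str]], cap: int, rng: np.random.Generator):
    if cap is not None and len(pairs) > cap:
        idx = rng.choice(len(pairs), size=cap, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    return pairs


def similarity_samples(
    C: Bicluster,
    level: list[Bicluster],
    store: AnnotationStore,
    cap: int = PAIR_CAP_DEFAULT,
    seed: int = 0,
    _sim: _SimgicCache | None = None,
) -> tuple[list[float], list[float]]:
    """Intra- and inter-bicluster SimGIC samples for one bicluster.

    Intra: unordered annotated gene pairs within ``C``.  Inter: pairs of an
    annotated gene of ``C`` with an annotated gene of the other biclusters
    at the same level that is not itself in ``C``.  Samples exceeding *cap*
    pairs are uniformly subsampled with a seeded generator; undefined
    similarities are dropped after subsampling.
    """
    sim = _sim or _SimgicCache(store)
    rng = np.random.default_rng(seed)
    annotated = sorted(g for g in C.genes if g in store.closed)
    others = sorted(
        {
            g
            for b in level
            if b.id != C.id
            for g in b.genes
            if g not in C.genes and g in store.closed
        }
    )
    intra_pairs = list(itertools.combinations(annotated, 2))
    inter_pairs = [(g, h) for g in annotated for h in others]
    intra_pairs = _subsample(intra_pairs, cap, rng)
    inter_pairs = _subsample(inter_pairs, cap, rng)
    intra = [v for g, h in intra_pairs if (v := sim(g, h)) is not None]
    inter = [v for g, h in inter_pairs if (v := sim(g, h)) is not None]
    return intra, inter


def one_tailed_welch(intra: list[float], inter: list[float]) -> float:
    """p-value of H1: mean(intra) > mean(inter); 1 when uninformative.

    Degenerate cases: either sample smaller than 2 gives p = 1; two
    zero-variance samples give p = 1 on equal means, 0 when the intra mean
    is strictly larger (the direction of H1) and 1 otherwise.
    """
    if len(intra) < 2 or len(inter) < 2:
        return 1.0
    a = np.asarray(intra, dtype=float)
    b = np.asarray(inter, dtype=float)
    if a.var() == 0.0 and b.var() == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 1.0
        return 0.0 if a.mean() > b.mean() else 1.0
    p = sps.ttest_ind(a, b, equal_var=False, alternative="greater").pvalue
    return float(p) if np.isfinite(p) else 1.0


@dataclass
class RankedBicluster:
    """One bicluster's functional-coherence statistics at its level."""

    id: str
    level: int
    p_bp: float
    p_mf: float
    mu0_bp: float | None
    mu_inter_bp: float | None
    mu0_mf: float | None
    mu_inter_mf: float | None
    n_annotated: int
    compactness: float | None = None
    n_genes: int = 0
    n_mirnas: int = 0


def rank_level(
    level: list[Bicluster],
    store_bp: AnnotationStore,
    store_mf: AnnotationStore | None = None,
    cap: int = PAIR_CAP_DEFAULT,
    seed: int = 0,
) -> list[RankedBicluster]:
    """Rank a hierarchy level by functional coherence (ascending p_BP, id).

    When no Molecular Function store is supplied, p_MF is reported as 1.
    The output is invariant to the input order of biclusters.
    """
    if not level:
        raise ValueError("empty level")
    level = sorted(level, key=lambda b: b.id)
    caches = {
        "BP": _SimgicCache(store_bp),
        "MF": _SimgicCache(store_mf) if store_mf is not None else None,
    }
    out = []
    for i, b in enumerate(level):
        stats_ns: dict[str, tuple[float, float | None, float | None]] = {}
        for ns, cache in caches.items():
            if cache is None:
                stats_ns[ns] = (1.0, None, None)
                continue
            intra, inter = similarity_samples(
                b, level, cache.store, cap=cap, seed=seed + i, _sim=cache
            )
            p = one_tailed_welch(intra, inter)
            mu0 = float(np.mean(intra)) if intra else None
            mu_inter = float(np.mean(inter)) if inter else None
            stats_ns[ns] = (p, mu0, mu_inter)
        n_annot = sum(1 for g in b.genes if g in store_bp.closed)
        out.append(
            RankedBicluster(
                id=b.id,
                level=b.level,
                p_bp=stats_ns["BP"][0],
                p_mf=stats_ns["MF"][0],
                mu0_bp=stats_ns["BP"][1],
                mu_inter_bp=stats_ns["BP"][2],
                mu0_mf=stats_ns["MF"][1],
                mu_inter_mf=stats_ns["MF"][2],
                n_annotated=n_annot,
                compactness=b.compactness,
                n_genes=len(b.genes),
                n_mirnas=len(b.mirnas),
            )
        )
    return sorted(out, key=lambda r: (r.p_bp, r.id))
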