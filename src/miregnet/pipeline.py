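"""End-to-end orchestration: combine -> bicluster -> rank, plus query/export.

The pipeline composes the three stages -- PU score combination, biclique
extraction with hierarchy building, and functional ranking -- and writes
their artifacts (scores TSV, hierarchy JSON, ranking TSV) together with a
manifest recording alpha, beta, seeds and the package version, so that an
identical configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .biclique import Bicluster, extract_bicliques
from .hierarchy import Hierarchy, build_hierarchy
from .io import (
    InteractionMatrix,
    mark_validated,
    read_predictions,
    read_validated_pairs,
)
from .ontology import close_and_score, read_gaf, read_obo
from .pu import PUDataset, baseline_sa, baseline_wsa, pu_combine
from .ranking import PAIR_CAP_DEFAULT, rank_level

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Stage: combine
# ---------------------------------------------------------------------------

def combine_scores(
    predictions_path: str | Path,
    validated_path: str | Path | None,
    algorithm_names: list[str],
    method: str = "pu",
    weights: list[float] | None = None,
    K: int = 10,
    seed: int = 0,
    missing_token: str = "NA",
) -> pd.DataFrame:
    """Combine upstream scores into one reliability score per pair.

    method "pu" runs the three-stage PU ensemble (requires a validated
    list); "sa" and "wsa" are the score-averaging baselines.  Returns a
    DataFrame (mirna, gene, score).
    """
    records = read_predictions(predictions_path, algorithm_names, missing_token)
    if validated_path is not None:
        pairs = read_validated_pairs(validated_path)
        records, unmatched = mark_validated(records, pairs)
        if unmatched:
            logger.info("%d validated pairs not in prediction table", len(unmatched))
    features = records[algorithm_names].to_numpy(dtype=float)
    if method == "pu":
        if not records["validated"].any():
            raise ValueError("PU combination requires validated (positive) pairs")
        data = PUDataset(
            features=features,
            labels=records["validated"].to_numpy(),
            pair_ids=tuple(zip(records["mirna"], records["gene"])),
        )
        scores, c = pu_combine(data, K=K, seed=seed)
        logger.info("estimated label frequency c = %.3f", c)
    elif method == "sa":
        scores = baseline_sa(features)
    elif method == "wsa":
        if weights is None:
            raise ValueError("method 'wsa' requires weights")
        scores = baseline_wsa(features, weights)
    else:
        raise ValueError(f"unknown combination method {method!r}")
    scores = np.clip(scores, 0.0, 1.0)
    return pd.DataFrame(
        {"mirna": records["mirna"], "gene": records["gene"], "score": scores}
    )


# ---------------------------------------------------------------------------
# Hierarchy serialization
# ---------------------------------------------------------------------------

def hierarchy_to_dict(h: Hierarchy) -> dict:
    return {
        "manifest": {
            "alpha": h.alpha,
            "beta": h.beta,
            "package": "miregnet",
            "version": __version__,
        },
        "levels": [
            [
                {
                    "id": b.id,
                    "level": b.level,
                    "genes": sorted(b.genes),
                    "mirnas": sorted(b.mirnas),
                    "compactness": b.compactness,
                }
                for b in lvl
            ]
            for lvl in h.levels
        ],
        "parent_links": h.parent_links,
        "merge_q": h.merge_q,
        "isolated": h.isolated,
    }


def hierarchy_from_dict(d: dict) -> Hierarchy:
    levels = [
        [
            Bicluster(
                id=bd["id"],
                genes=frozenset(bd["genes"]),
                mirnas=frozenset(bd["mirnas"]),
                level=bd["level"],
                compactness=bd["compactness"],
            )
            for bd in lvl
        ]
        for lvl in d["levels"]
    ]
    return Hierarchy(
        levels=levels,
        parent_links=[dict(x) for x in d["parent_links"]],
        alpha=d["manifest"]["alpha"],
        beta=d["manifest"]["beta"],
        isolated=d.get("isolated", {"mirnas": [], "genes": []}),
        merge_q=[dict(x) for x in d.get("merge_q", [])],
    )


def write_hierarchy_json(h: Hierarchy, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(hierarchy_to_dict(h), indent=2, sort_keys=True) + "\n"
    )


def read_hierarchy_json(path: str | Path) -> Hierarchy:
    return hierarchy_from_dict(json.loads(Path(path).read_text()))


def hierarchy_to_graphml(h: Hierarchy, path: str | Path) -> None:
    """Export the hierarchy as GraphML: nodes = biclusters, edges = parent links."""
    g = nx.DiGraph()
    for lvl in h.levels:
        for b in lvl:
            g.add_node(
                f"L{b.level}:{b.id}",
                level=b.level,
                n_genes=len(b.genes),
                n_mirnas=len(b.mirnas),
                compactness=-1.0 if b.compactness is None else b.compactness,
            )
    for li, links in enumerate(h.parent_links):
        for child, parent in links.items():
            g.add_edge(f"L{li + 1}:{child}", f"L{li + 2}:{parent}")
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Stage: bicluster + rank
# ---------------------------------------------------------------------------

def bicluster_matrix(
    A: InteractionMatrix,
    beta: float,
    alpha: float,
    max_levels: int = 10,
) -> Hierarchy:
    """Run biclique extraction (step 1) and hierarchy building (step 2)."""
    step1, isolated = extract_bicliques(A, beta)
    if not step1:
        raise ValueError("no bicliques survive pruning; lower beta")
    h = build_hierarchy(step1, A, alpha=alpha, max_levels=max_levels, beta=beta)
    h.isolated = isolated
    return h


def rank_hierarchy(
    h: Hierarchy,
    obo_path: str | Path,
    gaf_path: str | Path,
    namespaces: tuple[str, ...] = ("BP", "MF"),
    cap: int = PAIR_CAP_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank every hierarchy level by functional coherence (step 3)."""
    graph = read_obo(obo_path)
    direct, _ = read_gaf(gaf_path, graph)
    store_bp = close_and_score(direct, graph, "BP") if "BP" in namespaces else None
    store_mf = None
    if "MF" in namespaces:
        try:
            store_mf = close_and_score(direct, graph, "MF")
        except ValueError:
            logger.warning("no MF annotations; p_MF reported as 1")
    if store_bp is None:
        raise ValueError("BP namespace is required for ranking")
    rows = []
    for lvl in h.levels:
        for r in rank_level(lvl, store_bp, store_mf, cap=cap, seed=seed):
            rows.append(dataclasses.asdict(r))
    df = pd.DataFrame(rows)
    return df.sort_values(["level", "p_bp", "id"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All inputs and parameters of a combine -> bicluster -> rank run."""

    predictions: str | None = None
    validated: str | None = None
    algorithm_names: list[str] = field(default_factory=list)
    matrix: str | None = None          # alternative to predictions: 3-col TSV
    obo: str | None = None
    gaf: str | None = None
    out_dir: str = "miregnet_out"
    method: str = "pu"
    weights: list[float] | None = None
    K: int = 10
    beta: float = 0.5
    alpha: float = 0.3
    max_levels: int = 10
    cap: int = PAIR_CAP_DEFAULT
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all configured stages; return a dict of artifact paths.

    Inputs are validated before any stage runs; identical configurations
    produce byte-identical artifacts.
    """
    inputs = [
        p
        for p in (config.predictions, config.validated, config.matrix,
                  config.obo, config.gaf)
        if p is not None
    ]
    for p in inputs:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
    if config.matrix is None and config.predictions is None:
        raise ValueError("config must name either a prediction table or a matrix")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    if config.predictions is not None:
        scores = combine_scores(
            config.predictions,
            config.validated,
            config.algorithm_names,
            method=config.method,
            weights=config.weights,
            K=config.K,
            seed=config.seed,
        )
        scores_path = out_dir / "scores.tsv"
        scores.to_csv(scores_path, sep="\t", index=False)
        artifacts["scores"] = str(scores_path)
        A = InteractionMatrix.from_pairs(
            zip(scores["mirna"], scores["gene"], scores["score"])
        )
    else:
        A = InteractionMatrix.read_tsv(config.matrix)

    h = bicluster_matrix(A, beta=config.beta, alpha=config.alpha,
                         max_levels=config.max_levels)
    hierarchy_path = out_dir / "hierarchy.json"
    write_hierarchy_json(h, hierarchy_path)
    artifacts["hierarchy"] = str(hierarchy_path)

    if config.obo is not None and config.gaf is not None:
        ranking = rank_hierarchy(
            h, config.obo, config.gaf, cap=config.cap, seed=config.seed
        )
        ranking_path = out_dir / "ranking.tsv"
        ranking.to_csv(ranking_path, sep="\t", index=False)
        artifacts["ranking"] = str(ranking_path)

    manifest = {
        "alpha": config.alpha,
        "beta": config.beta,
        "seed": config.seed,
        "method": config.method,
        "K": config.K,
        "max_levels": config.max_levels,
        "cap": config.cap,
        "version": __version__,
        "artifacts": artifacts,
        "n_levels": h.n_levels,
        "n_level1_biclusters": len(h.levels[0]),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = str(manifest_path)
    return artifacts


# ---------------------------------------------------------------------------
# Query and export
# ---------------------------------------------------------------------------

def query_biclusters(
    h: Hierarchy,
    ranking: pd.DataFrame | None = None,
    levels: set[int] | None = None,
    max_p_bp: float | None = None,
    max_p_mf: float | None = None,
    min_compactness: float | None = None,
    members: list[str] | None = None,
    member_mode: str = "and",
    bicluster_id: str | None = None,
) -> pd.DataFrame:
    """Filter biclusters by level, p-values, compactness, members or id.

    All provided filters must hold (member filters combine in AND by
    default; ``member_mode="or"`` switches to OR).  An unknown bicluster id
    yields an empty result with a notice.
    """
    rows = []
    pvals: dict[tuple[int, str], tuple[float, float]] = {}
    if ranking is not None:
        for _, r in ranking.iterrows():
            pvals[(int(r["level"]), str(r["id"]))] = (
                float(r["p_bp"]), float(r["p_mf"])
            )
    for lvl in h.levels:
        for b in lvl:
            p_bp, p_mf = pvals.get((b.level, b.id), (float("nan"), float("nan")))
            rows.append(
                {
                    "id": b.id,
                    "level": b.level,
                    "compactness": b.compactness,
                    "p_bp": p_bp,
                    "p_mf": p_mf,
                    "n_genes": len(b.genes),
                    "n_mirnas": len(b.mirnas),
                    "_members": b.members,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    if bicluster_id is not None:
        df = df[df["id"] == bicluster_id]
        if df.empty:
            logger.warning("unknown bicluster id %r", bicluster_id)
    if levels is not None:
        df = df[df["level"].isin(levels)]
    if max_p_bp is not None:
        df = df[df["p_bp"] <= max_p_bp]
    if max_p_mf is not None:
        df = df[df["p_mf"] <= max_p_mf]
    if min_compactness is not None:
        df = df[df["compactness"] >= min_compactness]
    if members:
        if member_mode == "and":
            keep = df["_members"].map(lambda s: all(m in s for m in members))
        elif member_mode == "or":
            keep = df["_members"].map(lambda s: any(m in s for m in members))
        else:
            raise ValueError("member_mode must be 'and' or 'or'")
        df = df[keep]
    return df.drop(columns="_members").reset_index(drop=True)


def export_network(
    bicluster: Bicluster,
    A: InteractionMatrix,
    min_edge_score: float = 0.0,
    hide_isolated: bool = False,
) -> nx.Graph:
    """Bipartite miRNA-gene graph of one bicluster's interactions.

    Edges carry their interaction score; only recorded interactions with
    score >= *min_edge_score* are included.  With *hide_isolated*, nodes of
    degree 0 after filtering are removed.
    """
    g = nx.Graph()
    for m in sorted(bicluster.mirnas):
        g.add_node(m, kind="mirna")
    for gene in sorted(bicluster.genes):
        g.add_node(gene, kind="gene")
    for m in sorted(bicluster.mirnas):
        for gene in sorted(bicluster.genes):
            s = A.score(m, gene)
            if s > 0.0 and s >= min_edge_score:
                g.add_edge(m, gene, score=s)
    if hide_isolated:
        g.remove_nodes_from([n for n, d in dict(g.degree()).items() if d == 0])
    return g
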