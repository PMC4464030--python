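"""Seeded synthetic fixtures: planted score matrices, SCAR PU data, toy GO.

These generators define the study conditions under which the pipeline is
validated.  Everything is a pure function of its seed and parameters.

* :func:`planted_matrix` plants disjoint (optionally chained-overlapping)
  miRNA x gene modules with uniform in-module signal scores against a
  sparse uniform noise background, and returns the ground-truth modules
  for recovery scoring.
* :func:`pu_scores` draws true interaction labels Bernoulli(prior), gives
  each class per-dimension uniform score distributions separated by a
  shift, and labels true positives with constant probability ``c``
  (selected completely at random, the SCAR assumption).
* :func:`toy_ontology` grows a random tree-shaped ontology of bounded
  depth and annotates genes at random, except that each "coherent" gene
  group shares a dedicated deep (hence rare, high-IC) term -- the
  annotation structure the coherence ranking is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import InteractionMatrix
from .ontology import OntologyGraph
from .pu import PUDataset

#: background scores below this value are dropped, keeping the noise floor
#: sparse like real genome-wide prediction tables.
SPARSIFY_THRESHOLD = 0.05


def _mirna_name(i: int) -> str:
    return f"hsa-mir-{i:04d}"


def _gene_name(j: int) -> str:
    return f"GENE{j:04d}"


@dataclass
class PlantedDesign:
    """Layout of a planted-module interaction matrix."""

    n_mirna: int
    n_mrna: int
    modules: list[tuple[list[int], list[int]]]  # (miRNA indices, gene indices)
    signal_range: tuple[float, float] = (0.7, 1.0)
    noise_range: tuple[float, float] = (0.0, 0.2)
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo_s, hi_s = self.signal_range
        lo_n, hi_n = self.noise_range
        if not (0.0 <= lo_n <= hi_n <= 1.0 and 0.0 <= lo_s <= hi_s <= 1.0):
            raise ValueError("ranges must be within [0, 1]")
        if lo_s <= hi_n:
            raise ValueError("signal low must exceed noise high (separability)")
        if not (0.0 <= self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1)")
        for ms, gs in self.modules:
            if any(not 0 <= i < self.n_mirna for i in ms):
                raise ValueError("module miRNA index out of bounds")
            if any(not 0 <= j < self.n_mrna for j in gs):
                raise ValueError("module gene index out of bounds")

    @classmethod
    def grid(
        cls,
        n_modules: int = 4,
        mirnas_per_module: int = 10,
        genes_per_module: int = 40,
        **kwargs,
    ) -> "PlantedDesign":
        """Disjoint equally sized modules tiling the matrix."""
        modules = [
            (
                list(range(k * mirnas_per_module, (k + 1) * mirnas_per_module)),
                list(range(k * genes_per_module, (k + 1) * genes_per_module)),
            )
            for k in range(n_modules)
        ]
        return cls(
            n_mirna=n_modules * mirnas_per_module,
            n_mrna=n_modules * genes_per_module,
            modules=modules,
            **kwargs,
        )


def planted_matrix(
    design: PlantedDesign,
) -> tuple[InteractionMatrix, list[tuple[set[str], set[str]]]]:
    """Generate a planted-module matrix and its ground-truth modules.

    In-module cells are drawn uniformly from ``signal_range``; all other
    cells from ``noise_range`` and then sparsified: background values below
    0.05 are dropped.  When ``overlap_fraction`` is positive, that fraction
    of each module's miRNAs is additionally inserted into the next module
    (cyclically), producing overlapping ground truth.
    """
    rng = np.random.default_rng(design.seed)
    # effective module membership after chained overlap
    eff_modules: list[tuple[set[int], set[int]]] = [
        (set(ms), set(gs)) for ms, gs in design.modules
    ]
    if design.overlap_fraction > 0 and len(eff_modules) > 1:
        n_over = [
            int(np.ceil(design.overlap_fraction * len(ms)))
            for ms, _ in design.modules
        ]
        for k, (ms, _) in enumerate(design.modules):
            nxt = (k + 1) % len(eff_modules)
            eff_modules[nxt][0].update(sorted(ms)[: n_over[k]])

    values = rng.uniform(
        design.noise_range[0],
        design.noise_range[1],
        size=(design.n_mirna, design.n_mrna),
    )
    values[values < SPARSIFY_THRESHOLD] = 0.0
    for ms, gs in eff_modules:
        block = rng.uniform(
            design.signal_range[0],
            design.signal_range[1],
            size=(len(ms), len(gs)),
        )
        values[np.ix_(sorted(ms), sorted(gs))] = block

    mirnas = tuple(_mirna_name(i) for i in range(design.n_mirna))
    genes = tuple(_gene_name(j) for j in range(design.n_mrna))
    # names are zero-padded, so index order is already lexicographic
    A = InteractionMatrix(mirnas, genes, values)
    truth = [
        (
            {_mirna_name(i) for i in ms},
            {_gene_name(j) for j in gs},
        )
        for ms, gs in eff_modules
    ]
    return A, truth


def pu_scores(
    n: int,
    d: int = 2,
    prior: float = 0.5,
    label_frequency_c: float = 0.5,
    separation: float = 0.6,
    seed: int = 0,
    feature_width: float = 0.4,
) -> tuple[PUDataset, np.ndarray]:
    """SCAR positive-unlabeled score vectors with hidden ground truth.

    True class is Bernoulli(*prior*).  Non-interactions draw each of the
    *d* scores from U(0, feature_width); true interactions from
    U(separation, separation + feature_width), clipped to [0, 1].  True
    positives are labeled independently with probability
    *label_frequency_c*; everything else is unlabeled.  Returns the PU
    dataset and the hidden truth vector (for evaluation only).
    """
    if not (0.0 < prior < 1.0):
        raise ValueError("prior must lie in (0, 1)")
    if not (0.0 < label_frequency_c <= 1.0):
        raise ValueError("label_frequency_c must lie in (0, 1]")
    if separation < 0.0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    truth = rng.random(n) < prior
    X = rng.uniform(0.0, feature_width, size=(n, d))
    X[truth] += separation
    np.clip(X, 0.0, 1.0, out=X)
    labeled = truth & (rng.random(n) < label_frequency_c)
    pair_ids = tuple((f"hsa-mir-{i:06d}", f"GENE{i:06d}") for i in range(n))
    return PUDataset(features=X, labels=labeled, pair_ids=pair_ids), truth


def toy_ontology(
    n_terms: int,
    depth: int,
    n_genes: int,
    coherent_groups: list[set[str] | list[int]] | None = None,
    seed: int = 0,
    namespace: str = "biological_process",
    terms_per_gene: int = 3,
) -> tuple[OntologyGraph, dict[str, set[str]]]:
    """Random tree ontology plus per-gene annotations.

    The first *depth* terms form a root-to-leaf chain fixing the maximum
    depth; remaining terms attach to random existing terms of non-maximal
    depth.  Genes get *terms_per_gene* random direct terms; genes of a
    coherent group additionally share a dedicated term at maximal depth
    that no other gene carries, so the group is functionally coherent with
    high information content.  Groups may be given as gene-name sets or
    gene-index lists.
    """
    if n_terms < depth or depth < 1:
        raise ValueError("need n_terms >= depth >= 1")
    rng = np.random.default_rng(seed)
    term_name = lambda k: f"GO:{k:07d}"  # noqa: E731
    parents: dict[str, set[str]] = {term_name(0): set()}
    term_depth = {term_name(0): 0}
    for k in range(1, depth):
        parents[term_name(k)] = {term_name(k - 1)}
        term_depth[term_name(k)] = k
    for k in range(depth, n_terms):
        shallow = [t for t, dp in term_depth.items() if dp < depth - 1]
        parent = shallow[int(rng.integers(len(shallow)))]
        parents[term_name(k)] = {parent}
        term_depth[term_name(k)] = term_depth[parent] + 1

    genes = [_gene_name(j) for j in range(n_genes)]
    terms = sorted(parents)
    direct: dict[str, set[str]] = {
        g: {
            str(t)
            for t in rng.choice(
                terms, size=min(terms_per_gene, len(terms)), replace=False
            )
        }
        for g in genes
    }

    deepest_chain = term_name(depth - 1)
    next_id = n_terms
    for group in coherent_groups or []:
        members = {
            m if isinstance(m, str) else _gene_name(m) for m in group
        }
        dedicated = term_name(next_id)
        next_id += 1
        parents[dedicated] = {deepest_chain}
        term_depth[dedicated] = depth
        for g in members:
            direct.setdefault(g, set()).add(dedicated)

    graph = OntologyGraph(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace={t: _ns_code(namespace) for t in parents},
    )
    return graph, direct


def _ns_code(namespace: str) -> str:
    codes = {
        "biological_process": "BP",
        "molecular_function": "MF",
        "cellular_component": "CC",
    }
    return codes.get(namespace, namespace)


def write_obo(graph: OntologyGraph, path) -> None:
    """Write an ontology in OBO 1.2 stanza format (for the readers/CLI)."""
    ns_names = {"BP": "biological_process", "MF": "molecular_function",
                "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n\n")
        for term in sorted(graph.parents):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: term {term}\n")
            ns = graph.namespace.get(term, "BP")
            fh.write(f"namespace: {ns_names.get(ns, ns)}\n")
            for parent in sorted(graph.parents[term]):
                fh.write(f"is_a: {parent} ! term {parent}\n")
            fh.write("\n")


def write_gaf(direct: dict[str, set[str]], path, namespace: str = "P") -> None:
    """Write annotations in GAF 2.2 format (for the readers/CLI)."""
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                cols = [
                    "SYNTH", gene, gene, "enables", term, "SYNTH:0000",
                    "IEA", "", namespace, "", "", "protein", "taxon:9606",
                    "20240101", "SYNTH",
                ]
                fh.write("\t".join(cols) + "\n")
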