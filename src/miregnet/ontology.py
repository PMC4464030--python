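"""Gene Ontology input: OBO graphs, GAF annotations, information content.

Terms are organized in a DAG per namespace (Biological Process, Molecular
Function, Cellular Component); ``is_a`` and ``part_of`` are both treated as
subsumption edges.  A gene's annotation set ``GO(x)`` is its directly
annotated terms plus, by default, their ancestor closure.  The information
content of a term is

    IC(t) = -log p(t)

where ``p(t)`` is the fraction of annotated genes whose (closed) annotation
set contains ``t``; the logarithm base is configurable and defaults to the
natural log.  Parents are annotated at least as often as their children, so
IC never increases along child-to-parent edges -- asserted after scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

SUBSUMPTION_RELATIONS = ("is_a", "part_of")

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass
class OntologyGraph:
    """Acyclic term graph with is_a/part_of parent links and namespaces."""

    parents: dict[str, frozenset[str]]
    namespace: dict[str, str]            # term -> BP | MF | CC

    @property
    def terms(self) -> set[str]:
        return set(self.parents)

    def ancestors(self, term: str) -> set[str]:
        """All (transitive) is_a/part_of ancestors of *term* (exclusive)."""
        out: set[str] = set()
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in out:
                out.add(t)
                stack.extend(self.parents.get(t, ()))
        return out


def read_obo(path: str | Path) -> OntologyGraph:
    """Load an OBO 1.2 ontology, keeping is_a and part_of edges.

    Obsolete terms are skipped.  A cycle or a parent reference to an
    undefined term raises ``ValueError``.
    """
    g = obonet.read_obo(path)
    defined = {n for n, d in g.nodes(data=True) if d.get("name") or d.get("namespace")}
    parents: dict[str, set[str]] = {t: set() for t in defined}
    edges = []
    for child, parent, rel in g.edges(keys=True):
        if rel not in SUBSUMPTION_RELATIONS:
            continue
        if parent not in defined or child not in defined:
            raise ValueError(f"dangling parent reference: {child} -> {parent}")
        parents[child].add(parent)
        edges.append((child, parent))
    dag = nx.DiGraph(edges)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    namespace = {}
    for t in defined:
        ns = g.nodes[t].get("namespace", "biological_process")
        namespace[t] = _NAMESPACE_CODES.get(ns, ns)
    return OntologyGraph(
        parents={t: frozenset(ps) for t, ps in parents.items()},
        namespace=namespace,
    )


def read_gaf(
    path: str | Path, graph: OntologyGraph
) -> tuple[dict[str, set[str]], int]:
    """Read GAF 2.x annotations as gene symbol -> direct term sets.

    NOT-qualified rows are dropped; rows naming terms absent from *graph*
    are dropped and counted (second return value).  Gene symbols are
    uppercased so they match case-normalized interaction tables.
    """
    direct: dict[str, set[str]] = {}
    unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise ValueError(
                    f"malformed GAF line {lineno}: expected >=15 columns, got {len(cols)}"
                )
            symbol, qualifier, term = cols[2], cols[3], cols[4]
            if not symbol or not term:
                raise ValueError(f"malformed GAF line {lineno}: empty symbol or term")
            if "NOT" in qualifier.split("|"):
                continue
            if term not in graph.terms:
                unknown += 1
                continue
            direct.setdefault(symbol.upper(), set()).add(term)
    if unknown:
        logger.warning("%d GAF rows referenced terms absent from the ontology", unknown)
    return direct, unknown


@dataclass
class AnnotationStore:
    """Per-gene (closed) annotation sets and per-term information content."""

    namespace: str
    direct: dict[str, frozenset[str]]
    closed: dict[str, frozenset[str]]
    ic: dict[str, float]
    n_genes: int = 0

    def terms_of(self, gene: str) -> frozenset[str] | None:
        return self.closed.get(gene)


def close_and_score(
    direct: Mapping[str, set[str]],
    graph: OntologyGraph,
    namespace: str,
    log_base: float = math.e,
    use_closure: bool = True,
) -> AnnotationStore:
    """Ancestor-close annotations within a namespace and compute IC tables.

    ``p(t)`` is the fraction of namespace-annotated genes carrying ``t`` in
    their closed set; ``ic(t) = -log p(t)``.  Terms annotated to no gene do
    not appear in the IC table.
    """
    in_ns = {t for t in graph.terms if graph.namespace.get(t) == namespace}
    closed: dict[str, frozenset[str]] = {}
    direct_ns: dict[str, frozenset[str]] = {}
    for gene, terms in direct.items():
        terms_ns = set(terms) & in_ns
        if not terms_ns:
            continue
        direct_ns[gene] = frozenset(terms_ns)
        if use_closure:
            full = set(terms_ns)
            for t in terms_ns:
                full |= graph.ancestors(t) & in_ns
            closed[gene] = frozenset(full)
        else:
            closed[gene] = frozenset(terms_ns)
    if not closed:
        raise ValueError(f"no annotations in namespace {namespace}")
    n_genes = len(closed)
    counts: dict[str, int] = {}
    for terms in closed.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    log = math.log if log_base == math.e else (lambda x: math.log(x, log_base))
    ic = {t: -log(c / n_genes) for t, c in counts.items()}
    store = AnnotationStore(
        namespace=namespace,
        direct=direct_ns,
        closed=closed,
        ic=ic,
        n_genes=n_genes,
    )
    if use_closure:
        # without closure a parent can legitimately be rarer than a child
        _check_ic_monotone(store, graph)
    return store


def _check_ic_monotone(store: AnnotationStore, graph: OntologyGraph) -> None:
    """ic(parent) <= ic(child) for every subsumption edge with both scored."""
    for child, ps in graph.parents.items():
        if child not in store.ic:
            continue
        for parent in ps:
            if parent in store.ic and store.ic[parent] > store.ic[child] + 1e-12:
                raise AssertionError(
                    f"IC not monotone on edge {child} -> {parent}"
                )
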