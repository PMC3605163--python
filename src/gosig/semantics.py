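"""Semantic clustering of significant GO terms.

The information content (IC) of a term is -log of the fraction of corpus
annotations subsumed by the term (the term plus all its DAG descendants)
relative to the annotations subsumed by its domain root; a rarely used
term is highly informative.  Resnik similarity of two terms is the IC of
their most-informative common ancestor, preserving how specific their
relationship is.  Pairwise similarities over the significant term list
are normalized to the maximum observed value, turned into distances
(1 - similarity) and clustered agglomeratively; flat clusters are cut at
distance 1 - semantic_threshold (default threshold 0.8).  The clusters
are finally painted onto the minimal subgraph — the significant terms
plus all their ancestors — emitted as DOT text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ContractError, IntegrityError
from .io import GODag

logger = logging.getLogger(__name__)

#: fixed 12-color palette; cluster index -> color, deterministic.
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)


@dataclass
class ICMap:
    """Term -> information content (nats); the domain root has IC 0."""

    values: dict[str, float]
    domain: str

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def __getitem__(self, term: str) -> float:
        return self.values[term]


@dataclass
class SimilarityMatrix:
    """Symmetric normalized Resnik similarity over an ordered term list."""

    terms: list[str]
    values: np.ndarray  # square, symmetric, in [0, 1] when normalized
    normalized: bool


@dataclass
class ClusterAssignment:
    """Flat cluster labels (contiguous positive integers) per term."""

    labels: dict[str, int]
    threshold_used: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


def compute_ic(
    dag: GODag, corpus: Mapping[str, int], domain: str
) -> ICMap:
    """Information content of every term in a domain from direct annotation
    counts.

    ``corpus`` maps term -> number of direct annotations; the count a term
    subsumes is the sum over itself and all its descendants.  Terms
    subsuming zero annotations have undefined IC and are excluded (with a
    warning); they are later left out of similarity computations.
    """
    root = dag.roots.get(domain)
    if root is None:
        raise ContractError(f"no root for domain {domain}")
    terms = dag.domain_terms(domain)
    subsumed: dict[str, int] = {}
    for t in terms:
        members = {t} | {d for d in dag.descendants(t) if dag.domain(d) == domain}
        subsumed[t] = sum(corpus.get(m, 0) for m in members)
    total = subsumed[root]
    if total <= 0:
        raise ContractError(f"domain root {root} subsumes no annotations")
    values: dict[str, float] = {}
    undefined = []
    for t in terms:
        if subsumed[t] <= 0:
            undefined.append(t)
            continue
        v = -math.log(subsumed[t] / total)
        values[t] = v if v != 0 else 0.0
    if undefined:
        logger.warning(
            "%d term(s) subsume no annotations; IC undefined, excluded: %s",
            len(undefined), sorted(undefined)[:10],
        )
    return ICMap(values=values, domain=domain)


def resnik(dag: GODag, ic: ICMap, t1: str, t2: str) -> float:
    """IC of the most-informative common ancestor of two terms.

    A term is its own ancestor here, so ``resnik(t, t) == IC(t)``; within
    one domain the root is always shared, so siblings with no other shared
    ancestry score 0.
    """
    for t in (t1, t2):
        if t not in ic:
            raise ContractError(f"term {t} has no defined IC")
    common = ({t1} | dag.ancestors(t1)) & ({t2} | dag.ancestors(t2))
    common = {c for c in common if c in ic}
    if not common:
        raise IntegrityError(f"terms {t1}, {t2} share no ancestor with defined IC")
    return max(ic[c] for c in common)


def build_similarity_matrix(
    dag: GODag, ic: ICMap, terms: Sequence[str]
) -> SimilarityMatrix:
    """Pairwise Resnik matrix over a term list, normalized to its maximum.

    Diagonal (self-similarity) entries participate in the normalization.
    Terms without defined IC are excluded with a warning; fewer than two
    usable terms is an error.  An all-zero raw matrix cannot be normalized
    and is returned unchanged with a warning.
    """
    usable = [t for t in terms if t in ic]
    skipped = [t for t in terms if t not in ic]
    if skipped:
        logger.warning("excluded %d term(s) without IC from similarity: %s",
                       len(skipped), skipped[:10])
    if len(usable) < 2:
        raise ContractError("need at least 2 terms with defined IC")
    k = len(usable)
    raw = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            raw[i, j] = raw[j, i] = resnik(dag, ic, usable[i], usable[j])
    m = raw.max()
    if m == 0.0:
        logger.warning("all-zero similarity matrix; returned unnormalized")
        return SimilarityMatrix(terms=list(usable), values=raw, normalized=False)
    return SimilarityMatrix(terms=list(usable), values=raw / m, normalized=True)


def cluster_terms(
    sim: SimilarityMatrix,
    semantic_threshold: float = 0.8,
    linkage: str = "average",
) -> ClusterAssignment:
    """Agglomerative clustering of terms at distance 1 - similarity.

    Flat clusters are cut at cophenetic distance 1 - semantic_threshold;
    a threshold of 0 therefore yields one cluster holding every term.
    Labels are relabeled to contiguous positive integers in order of first
    appearance along the input term order.
    """
    if linkage not in ("single", "complete", "average"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    flat = hierarchy.fcluster(Z, t=1.0 - semantic_threshold, criterion="distance")
    relabel: dict[int, int] = {}
    labels: dict[str, int] = {}
    for term, raw in zip(sim.terms, flat):
        if raw not in relabel:
            relabel[raw] = len(relabel) + 1
        labels[term] = relabel[raw]
    return ClusterAssignment(labels=labels, threshold_used=semantic_threshold)


def minimal_subgraph(
    dag: GODag, terms: Iterable[str]
) -> tuple[set[str], set[tuple[str, str]]]:
    """Minimal DAG subgraph over a term list: the terms, all their
    ancestors up to the root, and the induced is_a edges
    (parent -> child direction, for display)."""
    nodes: set[str] = set()
    for t in terms:
        if t not in dag:
            logger.warning("term %s not in DAG; dropped from subgraph", t)
            continue
        nodes.add(t)
        nodes |= dag.ancestors(t)
    edges = {
        (parent, child)
        for child in nodes
        for parent in dag.parents(child)
        if parent in nodes
    }
    return nodes, edges


def emit_dot(
    nodes: set[str],
    edges: set[tuple[str, str]],
    clusters: ClusterAssignment,
    dag: GODag | None = None,
    graph_name: str = "go_subgraph",
) -> str:
    """Render the minimal subgraph as DOT text.

    Significant terms (those with a cluster label) are filled with a
    per-cluster color from the fixed palette; ancestor-only nodes stay
    uncolored.  Output is deterministic: nodes and edges are sorted.
    """
    lines = [f"digraph {graph_name} {{", '  node [shape=box, style=""];']
    for node in sorted(nodes):
        label = node
        if dag is not None and node in dag:
            label = f"{node}\\n{dag.name(node)}"
        if node in clusters.labels:
            color = PALETTE[(clusters.labels[node] - 1) % len(PALETTE)]
            lines.append(
                f'  "{node}" [label="{label}", style=filled, fillcolor="{color}"];'
            )
        else:
            lines.append(f'  "{node}" [label="{label}"];')
    for parent, child in sorted(edges):
        lines.append(f'  "{parent}" -> "{child}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
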