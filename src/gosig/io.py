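"""Reading and validating external inputs.

Inputs are delimiter-separated-values (DSV) files — tab-separated by
default, with a header row — plus a Gene Ontology graph in OBO format or
as a plain edge list.  Everything is parsed into small frozen domain
objects (:class:`ExpressionMatrix`, :class:`LabelVector`,
:class:`AnnotationTable`, :class:`GeneNameTable`, :class:`GODag`) that the
rest of the pipeline consumes.  Parsing is strict and deterministic: no
dialect sniffing, duplicate identifiers are hard errors, and the GO graph
is checked for acyclicity on every load.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

from .errors import IntegrityError, ParseError, SchemaError

logger = logging.getLogger(__name__)

#: GO domain codes used throughout the package.
DOMAINS = ("MF", "BP", "CC")

#: OBO namespace -> domain code.
_NAMESPACE_TO_DOMAIN = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}


@dataclass(frozen=True)
class DsvDialect:
    """Fixed DSV dialect: delimiter and whether a header row is present."""

    delimiter: str = "\t"
    header: bool = True


@dataclass
class ExpressionMatrix:
    """A P-probeset x N-sample matrix of post-normalization expression values.

    Parameters
    ----------
    probeset_ids
        Ordered, unique probeset identifiers (length P).
    sample_ids
        Ordered, unique sample identifiers (length N).
    values
        Real-valued P x N array; row *i* holds the measurements of
        ``probeset_ids[i]`` across all samples in column order.
    """

    probeset_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = len(self.probeset_ids), len(self.sample_ids)
        if self.values.shape != (p, n):
            raise IntegrityError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{p} probesets x {n} samples"
            )
        if p < 1 or n < 2:
            raise IntegrityError("expression matrix needs P >= 1 and N >= 2")
        if len(set(self.probeset_ids)) != p:
            raise IntegrityError("duplicate probeset identifiers")
        if len(set(self.sample_ids)) != n:
            raise IntegrityError("duplicate sample identifiers")
        if np.isnan(self.values).all(axis=1).any():
            raise IntegrityError("a probeset row is entirely missing")

    @property
    def n_probesets(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probeset_id: str) -> np.ndarray:
        return self.values[self.probeset_ids.index(probeset_id)]


@dataclass
class LabelVector:
    """Two-class labels, one per sample, coded -1 / +1."""

    assignments: dict[str, int]

    def __post_init__(self) -> None:
        classes = set(self.assignments.values())
        if classes != {-1, 1}:
            raise IntegrityError(
                f"labels must contain exactly the classes -1 and +1, got {sorted(classes)}"
            )

    def vector(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Label vector aligned to ``sample_ids`` order."""
        try:
            return np.array([self.assignments[s] for s in sample_ids], dtype=float)
        except KeyError as exc:  # pragma: no cover - defensive
            raise IntegrityError(f"sample {exc.args[0]!r} has no label") from exc

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive)."""
        vals = list(self.assignments.values())
        return vals.count(-1), vals.count(1)


@dataclass(frozen=True)
class AnnotationRecord:
    probeset_id: str
    gene_symbol: str
    go_term_ids: frozenset[str]
    entrez_id: str | None = None
    genbank_id: str | None = None


@dataclass
class AnnotationTable:
    """Platform annotations: probeset -> gene symbol, GO terms, external IDs."""

    records: list[AnnotationRecord]

    def __post_init__(self) -> None:
        ids = [r.probeset_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate probeset rows in annotation table: {dupes}")

    def by_probeset(self) -> dict[str, AnnotationRecord]:
        return {r.probeset_id: r for r in self.records}


@dataclass(frozen=True)
class GeneNameRecord:
    approved_symbol: str
    previous_symbols: frozenset[str]
    aliases: frozenset[str]
    status: str = "Approved"


@dataclass
class GeneNameTable:
    """HGNC-style gene-naming table (approved symbol, previous symbols, aliases)."""

    records: list[GeneNameRecord]

    def __post_init__(self) -> None:
        active = [r.approved_symbol for r in self.records if r.status.lower() != "withdrawn"]
        if len(set(active)) != len(active):
            raise IntegrityError("approved symbols not unique among non-withdrawn records")


class GODag:
    """The Gene Ontology is_a DAG: terms with names and domains, child->parent
    edges, and one root per domain.

    Internally a :class:`networkx.DiGraph` with edges directed child -> parent,
    so `descendants` in graph terms are ontology *ancestors*.
    """

    def __init__(
        self,
        terms: Mapping[str, tuple[str, str]],
        edges: Iterable[tuple[str, str]],
    ) -> None:
        self.terms: dict[str, tuple[str, str]] = dict(terms)
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise IntegrityError(f"edge references unknown term: {child} -> {parent}")
            if self.domain(child) != self.domain(parent):
                raise IntegrityError(
                    f"is_a edge crosses domains: {child} ({self.domain(child)}) -> "
                    f"{parent} ({self.domain(parent)})"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise IntegrityError(f"GO graph contains a cycle: {cycle}")
        self.graph = g
        self.roots: dict[str, str] = {}
        for term in self.terms:
            if g.out_degree(term) == 0:
                dom = self.domain(term)
                if dom in self.roots:
                    raise IntegrityError(
                        f"domain {dom} has multiple roots: {self.roots[dom]}, {term}"
                    )
                self.roots[dom] = term

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name(self, term_id: str) -> str:
        return self.terms[term_id][0]

    def domain(self, term_id: str) -> str:
        return self.terms[term_id][1]

    def domain_terms(self, domain: str) -> set[str]:
        return {t for t, (_, d) in self.terms.items() if d == domain}

    def parents(self, term_id: str) -> set[str]:
        return set(self.graph.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        return set(self.graph.predecessors(term_id))

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable by following is_a upward (excludes the term)."""
        return set(nx.descendants(self.graph, term_id))

    def descendants(self, term_id: str) -> set[str]:
        """All terms that subsume into this one (excludes the term)."""
        return set(nx.ancestors(self.graph, term_id))


# ---------------------------------------------------------------------------
# readers


def _read_dsv_rows(path: str, dialect: DsvDialect) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header, [(line_number, cells), ...]); ragged rows are the caller's problem."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        rows = [(i + 1, row) for i, row in enumerate(reader) if row]
    if not rows:
        raise ParseError(f"{path}: empty file")
    if dialect.header:
        header = rows[0][1]
        return header, rows[1:]
    return [], rows


def read_gedm(path: str, dialect: DsvDialect = DsvDialect()) -> ExpressionMatrix:
    """Read a gene expression data matrix from a DSV file.

    The file has a header row (first cell ignored or naming the ID column,
    remaining cells are sample IDs) and P probeset rows of N numeric values.
    """
    header, rows = _read_dsv_rows(path, dialect)
    if len(header) < 3:
        raise SchemaError(f"{path}: expected >= 2 sample columns, got {len(header) - 1}")
    sample_ids = header[1:]
    width = len(header)
    probeset_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(rows), width - 1), dtype=float)
    for out_i, (lineno, row) in enumerate(rows):
        if len(row) != width:
            raise ParseError(
                f"{path}: line {lineno}: ragged row ({len(row)} cells, expected {width})"
            )
        pid = row[0]
        if pid in seen:
            raise IntegrityError(f"{path}: line {lineno}: duplicate probeset ID {pid!r}")
        seen.add(pid)
        probeset_ids.append(pid)
        for j, cell in enumerate(row[1:]):
            try:
                values[out_i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}, column {j + 2}: non-numeric cell {cell!r}"
                ) from None
    return ExpressionMatrix(probeset_ids, sample_ids, values)


def read_labels(
    path: str,
    class_map: Mapping[str, int],
    dialect: DsvDialect = DsvDialect(),
) -> LabelVector:
    """Read sample labels and map raw class names to -1/+1.

    ``class_map`` is an explicit configuration requirement: raw labels are
    never ordered or inferred.
    """
    if set(class_map.values()) != {-1, 1}:
        raise SchemaError("class_map must map the two raw labels onto -1 and +1")
    _, rows = _read_dsv_rows(path, dialect)
    assignments: dict[str, int] = {}
    raw_seen: set[str] = set()
    for lineno, row in rows:
        if len(row) < 2:
            raise ParseError(f"{path}: line {lineno}: expected sample and label")
        sample, raw = row[0], row[1]
        if sample in assignments:
            raise IntegrityError(f"{path}: line {lineno}: duplicate sample {sample!r}")
        raw_seen.add(raw)
        if raw not in class_map:
            raise IntegrityError(
                f"{path}: line {lineno}: label {raw!r} not covered by class_map"
            )
        assignments[sample] = class_map[raw]
    if len(raw_seen) != 2:
        raise IntegrityError(
            f"{path}: expected exactly 2 raw classes, found {sorted(raw_seen)}"
        )
    counts = [list(assignments.values()).count(c) for c in (-1, 1)]
    if min(counts) < 2:
        raise IntegrityError(f"{path}: each class needs >= 2 samples, got {counts}")
    return LabelVector(assignments)


@dataclass(frozen=True)
class AnnotationColumns:
    """Column names and multi-value separator for a platform annotation DSV."""

    probeset: str = "probeset_id"
    symbol: str = "gene_symbol"
    go_terms: str = "go_terms"
    entrez: str | None = "entrez_id"
    genbank: str | None = "genbank_id"
    go_separator: str = ";"


def read_annotations(
    path: str,
    columns: AnnotationColumns = AnnotationColumns(),
    dialect: DsvDialect = DsvDialect(),
) -> AnnotationTable:
    """Read a GEO-GPL-style platform annotation table."""
    header, rows = _read_dsv_rows(path, dialect)
    idx = {name: i for i, name in enumerate(header)}
    for mandatory in (columns.probeset, columns.symbol, columns.go_terms):
        if mandatory not in idx:
            raise SchemaError(f"{path}: missing mandatory column {mandatory!r}")

    def cell(row: list[str], col: str | None) -> str | None:
        if col is None or col not in idx or idx[col] >= len(row):
            return None
        return row[idx[col]].strip() or None

    records = []
    for _lineno, row in rows:
        go_cell = cell(row, columns.go_terms) or ""
        go_ids = frozenset(t.strip() for t in go_cell.split(columns.go_separator) if t.strip())
        records.append(
            AnnotationRecord(
                probeset_id=cell(row, columns.probeset) or "",
                gene_symbol=cell(row, columns.symbol) or "",
                go_term_ids=go_ids,
                entrez_id=cell(row, columns.entrez),
                genbank_id=cell(row, columns.genbank),
            )
        )
    if any(not r.probeset_id for r in records):
        raise IntegrityError(f"{path}: empty probeset ID")
    return AnnotationTable(records)


def read_gene_names(
    path: str,
    dialect: DsvDialect = DsvDialect(),
    multi_separator: str = "|",
) -> GeneNameTable:
    """Read an HGNC-style gene-naming table.

    Expected columns: approved_symbol, previous_symbols, aliases, status;
    multi-valued cells are split on ``multi_separator``.
    """
    header, rows = _read_dsv_rows(path, dialect)
    idx = {name: i for i, name in enumerate(header)}
    if "approved_symbol" not in idx:
        raise SchemaError(f"{path}: missing mandatory column 'approved_symbol'")

    def multi(row: list[str], col: str) -> frozenset[str]:
        if col not in idx or idx[col] >= len(row):
            return frozenset()
        return frozenset(s.strip() for s in row[idx[col]].split(multi_separator) if s.strip())

    records = []
    for _lineno, row in rows:
        status = row[idx["status"]] if "status" in idx and idx["status"] < len(row) else "Approved"
        records.append(
            GeneNameRecord(
                approved_symbol=row[idx["approved_symbol"]].strip(),
                previous_symbols=multi(row, "previous_symbols"),
                aliases=multi(row, "aliases"),
                status=status or "Approved",
            )
        )
    return GeneNameTable(records)


def read_go_graph(
    path: str,
    format: str = "obo",
    include_part_of: bool = False,
) -> GODag:
    """Read the GO DAG from an OBO file or a plain edge list.

    The edge-list format is a 3-column DSV (term_id, parent_id, domain) with
    an empty parent for the per-domain roots; term names default to the IDs.
    Only is_a edges are used unless ``include_part_of`` is set (OBO only).
    """
    if format == "obo":
        relations = {"is_a"} | ({"part_of"} if include_part_of else set())
        g = obonet.read_obo(path)
        terms: dict[str, tuple[str, str]] = {}
        for node, data in g.nodes(data=True):
            ns = data.get("namespace")
            if ns not in _NAMESPACE_TO_DOMAIN:
                raise IntegrityError(f"term {node} has unknown domain namespace {ns!r}")
            terms[node] = (data.get("name", node), _NAMESPACE_TO_DOMAIN[ns])
        edges = [
            (child, parent)
            for child, parent, rel in g.edges(keys=True)
            if rel in relations and parent in terms
        ]
        return GODag(terms, edges)
    if format == "edge-list":
        _, rows = _read_dsv_rows(path, DsvDialect())
        terms = {}
        raw_edges: list[tuple[str, str]] = []
        for lineno, row in rows:
            if len(row) < 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            term, parent, domain = row[0].strip(), row[1].strip(), row[2].strip()
            if domain not in DOMAINS:
                raise IntegrityError(f"{path}: line {lineno}: unknown domain {domain!r}")
            terms[term] = (term, domain)
            if parent:
                raw_edges.append((term, parent))
        for child, parent in raw_edges:
            if parent not in terms:
                terms[parent] = (parent, terms[child][1])
        return GODag(terms, raw_edges)
    raise ValueError(f"unknown GO graph format {format!r}")
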