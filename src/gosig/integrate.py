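"""Local data integration: the derived mappings.

Two derived tables are built from the raw inputs before any learning
happens: ``term2probeset``, the bidirectional GO term <-> probeset map that
drives subsetting, and ``probeset2gene``, the gene-naming map in which
every platform symbol is verified against the HGNC table (platform
annotations go stale; obsolete symbols are resolved through previous
symbols and aliases rather than trusted as-is).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .io import AnnotationTable, GODag, GeneNameTable

logger = logging.getLogger(__name__)


@dataclass
class TermProbesetMap:
    """Bidirectional GO term <-> probeset mapping for one GO domain.

    ``term_to_probesets`` and ``probeset_to_terms`` are exact inverses of
    each other by construction.
    """

    term_to_probesets: dict[str, frozenset[str]]
    probeset_to_terms: dict[str, frozenset[str]]
    domain: str

    def pairs(self) -> list[tuple[str, str]]:
        """Sorted (term, probeset) pairs, the persistence layout."""
        return sorted(
            (t, p) for t, ps in self.term_to_probesets.items() for p in ps
        )


class ResolutionStatus(str, Enum):
    APPROVED = "approved"
    PREVIOUS = "previous-resolved"
    ALIAS = "alias-resolved"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class GeneResolution:
    resolved_symbol: str
    status: ResolutionStatus
    entrez_id: str | None = None
    genbank_id: str | None = None


@dataclass
class ProbesetGeneMap:
    """probeset -> HGNC-verified gene symbol with resolution provenance."""

    resolutions: dict[str, GeneResolution]

    def rows(self) -> list[tuple[str, str, str, str | None, str | None]]:
        return [
            (p, r.resolved_symbol, r.status.value, r.entrez_id, r.genbank_id)
            for p, r in sorted(self.resolutions.items())
        ]


def invert_mapping(mapping: dict[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    """Invert a set-valued mapping; inverse of the inverse is the identity."""
    out: dict[str, set[str]] = {}
    for key, values in mapping.items():
        for v in values:
            out.setdefault(v, set()).add(key)
    return {k: frozenset(v) for k, v in out.items()}


def build_term_to_probeset(
    anno: AnnotationTable,
    dag: GODag,
    domain: str,
    expression_probesets: Iterable[str],
    propagate: bool = False,
) -> TermProbesetMap:
    """Build the bidirectional term <-> probeset map for one GO domain.

    Only annotations whose term exists in the DAG and belongs to ``domain``
    are kept (unknown terms are logged and dropped), and only probesets
    present in the expression matrix survive.  With ``propagate`` each
    annotation is additionally attached to every DAG ancestor of its term
    within the domain (the GO true-path rule); the default maps probesets
    exactly as the platform annotation states.  Terms left with zero
    probesets are dropped — they would yield empty subsets.
    """
    present = set(expression_probesets)
    term_to: dict[str, set[str]] = {}
    dropped_terms: set[str] = set()
    for rec in anno.records:
        if rec.probeset_id not in present:
            continue
        for term in rec.go_term_ids:
            if term not in dag:
                dropped_terms.add(term)
                continue
            if dag.domain(term) != domain:
                continue
            targets = {term}
            if propagate:
                targets |= {a for a in dag.ancestors(term) if dag.domain(a) == domain}
            for t in targets:
                term_to.setdefault(t, set()).add(rec.probeset_id)
    if dropped_terms:
        logger.warning(
            "dropped %d annotation term(s) absent from the GO DAG: %s",
            len(dropped_terms), sorted(dropped_terms)[:10],
        )
    frozen = {t: frozenset(ps) for t, ps in term_to.items() if ps}
    return TermProbesetMap(
        term_to_probesets=frozen,
        probeset_to_terms=invert_mapping(frozen),
        domain=domain,
    )


def build_probeset_to_gene(anno: AnnotationTable, hgnc: GeneNameTable) -> ProbesetGeneMap:
    """Verify each platform gene symbol against the HGNC table.

    Resolution order: exact approved symbol, then previous symbols, then
    aliases; a symbol matching the previous symbols or aliases of two or
    more approved records is ambiguous and stays unresolved (with a
    warning), keeping the platform symbol.  The outcome is independent of
    table row order.
    """
    active = [r for r in hgnc.records if r.status.lower() != "withdrawn"]
    approved = {r.approved_symbol for r in active}
    previous: dict[str, set[str]] = {}
    aliases: dict[str, set[str]] = {}
    for r in active:
        for s in r.previous_symbols:
            previous.setdefault(s, set()).add(r.approved_symbol)
        for s in r.aliases:
            aliases.setdefault(s, set()).add(r.approved_symbol)

    resolutions: dict[str, GeneResolution] = {}
    for rec in anno.records:
        sym = rec.gene_symbol
        if sym in approved:
            res = GeneResolution(sym, ResolutionStatus.APPROVED, rec.entrez_id, rec.genbank_id)
        elif sym in previous and len(previous[sym]) == 1:
            (target,) = previous[sym]
            res = GeneResolution(target, ResolutionStatus.PREVIOUS, rec.entrez_id, rec.genbank_id)
        elif sym in aliases and len(aliases[sym]) == 1 and sym not in previous:
            (target,) = aliases[sym]
            res = GeneResolution(target, ResolutionStatus.ALIAS, rec.entrez_id, rec.genbank_id)
        else:
            if sym in previous or sym in aliases:
                logger.warning(
                    "symbol %r is ambiguous (maps to multiple approved symbols); "
                    "left unresolved", sym,
                )
            res = GeneResolution(sym, ResolutionStatus.UNRESOLVED, rec.entrez_id, rec.genbank_id)
        resolutions[rec.probeset_id] = res
    return ProbesetGeneMap(resolutions)
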