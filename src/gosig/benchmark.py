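"""Benchmark coverage of pipeline output.

Disease benchmark lists — approved gene symbols and GO terms with their
domains — are compared against the genes and significant terms the
pipeline recovered.  Gene coverage always uses the full benchmark as
denominator; term coverage may restrict the denominator to the GO domain
the run analyzed (a whole-domain run can only ever recover terms of that
domain, so the restricted number is the fair one for this method, while
enrichment-style baselines are scored against all benchmark terms).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable

from .errors import ContractError
from .io import DsvDialect


@dataclass
class BenchmarkLists:
    """Reference gene symbols and (term, domain) pairs for a disease."""

    genes: frozenset[str]
    terms: frozenset[tuple[str, str]]

    @classmethod
    def from_sets(
        cls, genes: Iterable[str], terms: Iterable[tuple[str, str]]
    ) -> "BenchmarkLists":
        return cls(
            genes=frozenset(g.strip().upper() for g in genes if g.strip()),
            terms=frozenset((t.strip(), d.strip()) for t, d in terms),
        )


@dataclass
class CoverageReport:
    n_benchmark: int
    n_covered: int
    coverage: float
    restriction: str  # "all" | "domain-restricted"

    @property
    def percent(self) -> int:
        """Rounded integer percentage, the summary-table style."""
        return round(100.0 * self.coverage)


def read_benchmark_genes(path: str, dialect: DsvDialect = DsvDialect()) -> frozenset[str]:
    """One symbol per row (header optional via dialect); uppercased."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=dialect.delimiter) if r]
    if dialect.header:
        rows = rows[1:]
    return frozenset(r[0].strip().upper() for r in rows if r[0].strip())


def read_benchmark_terms(
    path: str, dialect: DsvDialect = DsvDialect()
) -> frozenset[tuple[str, str]]:
    """Rows of (term_id, domain)."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=dialect.delimiter) if r]
    if dialect.header:
        rows = rows[1:]
    return frozenset((r[0].strip(), r[1].strip()) for r in rows if len(r) >= 2)


def coverage_genes(selected_genes: Iterable[str], bench: BenchmarkLists) -> CoverageReport:
    """Fraction of benchmark genes recovered (unique symbols, case-folded)."""
    if not bench.genes:
        raise ContractError("empty benchmark gene list")
    selected = {g.strip().upper() for g in selected_genes}
    covered = selected & bench.genes
    return CoverageReport(
        n_benchmark=len(bench.genes),
        n_covered=len(covered),
        coverage=len(covered) / len(bench.genes),
        restriction="all",
    )


def coverage_terms(
    significant_terms: Iterable[str],
    bench: BenchmarkLists,
    domain: str,
    restrict: bool = True,
) -> CoverageReport:
    """Fraction of benchmark GO terms recovered.

    With ``restrict`` the denominator is limited to benchmark terms of the
    analyzed domain; otherwise all benchmark terms count.
    """
    if not bench.terms:
        raise ContractError("empty benchmark term list")
    denominator = (
        {t for t, d in bench.terms if d == domain} if restrict
        else {t for t, _ in bench.terms}
    )
    if not denominator:
        raise ContractError(f"no benchmark terms in domain {domain}")
    covered = set(significant_terms) & denominator
    return CoverageReport(
        n_benchmark=len(denominator),
        n_covered=len(covered),
        coverage=len(covered) / len(denominator),
        restriction="domain-restricted" if restrict else "all",
    )
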