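"""From learner output to interpretable results.

A GO term is *significant* when its mean outer-CV test error falls
strictly below the error threshold (0.30 in typical use).  Within a
significant l1l2 term, a variable is *properly selected* when its outer
selection frequency, as a fraction of the outer fold count, strictly
exceeds the frequency threshold; for a significant RLS term every
variable is properly selected.  Significant l1l2 terms at each mu are
merged with the single RLS list into *unified term lists* carrying pooled
confusion counts and the Matthews correlation coefficient, and
selected/not-selected histograms summarize variable behavior across all
significant subsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from .errors import ContractError
from .integrate import ProbesetGeneMap, ResolutionStatus
from .io import AnnotationTable
from .learn import RLS_KEY, PerMuResult, SelectionResult
from .subsets import L1L2FS, RLS


@dataclass(frozen=True)
class TermVerdict:
    """Significance call for one (term, mu) pair or one RLS term."""

    term_id: str
    mu_key: str
    significant: bool
    error_estimate: float
    threshold_used: float


@dataclass(frozen=True)
class VariableRecord:
    """A properly selected variable, annotated back to gene level."""

    probeset_id: str
    gene_symbol: str
    resolution_status: str
    entrez_id: str | None = None
    genbank_id: str | None = None
    frequency: int | None = None  # absent for RLS terms


@dataclass
class UnifiedTermRecord:
    """One significant GO term in a unified (l1l2 + RLS) list."""

    term_id: str
    term_name: str
    total_variables: int
    n_properly_selected: int
    error_estimate: float
    confusion_totals: tuple[int, int, int, int]
    mcc: float
    source: str  # mu key ("mu0", ...) or "RLS"


@dataclass
class SelectionHistogram:
    """How often each variable was (or was not) selected across the data
    subsets of significant GO terms."""

    polarity: str  # "selected" | "not-selected"
    counts: list[tuple[str, str, int]]  # (probeset, gene symbol, count)
    total_entries: int
    n_significant_terms: int
    n_domain_terms: int


def call_significance(
    results: Mapping[str, SelectionResult], error_threshold: float
) -> dict[tuple[str, str], TermVerdict]:
    """Apply the strict error threshold to every (term, mu) and RLS entry.

    ``error == threshold`` is *not* significant: the rule is strictly
    below.
    """
    if not (0.0 < error_threshold <= 0.5):
        raise ContractError("error threshold must lie in (0, 0.5]")
    verdicts: dict[tuple[str, str], TermVerdict] = {}
    for term_id, res in results.items():
        for mu_key, pm in res.per_mu.items():
            verdicts[(term_id, mu_key)] = TermVerdict(
                term_id=term_id,
                mu_key=mu_key,
                significant=pm.mean_test_error < error_threshold,
                error_estimate=pm.mean_test_error,
                threshold_used=error_threshold,
            )
    return verdicts


def select_variables(
    result: SelectionResult,
    verdict: TermVerdict,
    freq_threshold: float,
) -> list[str]:
    """Properly selected variables of one significant term.

    For l1l2 terms: frequency / outer_K strictly above ``freq_threshold``
    (so a threshold of 1.0 passes nothing).  For RLS terms: all subset
    variables.
    """
    if not verdict.significant:
        raise ContractError(
            f"select_variables called on non-significant term {verdict.term_id}"
        )
    pm = result.per_mu[verdict.mu_key]
    if result.technique == RLS:
        return sorted(pm.frequencies)
    outer_k = len(pm.splits)
    return sorted(
        v for v, f in pm.frequencies.items() if f / outer_k > freq_threshold
    )


def compute_mcc(confusion: tuple[int, int, int, int]) -> float:
    """Matthews correlation coefficient; any zero denominator factor -> 0."""
    tp, tn, fp, fn = confusion
    if tp + tn + fp + fn <= 0:
        raise ContractError("empty confusion")
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def _pooled_confusion(pm: PerMuResult) -> tuple[int, int, int, int]:
    totals = np.sum([s.confusion for s in pm.splits], axis=0)
    return tuple(int(t) for t in totals)


def build_unified_list(
    results: Mapping[str, SelectionResult],
    verdicts: Mapping[tuple[str, str], TermVerdict],
    mu_key: str,
    freq_threshold: float,
    term_names: Mapping[str, str] | None = None,
) -> list[UnifiedTermRecord]:
    """Merge the significant l1l2 terms at one mu with the RLS terms.

    The two sources are disjoint by routing; a term appearing in both is a
    contract violation.  Records are sorted by error estimate ascending,
    ties broken by term id.  The mean outer test error is reused as the
    record's classification error estimate.
    """
    records: list[UnifiedTermRecord] = []
    seen: set[str] = set()
    for (term_id, key), verdict in verdicts.items():
        if not verdict.significant:
            continue
        res = results[term_id]
        if res.technique == L1L2FS and key != mu_key:
            continue
        if res.technique == RLS and key != RLS_KEY:
            continue
        if term_id in seen:
            raise ContractError(f"term {term_id} appears in both l1l2 and RLS sources")
        seen.add(term_id)
        pm = res.per_mu[key]
        conf = _pooled_confusion(pm)
        n_sel = len(select_variables(res, verdict, freq_threshold))
        records.append(
            UnifiedTermRecord(
                term_id=term_id,
                term_name=(term_names or {}).get(term_id, term_id),
                total_variables=res.total_variables,
                n_properly_selected=n_sel,
                error_estimate=verdict.error_estimate,
                confusion_totals=conf,
                mcc=compute_mcc(conf),
                source=key,
            )
        )
    records.sort(key=lambda r: (r.error_estimate, r.term_id))
    return records


def annotate_variables(
    probeset_ids: Sequence[str],
    p2g: ProbesetGeneMap,
    anno: AnnotationTable,
    frequencies: Mapping[str, int] | None = None,
) -> list[VariableRecord]:
    """Annotate probesets back to gene symbols and external IDs.

    Annotations come primarily from the platform table and are verified
    against HGNC via the probeset2gene map; missing external IDs are
    permitted.  Unknown probesets yield unresolved records with a warning.
    """
    by_ps = anno.by_probeset()
    out: list[VariableRecord] = []
    for pid in probeset_ids:
        res = p2g.resolutions.get(pid)
        rec = by_ps.get(pid)
        if res is None:
            import logging

            logging.getLogger(__name__).warning(
                "probeset %s missing from annotation table", pid
            )
            out.append(
                VariableRecord(
                    probeset_id=pid,
                    gene_symbol=pid,
                    resolution_status=ResolutionStatus.UNRESOLVED.value,
                    frequency=(frequencies or {}).get(pid),
                )
            )
            continue
        out.append(
            VariableRecord(
                probeset_id=pid,
                gene_symbol=res.resolved_symbol,
                resolution_status=res.status.value,
                entrez_id=rec.entrez_id if rec else None,
                genbank_id=rec.genbank_id if rec else None,
                frequency=(frequencies or {}).get(pid),
            )
        )
    return out


def build_histograms(
    results: Mapping[str, SelectionResult],
    verdicts: Mapping[tuple[str, str], TermVerdict],
    mu_key: str,
    freq_threshold: float,
    n_domain_terms: int,
    gene_symbols: Mapping[str, str] | None = None,
) -> tuple[SelectionHistogram, SelectionHistogram | None]:
    """Selected / not-selected variable histograms over significant subsets.

    The counting basis is membership in significant subsets only: for each
    variable, selected + not-selected counts equal the number of
    significant subsets containing it.  For the RLS pseudo-mu only the
    selected histogram exists (all variables are properly selected there).
    """
    sel_counts: dict[str, int] = {}
    notsel_counts: dict[str, int] = {}
    n_sig = 0
    for (term_id, key), verdict in verdicts.items():
        if key != mu_key or not verdict.significant:
            continue
        n_sig += 1
        res = results[term_id]
        selected = set(select_variables(res, verdict, freq_threshold))
        for v in res.per_mu[key].frequencies:
            if v in selected:
                sel_counts[v] = sel_counts.get(v, 0) + 1
            else:
                notsel_counts[v] = notsel_counts.get(v, 0) + 1

    def mk(polarity: str, counts: dict[str, int]) -> SelectionHistogram:
        rows = [
            (p, (gene_symbols or {}).get(p, p), c)
            for p, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return SelectionHistogram(
            polarity=polarity,
            counts=rows,
            total_entries=len(rows),
            n_significant_terms=n_sig,
            n_domain_terms=n_domain_terms,
        )

    selected_hist = mk("selected", sel_counts)
    if mu_key == RLS_KEY:
        return selected_hist, None
    return selected_hist, mk("not-selected", notsel_counts)


@dataclass
class ErrorStatistics:
    """Mean/SD/median of outer test error per mu key and overall."""

    per_mu: dict[str, tuple[float, float, float]]  # key -> (mean, sd, median)
    overall: tuple[float, float, float]


def summarize_errors(results: Mapping[str, SelectionResult]) -> ErrorStatistics:
    """Classification-error statistics across all data subsets."""
    if not results:
        raise ContractError("no results to summarize")
    by_key: dict[str, list[float]] = {}
    for res in results.values():
        for key, pm in res.per_mu.items():
            by_key.setdefault(key, []).append(pm.mean_test_error)
    per_mu = {
        key: (float(np.mean(v)), float(np.std(v)), float(median(v)))
        for key, v in sorted(by_key.items())
    }
    everything = [e for v in by_key.values() for e in v]
    overall = (
        float(np.mean(everything)),
        float(np.std(everything)),
        float(median(everything)),
    )
    return ErrorStatistics(per_mu=per_mu, overall=overall)
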