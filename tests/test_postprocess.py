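"""Significance calling, proper selection, unified lists, MCC, histograms."""

import math

import numpy as np
import pytest

from gosig import (
    annotate_variables,
    build_histograms,
    build_unified_list,
    call_significance,
    compute_mcc,
    select_variables,
    summarize_errors,
)
from gosig.errors import ContractError
from gosig.integrate import build_probeset_to_gene
from gosig.io import (
    AnnotationRecord,
    AnnotationTable,
    GeneNameRecord,
    GeneNameTable,
)
from gosig.learn import RLS_KEY, PerMuResult, SelectionResult, SplitResult
from gosig.subsets import L1L2FS, RLS


def _split(i, selected, err, fold=4):
    wrong = round(err * fold)
    return SplitResult(
        split_index=i,
        selected_variables=tuple(selected),
        test_error=wrong / fold,
        train_error=0.0,
        confusion=(fold - wrong, 0, 0, wrong),
    )


def _result(term, technique, variables, split_specs, mu_key="mu0"):
    splits = [_split(i, sel, err) for i, (sel, err) in enumerate(split_specs)]
    pm = PerMuResult.from_splits(None if technique == RLS else 0.1, splits, variables)
    key = RLS_KEY if technique == RLS else mu_key
    return SelectionResult(term, technique, {key: pm}, len(variables))


@pytest.fixture
def mixed_results():
    """Two l1l2 terms (one clearly significant) and one significant RLS term."""
    r_sig = _result(
        "GO:A", L1L2FS, ["p1", "p2", "p3"],
        [(["p1"], 0.0), (["p1", "p2"], 0.25), (["p1"], 0.25), (["p1"], 0.0)],
    )
    r_not = _result(
        "GO:B", L1L2FS, ["p4", "p5"],
        [([], 0.5), (["p4"], 0.5), ([], 0.75), ([], 0.5)],
    )
    r_rls = _result(
        "GO:C", RLS, ["p6", "p7"],
        [(["p6", "p7"], 0.0)] * 4,
    )
    return {"GO:A": r_sig, "GO:B": r_not, "GO:C": r_rls}


class TestSignificance:
    @pytest.mark.parametrize(
        "error,significant",
        [(0.25, True), (0.30, False), (0.55, False), (0.2999, True)],
    )
    def test_strictly_below_threshold(self, error, significant):
        res = _result("GO:X", L1L2FS, ["p1"], [([], error)] * 4)
        # fabricate exact mean by overriding (splits carry rounded errors)
        res.per_mu["mu0"].mean_test_error = error
        verdicts = call_significance({"GO:X": res}, 0.30)
        assert verdicts[("GO:X", "mu0")].significant is significant

    def test_one_verdict_per_term_and_mu(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        assert set(verdicts) == {("GO:A", "mu0"), ("GO:B", "mu0"), ("GO:C", RLS_KEY)}

    def test_threshold_domain_checked(self, mixed_results):
        with pytest.raises(ContractError):
            call_significance(mixed_results, 0.9)


class TestSelectVariables:
    def test_frequency_strictly_above_threshold(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        res = mixed_results["GO:A"]  # freqs p1:4, p2:1, p3:0
        assert select_variables(res, verdicts[("GO:A", "mu0")], 0.5) == ["p1"]

    def test_threshold_one_selects_nothing(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        res = mixed_results["GO:A"]
        assert select_variables(res, verdicts[("GO:A", "mu0")], 1.0) == []

    def test_rls_selects_all_variables(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        res = mixed_results["GO:C"]
        assert select_variables(res, verdicts[("GO:C", RLS_KEY)], 0.5) == ["p6", "p7"]

    def test_non_significant_term_is_contract_error(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        with pytest.raises(ContractError):
            select_variables(mixed_results["GO:B"], verdicts[("GO:B", "mu0")], 0.5)


class TestMcc:
    @pytest.mark.parametrize(
        "confusion,expected",
        [
            ((5, 5, 0, 0), 1.0),
            ((0, 0, 5, 5), -1.0),
            ((3, 4, 1, 2), 10 / math.sqrt(600)),  # ~0.408
            ((5, 0, 5, 0), 0.0),  # zero denominator factor
        ],
    )
    def test_values(self, confusion, expected):
        assert compute_mcc(confusion) == pytest.approx(expected, abs=1e-12)


class TestUnifiedList:
    def test_merges_l1l2_and_rls_sources(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        unified = build_unified_list(mixed_results, verdicts, "mu0", 0.5)
        assert [u.term_id for u in unified] == ["GO:C", "GO:A"]  # by error asc
        assert {u.source for u in unified} == {"mu0", RLS_KEY}

    def test_mcc_recomputable_from_confusion_totals(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        for u in build_unified_list(mixed_results, verdicts, "mu0", 0.5):
            assert u.mcc == pytest.approx(compute_mcc(u.confusion_totals))
            assert u.n_properly_selected <= u.total_variables

    def test_empty_when_nothing_significant(self, mixed_results):
        l1l2_only = {t: r for t, r in mixed_results.items() if t != "GO:C"}
        verdicts = call_significance(l1l2_only, 0.01)
        assert build_unified_list(l1l2_only, verdicts, "mu0", 0.5) == []

    def test_partition_covers_all_significant_terms(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        unified = build_unified_list(mixed_results, verdicts, "mu0", 0.5)
        sig = {t for (t, k), v in verdicts.items() if v.significant}
        assert {u.term_id for u in unified} == sig


class TestAnnotateVariables:
    @pytest.fixture
    def maps(self):
        anno = AnnotationTable(
            [
                AnnotationRecord("p1", "TP53", frozenset(), "7157", "NM_000546"),
                AnnotationRecord("p2", "EGFR", frozenset(), "1956", None),
            ]
        )
        hgnc = GeneNameTable(
            [GeneNameRecord("TP53", frozenset(), frozenset()),
             GeneNameRecord("EGFR", frozenset(), frozenset())]
        )
        return anno, build_probeset_to_gene(anno, hgnc)

    def test_full_record(self, maps):
        anno, p2g = maps
        (rec,) = annotate_variables(["p1"], p2g, anno, {"p1": 4})
        assert rec.gene_symbol == "TP53"
        assert rec.entrez_id == "7157" and rec.genbank_id == "NM_000546"
        assert rec.frequency == 4

    def test_missing_external_id_permitted(self, maps):
        anno, p2g = maps
        (rec,) = annotate_variables(["p2"], p2g, anno)
        assert rec.genbank_id is None and rec.frequency is None

    def test_unknown_probeset_yields_unresolved_record(self, maps):
        anno, p2g = maps
        (rec,) = annotate_variables(["p9"], p2g, anno)
        assert rec.resolution_status == "unresolved"


class TestHistograms:
    def test_conservation_selected_plus_not_selected(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        sel, notsel = build_histograms(mixed_results, verdicts, "mu0", 0.5, 10)
        sel_c = {p: c for p, _, c in sel.counts}
        not_c = {p: c for p, _, c in notsel.counts}
        # membership count in significant mu0 subsets (only GO:A here)
        for p in ("p1", "p2", "p3"):
            assert sel_c.get(p, 0) + not_c.get(p, 0) == 1
        # variables of non-significant subsets appear in neither histogram
        assert "p4" not in sel_c and "p4" not in not_c

    def test_rls_has_no_not_selected_histogram(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        sel, notsel = build_histograms(mixed_results, verdicts, RLS_KEY, 0.5, 10)
        assert notsel is None
        assert {p: c for p, _, c in sel.counts} == {"p6": 1, "p7": 1}

    def test_metadata_fields(self, mixed_results):
        verdicts = call_significance(mixed_results, 0.30)
        sel, _ = build_histograms(mixed_results, verdicts, "mu0", 0.5, 42)
        assert sel.n_significant_terms == 1
        assert sel.n_domain_terms == 42
        assert sel.total_entries == len(sel.counts)


class TestSummarizeErrors:
    def test_two_results_mean_and_median(self):
        results = {
            "GO:A": _result("GO:A", L1L2FS, ["p1"], [([], 0.1)] * 4),
            "GO:B": _result("GO:B", L1L2FS, ["p2"], [([], 0.3)] * 4),
        }
        results["GO:A"].per_mu["mu0"].mean_test_error = 0.1
        results["GO:B"].per_mu["mu0"].mean_test_error = 0.3
        stats = summarize_errors(results)
        mean, sd, med = stats.per_mu["mu0"]
        assert mean == pytest.approx(0.2) and med == pytest.approx(0.2)

    def test_single_result_sd_zero(self):
        results = {"GO:A": _result("GO:A", L1L2FS, ["p1"], [([], 0.25)] * 4)}
        mean, sd, med = summarize_errors(results).per_mu["mu0"]
        assert sd == 0.0 and mean == med == 0.25

    def test_statistics_match_recomputation_from_splits(self, mixed_results):
        stats = summarize_errors(mixed_results)
        errs = [
            pm.mean_test_error
            for r in mixed_results.values()
            for pm in r.per_mu.values()
        ]
        assert stats.overall[0] == pytest.approx(float(np.mean(errs)))
        assert stats.overall[2] == pytest.approx(float(np.median(errs)))
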