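"""The two pipeline phases operating on a shared *ensemble* directory.

The experiment phase ingests all inputs, persists raw and derived tables
in the embedded relational store, masks the expression matrix per GO
term, runs the learner on every subset (optionally in parallel — results
are merged by term key, so worker count never changes a byte of output)
and marks the ensemble complete.  The postprocess phase then works on the
frozen ensemble only: significance calls, unified term lists, properly
selected variables, histograms, error statistics, semantic clustering
and optional benchmark coverage.  Both phases are replayable from the
config snapshot stored inside the ensemble.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
from dataclasses import dataclass

import yaml
from joblib import Parallel, delayed

from . import benchmark as bench_mod
from . import postprocess as pp
from .errors import GosigError, IncompleteEnsembleError
from .integrate import build_probeset_to_gene, build_term_to_probeset
from .io import (
    AnnotationColumns,
    DsvDialect,
    read_annotations,
    read_gedm,
    read_gene_names,
    read_go_graph,
    read_labels,
)
from .learn import RLS_KEY, SelectionResult, SolverConfig, run_task
from .semantics import (
    build_similarity_matrix,
    cluster_terms,
    compute_ic,
    emit_dot,
    minimal_subgraph,
)
from .store import RelationalStore
from .subsets import generate_subsets

logger = logging.getLogger(__name__)

COMPLETE_MARKER = "COMPLETE"


@dataclass
class Thresholds:
    error: float = 0.30
    frequency: float = 0.5
    semantic: float = 0.8


def load_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise GosigError(f"{path}: config must be a mapping with an 'inputs' section")
    return cfg


def solver_config_from(cfg: dict) -> SolverConfig:
    s = cfg.get("solver", {}) or {}
    return SolverConfig(
        mu_values=tuple(s["mu_values"]) if s.get("mu_values") else None,
        l1_grid=tuple(s["l1_grid"]) if s.get("l1_grid") else None,
        n_l1=int(s.get("n_l1", 20)),
        inner_k=int(s.get("inner_k", 3)),
        outer_k=int(s.get("outer_k", 4)),
        tol=float(s.get("tol", 1e-5)),
        max_iter=int(s.get("max_iter", 5000)),
        seed=int(s.get("seed", 0)),
        standardize=bool(s.get("standardize", True)),
        rls_lam=float(s.get("rls_lam", 0.0)),
    )


def _write_tsv(path: str, header: list[str], rows: list[list]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join("" if c is None else str(c) for c in row) + "\n")


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def run_experiment(config_path: str, ensemble_dir: str, workers: int = 1) -> str:
    """Phase 1: ingest, integrate, subset, learn.  Returns the ensemble path.

    The ensemble is marked complete only after every mapped term has a
    stored :class:`SelectionResult`; a failed run leaves no completion
    marker and postprocess will refuse it.
    """
    cfg = load_config(config_path)
    inputs = cfg["inputs"]
    for key in ("gedm", "annotations", "labels", "gene_names", "go"):
        if key not in inputs:
            raise GosigError(f"config missing input path {key!r}")
        if not os.path.exists(inputs[key]):
            raise GosigError(f"input file not found: {inputs[key]} (for {key!r})")

    os.makedirs(ensemble_dir, exist_ok=True)
    marker = os.path.join(ensemble_dir, COMPLETE_MARKER)
    if os.path.exists(marker):
        os.remove(marker)
    os.makedirs(os.path.join(ensemble_dir, "results"), exist_ok=True)
    shutil.copyfile(config_path, os.path.join(ensemble_dir, "config.yaml"))

    dialect = DsvDialect(delimiter=cfg.get("delimiter", "\t"))
    col_cfg = cfg.get("columns", {}) or {}
    columns = AnnotationColumns(
        probeset=col_cfg.get("probeset", "probeset_id"),
        symbol=col_cfg.get("symbol", "gene_symbol"),
        go_terms=col_cfg.get("go_terms", "go_terms"),
        entrez=col_cfg.get("entrez", "entrez_id"),
        genbank=col_cfg.get("genbank", "genbank_id"),
        go_separator=col_cfg.get("go_separator", ";"),
    )
    class_map = {str(k): int(v) for k, v in cfg["class_map"].items()}
    domain = cfg.get("domain", "BP")

    gedm = read_gedm(inputs["gedm"], dialect)
    logger.info("GEDM: %d probesets x %d samples", gedm.n_probesets, gedm.n_samples)
    anno = read_annotations(inputs["annotations"], columns, dialect)
    labels = read_labels(inputs["labels"], class_map, dialect)
    hgnc = read_gene_names(inputs["gene_names"], dialect)
    dag = read_go_graph(inputs["go"], format=inputs.get("go_format", "obo"))

    store = RelationalStore(os.path.join(ensemble_dir, "store.db"))
    store.load_raw_tables(gedm, anno, hgnc, labels)

    tpmap = build_term_to_probeset(
        anno, dag, domain, gedm.probeset_ids,
        propagate=bool(cfg.get("propagate", False)),
    )
    p2g = build_probeset_to_gene(anno, hgnc)
    store.save_term_to_probeset(tpmap.pairs())
    store.save_probeset_to_gene(p2g.rows())
    store.close()

    subsets = generate_subsets(
        gedm, tpmap,
        ratio_threshold=float(cfg.get("ratio_threshold", 1.0)),
        min_probesets=int(cfg.get("min_probesets", 1)),
    )
    _write_tsv(
        os.path.join(ensemble_dir, "subsets.tsv"),
        ["term_id", "n_variables", "technique"],
        [[s.term_id, s.n_variables, s.technique] for s in subsets],
    )

    solver_cfg = solver_config_from(cfg)
    results: list[SelectionResult] = Parallel(n_jobs=workers, backend="loky" if workers > 1 else "sequential")(
        delayed(run_task)(s, labels, solver_cfg) for s in subsets
    )
    for res in sorted(results, key=lambda r: r.term_id):
        out = os.path.join(ensemble_dir, "results", f"{res.term_id.replace(':', '_')}.json")
        with open(out, "w") as fh:
            json.dump(res.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    with open(marker, "w") as fh:
        fh.write("experiment phase complete\n")
    logger.info("experiment complete: %d subsets learned", len(subsets))
    return ensemble_dir


def load_results(ensemble_dir: str) -> dict[str, SelectionResult]:
    """Load all stored SelectionResults from a completed ensemble."""
    if not os.path.exists(os.path.join(ensemble_dir, COMPLETE_MARKER)):
        raise IncompleteEnsembleError(
            f"ensemble at {ensemble_dir} is incomplete; run the experiment phase first"
        )
    results: dict[str, SelectionResult] = {}
    rdir = os.path.join(ensemble_dir, "results")
    for fname in sorted(os.listdir(rdir)):
        if fname.endswith(".json"):
            with open(os.path.join(rdir, fname)) as fh:
                res = SelectionResult.from_dict(json.load(fh))
            results[res.term_id] = res
    return results


def run_postprocess(
    ensemble_dir: str,
    thresholds: Thresholds = Thresholds(),
    benchmark_genes: str | None = None,
    benchmark_terms: str | None = None,
) -> str:
    """Phase 2: significance, outputs, semantics, benchmark coverage.

    Writes everything under ``<ensemble>/output`` and returns that path.
    Re-running on a frozen ensemble reproduces the outputs byte for byte.
    """
    results = load_results(ensemble_dir)
    cfg = load_config(os.path.join(ensemble_dir, "config.yaml"))
    inputs = cfg["inputs"]
    domain = cfg.get("domain", "BP")
    dialect = DsvDialect(delimiter=cfg.get("delimiter", "\t"))
    col_cfg = cfg.get("columns", {}) or {}
    columns = AnnotationColumns(
        probeset=col_cfg.get("probeset", "probeset_id"),
        symbol=col_cfg.get("symbol", "gene_symbol"),
        go_terms=col_cfg.get("go_terms", "go_terms"),
        entrez=col_cfg.get("entrez", "entrez_id"),
        genbank=col_cfg.get("genbank", "genbank_id"),
        go_separator=col_cfg.get("go_separator", ";"),
    )
    anno = read_annotations(inputs["annotations"], columns, dialect)
    hgnc = read_gene_names(inputs["gene_names"], dialect)
    dag = read_go_graph(inputs["go"], format=inputs.get("go_format", "obo"))
    gedm = read_gedm(inputs["gedm"], dialect)
    tpmap = build_term_to_probeset(
        anno, dag, domain, gedm.probeset_ids,
        propagate=bool(cfg.get("propagate", False)),
    )
    p2g = build_probeset_to_gene(anno, hgnc)
    n_domain_terms = len(dag.domain_terms(domain))
    gene_symbols = {pid: r.resolved_symbol for pid, r in p2g.resolutions.items()}
    term_names = {t: dag.name(t) for t in dag.terms}

    outdir = os.path.join(ensemble_dir, "output")
    if os.path.exists(outdir):
        shutil.rmtree(outdir)
    os.makedirs(outdir)

    verdicts = pp.call_significance(results, thresholds.error)
    mu_keys = sorted({k for r in results.values() for k in r.per_mu})
    l1l2_keys = [k for k in mu_keys if k != RLS_KEY]
    unified_keys = l1l2_keys if l1l2_keys else [RLS_KEY]

    # error statistics
    stats = pp.summarize_errors(results)
    _write_tsv(
        os.path.join(outdir, "error_statistics.tsv"),
        ["scope", "mean_test_error", "sd_test_error", "median_test_error"],
        [[k, _fmt(m), _fmt(s), _fmt(md)] for k, (m, s, md) in stats.per_mu.items()]
        + [["overall", *map(_fmt, stats.overall)]],
    )

    # per-mu significant term lists with l1l2 model-selection details
    for key in mu_keys:
        rows = []
        for term_id in sorted(results):
            res = results[term_id]
            if key not in res.per_mu:
                continue
            v = verdicts[(term_id, key)]
            if not v.significant:
                continue
            pm = res.per_mu[key]
            n_sel = len(pp.select_variables(res, v, thresholds.frequency))
            rows.append([
                term_id, key, _fmt(pm.mean_test_error), _fmt(pm.sd_test_error),
                _fmt(pm.mean_train_error), _fmt(pm.sd_train_error),
                _fmt(pm.median_test_error), res.total_variables, n_sel,
            ])
        _write_tsv(
            os.path.join(outdir, f"significant_terms_{key}.tsv"),
            ["term_id", "mu_index", "mean_test_error", "sd_test_error",
             "mean_train_error", "sd_train_error", "median_test_error",
             "total_variables", "n_properly_selected"],
            rows,
        )

    # unified lists, variable lists, histograms, semantics, coverage per mu
    for key in unified_keys:
        unified = pp.build_unified_list(
            results, verdicts, key, thresholds.frequency, term_names
        )
        _write_tsv(
            os.path.join(outdir, f"unified_terms_{key}.tsv"),
            ["term_id", "term_name", "total_variables", "n_properly_selected",
             "error_estimate", "TP", "TN", "FP", "FN", "MCC", "source"],
            [[u.term_id, u.term_name, u.total_variables, u.n_properly_selected,
              _fmt(u.error_estimate), *u.confusion_totals, _fmt(u.mcc), u.source]
             for u in unified],
        )

        var_rows = []
        sel_genes: set[str] = set()
        for u in unified:
            res = results[u.term_id]
            v = verdicts[(u.term_id, u.source)]
            selected = pp.select_variables(res, v, thresholds.frequency)
            freqs = res.per_mu[u.source].frequencies if u.source != RLS_KEY else None
            for rec in pp.annotate_variables(selected, p2g, anno, freqs):
                var_rows.append([
                    u.term_id, rec.probeset_id, rec.gene_symbol,
                    rec.resolution_status, rec.entrez_id, rec.genbank_id,
                    rec.frequency,
                ])
                sel_genes.add(rec.gene_symbol)
        _write_tsv(
            os.path.join(outdir, f"properly_selected_{key}.tsv"),
            ["term_id", "probeset_id", "gene_symbol", "resolution_status",
             "entrez_id", "genbank_id", "frequency"],
            var_rows,
        )

        for hist_key in ({key, RLS_KEY} if key != RLS_KEY else {RLS_KEY}):
            sel_h, notsel_h = pp.build_histograms(
                results, verdicts, hist_key, thresholds.frequency,
                n_domain_terms, gene_symbols,
            )
            for hist in filter(None, (sel_h, notsel_h)):
                name = f"histogram_{hist.polarity.replace('-', '_')}_{hist_key}.tsv"
                with open(os.path.join(outdir, name), "w") as fh:
                    fh.write(f"# total_entries={hist.total_entries}\t"
                             f"n_significant_terms={hist.n_significant_terms}\t"
                             f"n_domain_terms={hist.n_domain_terms}\n")
                    fh.write("probeset_id\tgene_symbol\tcount\n")
                    for pid, sym, c in hist.counts:
                        fh.write(f"{pid}\t{sym}\t{c}\n")

        sig_terms = [u.term_id for u in unified]
        if len(sig_terms) >= 2:
            corpus = {t: len(ps) for t, ps in tpmap.term_to_probesets.items()}
            ic = compute_ic(dag, corpus, domain)
            usable = [t for t in sig_terms if t in ic]
            if len(usable) >= 2:
                sim = build_similarity_matrix(dag, ic, usable)
                clusters = cluster_terms(sim, thresholds.semantic)
                _write_tsv(
                    os.path.join(outdir, f"clusters_{key}.tsv"),
                    ["term_id", "cluster"],
                    [[t, clusters.labels[t]] for t in sim.terms],
                )
                _write_tsv(
                    os.path.join(outdir, f"similarity_{key}.tsv"),
                    ["term_id", *sim.terms],
                    [[t, *[_fmt(v) for v in row]]
                     for t, row in zip(sim.terms, sim.values)],
                )
                nodes, sub_edges = minimal_subgraph(dag, sim.terms)
                with open(os.path.join(outdir, f"subgraph_{key}.dot"), "w") as fh:
                    fh.write(emit_dot(nodes, sub_edges, clusters, dag))
        else:
            logger.info("fewer than 2 significant terms for %s; clustering skipped", key)

        if benchmark_genes or benchmark_terms:
            cov_rows = []
            bl = bench_mod.BenchmarkLists(
                genes=bench_mod.read_benchmark_genes(benchmark_genes)
                if benchmark_genes else frozenset(),
                terms=bench_mod.read_benchmark_terms(benchmark_terms)
                if benchmark_terms else frozenset(),
            )
            if bl.genes:
                rep = bench_mod.coverage_genes(sel_genes, bl)
                cov_rows.append(["genes", rep.restriction, rep.n_covered,
                                 rep.n_benchmark, _fmt(rep.coverage), rep.percent])
            if bl.terms:
                for restrict in (True, False):
                    rep = bench_mod.coverage_terms(sig_terms, bl, domain, restrict)
                    cov_rows.append(["terms", rep.restriction, rep.n_covered,
                                     rep.n_benchmark, _fmt(rep.coverage), rep.percent])
            _write_tsv(
                os.path.join(outdir, f"coverage_{key}.tsv"),
                ["list", "restriction", "n_covered", "n_benchmark",
                 "coverage", "percent"],
                cov_rows,
            )
    return outdir
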