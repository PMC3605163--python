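"""Synthetic input bundles with controlled signal.

Generates everything the pipeline ingests — expression matrix, platform
annotations, labels, gene-naming table, a toy GO DAG in OBO format and
benchmark lists — plus a ground-truth manifest, entirely offline.  The
model is a two-class differential-expression design: every probeset is
i.i.d. Gaussian baseline noise, and the probesets of *informative* terms
receive an additive class shift so that the two class means differ by
``effect_size`` standard deviations.  Informative probesets are exclusive
to their term, so every other term is pure noise and its subset carries
no class signal beyond chance.

A fixed seed makes the bundle byte-identical across runs.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import GosigError
from .io import GODag

_OBO_NAMESPACE = {"MF": "molecular_function", "BP": "biological_process",
                  "CC": "cellular_component"}


@dataclass(frozen=True)
class InformativeTerm:
    """A GO term carrying class signal in the generated bundle."""

    term_id: str
    n_informative: int
    effect_size: float = 3.0  # class-mean gap in SD units

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise GosigError("effect size must be >= 0")


@dataclass
class FixtureSpec:
    """Study conditions for a synthetic bundle.

    Defaults mirror the desk-scale verification design: 40 samples split
    evenly over two classes, unit Gaussian noise, term sizes log-uniform
    in [3, 200] so both the RLS route (small subsets) and the l1l2 route
    (large subsets) are exercised, and a 3-SD class shift on the
    informative probesets.
    """

    n_samples: int = 40
    n_noise_probesets: int = 200
    n_terms: int = 10
    term_size_range: tuple[int, int] = (3, 200)
    informative_terms: list[InformativeTerm] = field(default_factory=list)
    noise_sigma: float = 1.0
    class_balance: float = 0.5
    domain: str = "BP"
    heavy_tailed: bool = False  # Student-t(3) noise instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise GosigError("need at least 4 samples (2 per class)")
        if self.n_terms < 1:
            raise GosigError("need at least one term")
        lo, hi = self.term_size_range
        if not (1 <= lo <= hi):
            raise GosigError("bad term_size_range")


def _term_ids(n: int) -> list[str]:
    # synthetic GO-style identifiers; GO:9 prefix avoids real accessions
    return [f"GO:9{i:06d}" for i in range(1, n + 1)]


def _random_dag(
    term_ids: list[str], root: str, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Random rooted tree plus extra is_a edges (acyclic: edges only point
    to earlier terms)."""
    ordered = [root] + term_ids
    edges: list[tuple[str, str]] = []
    for i, term in enumerate(term_ids, start=1):
        parent = ordered[int(rng.integers(0, i))]
        edges.append((term, parent))
        # occasional second parent deeper in the hierarchy
        if i > 2 and rng.random() < 0.25:
            extra = ordered[int(rng.integers(0, i))]
            if extra != parent:
                edges.append((term, extra))
    return edges


def write_obo(
    path: str,
    terms: dict[str, tuple[str, str]],
    edges: list[tuple[str, str]],
) -> None:
    """Write a minimal OBO file readable by obonet."""
    parents: dict[str, list[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: gosig-synthetic\n")
        for term in sorted(terms):
            name, domain = terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\n")
            fh.write(f"namespace: {_OBO_NAMESPACE[domain]}\n")
            for p in sorted(set(parents.get(term, []))):
                fh.write(f"is_a: {p} ! {terms[p][0]}\n")


def make_toy_dag(
    n_terms: int, seed: int, domain: str = "BP"
) -> tuple[GODag, dict[str, int], dict]:
    """A single-domain toy DAG with annotation counts and an IC manifest.

    The manifest's expected IC values are computed here by exhaustive
    brute-force enumeration of each term's descendant closure — an
    independent oracle for the IC implementation.
    """
    if n_terms < 3:
        raise GosigError("need at least 3 terms")
    rng = np.random.default_rng(seed)
    root = "GO:9000000"
    ids = _term_ids(n_terms - 1)
    edges = _random_dag(ids, root, rng)
    terms = {t: (f"synthetic term {t[-4:]}", domain) for t in [root] + ids}
    terms[root] = ("synthetic root", domain)
    dag = GODag(terms, edges)

    corpus = {t: int(rng.integers(0, 5)) for t in ids}
    corpus[root] = 1  # root always subsumes >= 1 annotation
    # leaf-biased extra annotations so deep terms are informative
    for t in ids:
        if not dag.children(t):
            corpus[t] += 1

    # brute-force descendant closure by reverse DFS over the raw edge list
    children_of: dict[str, set[str]] = {t: set() for t in terms}
    for child, parent in edges:
        children_of[parent].add(child)

    def closure(t: str) -> set[str]:
        out, stack = {t}, [t]
        while stack:
            for c in children_of[stack.pop()]:
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    subsumed = {t: sum(corpus.get(m, 0) for m in closure(t)) for t in terms}
    total = subsumed[root]
    expected_ic = {
        t: (-math.log(s / total) if s > 0 else None) for t, s in subsumed.items()
    }
    manifest = {
        "root": root,
        "domain": domain,
        "subsumed_counts": subsumed,
        "total_annotations": total,
        "expected_ic": expected_ic,
    }
    return dag, corpus, manifest


def make_bundle(spec: FixtureSpec, outdir: str) -> dict[str, str]:
    """Write a complete synthetic input bundle to ``outdir``.

    Returns the mapping of logical input name -> file path.  The bundle
    contains ``gedm.tsv``, ``annotations.tsv``, ``labels.tsv``,
    ``gene_names.tsv``, ``go.obo``, ``benchmark_genes.tsv``,
    ``benchmark_terms.tsv`` and a ``manifest.json`` of ground truth.
    """
    for it in spec.informative_terms:
        lo, _hi = spec.term_size_range
        if it.n_informative < 1:
            raise GosigError(f"{it.term_id}: n_informative must be >= 1")
    known = set(_term_ids(spec.n_terms))
    for it in spec.informative_terms:
        if it.term_id not in known:
            raise GosigError(f"informative term {it.term_id} not among generated terms")

    rng = np.random.default_rng(spec.seed)
    os.makedirs(outdir, exist_ok=True)

    # --- DAG -------------------------------------------------------------
    root = "GO:9000000"
    term_ids = _term_ids(spec.n_terms)
    edges = _random_dag(term_ids, root, rng)
    terms = {t: (f"synthetic term {t[-4:]}", spec.domain) for t in term_ids}
    terms[root] = ("synthetic root", spec.domain)

    # --- term membership --------------------------------------------------
    lo, hi = spec.term_size_range
    sizes = {
        t: int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        for t in term_ids
    }
    informative = {it.term_id: it for it in spec.informative_terms}
    noise_pool = [f"p{i:05d}" for i in range(1, spec.n_noise_probesets + 1)]
    membership: dict[str, list[str]] = {}
    informative_probesets: dict[str, list[str]] = {}
    extra_counter = 0
    for t in term_ids:
        size = sizes[t]
        info_ps: list[str] = []
        if t in informative:
            n_inf = informative[t].n_informative
            size = max(size, n_inf)
            info_ps = [f"i{extra_counter + j:04d}" for j in range(n_inf)]
            extra_counter += n_inf
        n_noise = min(size - len(info_ps), len(noise_pool))
        chosen = rng.choice(len(noise_pool), size=n_noise, replace=False)
        membership[t] = info_ps + sorted(noise_pool[i] for i in chosen)
        informative_probesets[t] = info_ps

    all_probesets = sorted({p for ps in membership.values() for p in ps})
    p_index = {p: i for i, p in enumerate(all_probesets)}

    # --- labels -----------------------------------------------------------
    n_pos = int(round(spec.n_samples * spec.class_balance))
    n_pos = min(max(n_pos, 2), spec.n_samples - 2)
    sample_ids = [f"s{i:03d}" for i in range(1, spec.n_samples + 1)]
    y = np.array([1] * n_pos + [-1] * (spec.n_samples - n_pos))
    y = y[rng.permutation(spec.n_samples)]
    raw_labels = {1: "case", -1: "control"}
    class_map = {"case": 1, "control": -1}

    # --- expression -------------------------------------------------------
    shape = (len(all_probesets), spec.n_samples)
    if spec.heavy_tailed:
        noise = rng.standard_t(3, size=shape) * spec.noise_sigma
    else:
        noise = rng.normal(0.0, spec.noise_sigma, size=shape)
    values = noise
    for t, it in informative.items():
        shift = 0.5 * it.effect_size * spec.noise_sigma
        for p in informative_probesets[t]:
            values[p_index[p], :] += shift * y

    # --- genes ------------------------------------------------------------
    gene_of = {p: f"G{p_index[p] + 1:05d}" for p in all_probesets}
    # a few platform symbols are stale: written as previous symbols / aliases
    stale_prev = {p: f"OLD{p_index[p] + 1}" for p in all_probesets[:2]}
    stale_alias = {p: f"ALT{p_index[p] + 1}" for p in all_probesets[2:4]}

    paths = {
        "gedm": os.path.join(outdir, "gedm.tsv"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "labels": os.path.join(outdir, "labels.tsv"),
        "gene_names": os.path.join(outdir, "gene_names.tsv"),
        "go": os.path.join(outdir, "go.obo"),
        "benchmark_genes": os.path.join(outdir, "benchmark_genes.tsv"),
        "benchmark_terms": os.path.join(outdir, "benchmark_terms.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }

    with open(paths["gedm"], "w") as fh:
        fh.write("probeset_id\t" + "\t".join(sample_ids) + "\n")
        for p in all_probesets:
            row = "\t".join(f"{v:.6f}" for v in values[p_index[p]])
            fh.write(f"{p}\t{row}\n")

    terms_of: dict[str, set[str]] = {p: set() for p in all_probesets}
    for t, ps in membership.items():
        for p in ps:
            terms_of[p].add(t)
    with open(paths["annotations"], "w") as fh:
        fh.write("probeset_id\tgene_symbol\tgo_terms\tentrez_id\tgenbank_id\n")
        for p in all_probesets:
            symbol = stale_prev.get(p) or stale_alias.get(p) or gene_of[p]
            entrez = str(10000 + p_index[p])
            genbank = "" if p_index[p] % 7 == 0 else f"NM_{90000 + p_index[p]}"
            fh.write(
                f"{p}\t{symbol}\t{';'.join(sorted(terms_of[p]))}\t{entrez}\t{genbank}\n"
            )

    with open(paths["labels"], "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s, lab in zip(sample_ids, y):
            fh.write(f"{s}\t{raw_labels[int(lab)]}\n")

    with open(paths["gene_names"], "w") as fh:
        fh.write("approved_symbol\tprevious_symbols\taliases\tstatus\n")
        for p in all_probesets:
            prev = stale_prev.get(p, "")
            alias = stale_alias.get(p, "")
            fh.write(f"{gene_of[p]}\t{prev}\t{alias}\tApproved\n")

    write_obo(paths["go"], terms, edges)

    informative_genes = sorted(
        gene_of[p] for t in informative for p in informative_probesets[t]
    )
    decoy_genes = [f"DECOY{i}" for i in range(1, 6)]
    with open(paths["benchmark_genes"], "w") as fh:
        fh.write("gene_symbol\n")
        for g in informative_genes + decoy_genes:
            fh.write(g + "\n")

    decoy_terms = [(t, spec.domain) for t in term_ids if t not in informative][:2]
    other_domain = "MF" if spec.domain != "MF" else "CC"
    with open(paths["benchmark_terms"], "w") as fh:
        fh.write("term_id\tdomain\n")
        for t in sorted(informative):
            fh.write(f"{t}\t{spec.domain}\n")
        for t, d in decoy_terms:
            fh.write(f"{t}\t{d}\n")
        fh.write(f"GO:9999999\t{other_domain}\n")

    manifest = {
        "seed": spec.seed,
        "domain": spec.domain,
        "n_samples": spec.n_samples,
        "n_probesets": len(all_probesets),
        "class_map": class_map,
        "term_sizes": {t: len(membership[t]) for t in term_ids},
        "informative_terms": {
            t: {
                "probesets": informative_probesets[t],
                "genes": sorted(gene_of[p] for p in informative_probesets[t]),
                "effect_size": informative[t].effect_size,
            }
            for t in sorted(informative)
        },
        "membership": {t: membership[t] for t in sorted(membership)},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
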