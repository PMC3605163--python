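# gosig — knowledge-driven gene-signature discovery

`gosig` analyzes two-class gene-expression experiments the other way
around from the usual select-then-enrich workflow: instead of mining one
monolithic expression matrix for differentially expressed genes and
testing the result for Gene Ontology enrichment afterwards, it uses the
ontology *first*. The P × N expression matrix (P probesets, N samples) is
masked into one P_X × N submatrix per GO term, using the platform's
probeset → GO annotations, and a supervised classifier with embedded
variable selection is run on every submatrix. A GO term is *significant*
when its subset classifies the two phenotypes well; the probesets that
drive that classification stably are the term's signature. Functional
interpretation is therefore built into the selection step rather than
bolted on after it.

It is written for computational biologists working with two-class
microarray-style expression data (tumor/normal, case/control) who want
per-function gene signatures with honest cross-validated error estimates.

## The method

For each GO-term subset with design matrix X ∈ ℝ^{n×p} and labels
y ∈ {−1,+1}^n, variable selection solves the l1l2-regularized
least-squares problem

    min_w  (1/n)‖y − Xw‖₂² + μ‖w‖₂² + λ₁‖w‖₁

by accelerated iterative soft-thresholding (FISTA). λ₁ controls sparsity
(the solution is exactly 0 at λ₁ ≥ 2·maxⱼ|(1/n)Σᵢ Xᵢⱼyᵢ|); the
*correlation parameter* μ governs how many correlated variables enter the
selected list together. Model selection is a full nested K-fold
cross-validation: inner folds choose λ₁, outer folds estimate the
classification error (sign rule on an RLS refit of the selected support)
and record which variables each split selected. Subsets small enough that
p is roughly ≤ n skip model selection and are classified with plain
regularized least squares (regularization 0) on all variables.

Postprocessing calls a term significant when its mean outer-CV error is
strictly below a threshold (default 0.30), calls a variable *properly
selected* when its outer-fold selection frequency strictly exceeds a
fraction threshold (default 0.5), merges the per-μ l1l2 lists with the
RLS list into unified term lists with pooled confusion counts and the
Matthews correlation coefficient, and annotates probesets back to
HGNC-verified gene symbols. Significant terms are then clustered by
Resnik semantic similarity — the information content
IC(t) = −log(annotations subsumed by t / annotations subsumed by the
root) of the most-informative common ancestor, normalized to the maximum
observed value — with an agglomerative cut at distance
1 − semantic-threshold (default 0.8), and painted onto the minimal GO
subgraph as DOT. Optional benchmark gene/term lists are scored by
coverage, with the term denominator restricted to the analyzed GO domain.

## Worked example

`examples/run_pipeline.py` generates a synthetic bundle (40 samples, six
BP terms of 45–70 probesets, one term carrying five probesets with a 3-SD
class shift), runs both pipeline phases and prints:

```
--- unified term list (mu index 0) ---
term_id	term_name	total_variables	n_properly_selected	error_estimate	TP	TN	FP	FN	MCC	source
GO:9000001	synthetic term 0001	59	5	0	20	20	0	0	1	mu0

--- benchmark coverage ---
list	restriction	n_covered	n_benchmark	coverage	percent
genes	all	5	10	0.5	50
terms	domain-restricted	1	3	0.3333333333	33
```

The planted term GO:9000001 is the only significant one: its 59-variable
subset classifies the 40 samples with zero outer-CV error (perfect pooled
confusion, MCC 1), and exactly the five informative probesets are
properly selected. The benchmark lists contain the five informative genes
plus five decoys, so gene coverage is 50%; of the three same-domain
benchmark terms one (the planted term) is recovered, 33%.

The other examples each exercise one capability:
`solve_l1l2.py` (sparsity path and the μ effect on correlated variables),
`semantic_clustering.py` (IC, Resnik similarity, threshold behavior),
`benchmark_coverage.py` (coverage arithmetic and domain restriction).

There is also a thin CLI over the same pipeline:

```sh
gosig experiment  --config config.yaml --ensemble runs/exp1
gosig postprocess --ensemble runs/exp1 --error-threshold 0.30
```

## Layout

- `src/gosig/io.py`, `store.py` — DSV/OBO ingestion and the embedded
  relational store (raw tables GEDM/ANNO/HGNC/LABELS).
- `src/gosig/integrate.py` — derived term2probeset and probeset2gene maps.
- `src/gosig/subsets.py` — per-term masking and RLS/l1l2 routing.
- `src/gosig/learn.py` — the l1l2 solver, RLS, nested CV, frequencies.
- `src/gosig/postprocess.py` — significance, unified lists, MCC, histograms.
- `src/gosig/semantics.py` — IC, Resnik, clustering, minimal subgraph, DOT.
- `src/gosig/benchmark.py` — coverage scoring.
- `src/gosig/synthetic.py` — synthetic input bundles with controlled signal.
- `src/gosig/pipeline.py`, `cli.py` — the two phases over a shared ensemble.

See `docs/methods.md` for the modeling assumptions, parameter defaults
and numerical choices.
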