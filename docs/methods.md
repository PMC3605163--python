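# Methods

## Problem setting and model

The package addresses two-class supervised analysis of an expression
matrix (P probesets × N samples, P ≫ N) in which prior knowledge — the
Gene Ontology DAG plus the platform's probeset→term annotations — is
applied *before* variable selection. Each GO term of the chosen domain
(MF, BP or CC) masks the matrix down to its annotated probesets, and
every resulting P_X × N subset is analyzed independently. Analysis stays
at the probeset level throughout: several probesets may interrogate one
gene, and aggregating them (e.g. averaging) would introduce bias, so no
gene-level collapsing is performed before learning. Subsets overlap by
construction because the DAG shares probesets across terms; this is
intentional, not an error condition.

Per subset, variable selection is the convex problem

    J(w) = (1/n)‖y − Xw‖² + μ‖w‖² + λ₁‖w‖₁ ,   y ∈ {−1,+1}ⁿ

with X the subset's samples-by-probesets matrix. The loss carries a 1/n
scaling so penalty grids are independent of the sample count; under this
convention the smallest fully-shrinking penalty is
λ₁max = 2·maxⱼ|(1/n)Σᵢ Xᵢⱼ yᵢ|. The solver is FISTA with a fixed step
1/L, L = 2(σmax(X)²/n + μ), stopping when the subgradient (KKT) residual
drops below the tolerance; warm starts are used along the λ₁ path.
Prediction is two-stage: the l1l2 support is refitted by regularized
least squares (regularizer 0 by default, i.e. the minimum-norm
least-squares solution) and classified by the sign rule, with an exact
zero score mapping to +1. An empty support predicts the majority
training label (tie → +1).

## Model selection and error estimation

Each l1l2 subset runs two nested stratified K-fold loops sharing one
per-term random stream:

- **outer loop** (default K = 4): estimates the test error, records the
  selected-variable set of each split and the per-split confusion
  counts; selection *frequency* is the number of outer splits selecting
  a variable.
- **inner loop** (default K = 3), run inside each outer training fold:
  chooses λ₁ from a geometric grid (default 20 points from 1e−3·λ₁max up
  to the fold's λ₁max, descending for warm starts).

The inner criterion is the *squared* validation loss of the two-stage
refit, not the 0/1 classification error. On validation folds of a dozen
samples the 0/1 error takes few distinct values, producing massive ties
across the λ₁ grid; resolving those ties toward the sparsest model
systematically drops members of correlated informative groups, which
defeats the purpose of the correlation parameter μ. The squared loss is
the quantity the solver itself optimizes and is continuous, so ties are
rare; when they do occur the largest λ₁ (sparsest model) still wins.

Columns are standardized with outer-training-fold statistics only
(applied unchanged to the test fold), preventing information leakage;
zero-variance columns get unit scale. Folds are stratified so every fold
contains both classes; a class smaller than K is a hard error.

Subsets with P_X ≤ ratio·N (default ratio 1.0, boundary inclusive) skip
model selection: plain RLS with regularizer 0 on all variables, outer
loop only, every variable counted as selected in every split. The final
selected-or-not verdict for these subsets is made downstream at
significance time.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| μ grid | {0.01, 0.1, 1}·trace(XᵀX)/(np) | correlation penalty; larger values co-select correlated variables (scale ≈ 1 after standardization) |
| λ₁ grid | 20-point geometric, per fold | sparsity penalty range up to full shrinkage |
| outer_K / inner_K | 4 / 3 | error estimation / λ₁ choice |
| error threshold | 0.30 | term significant iff mean outer error strictly below |
| frequency threshold | 0.5 | variable properly selected iff frequency/outer_K strictly above |
| semantic threshold | 0.8 | flat-cluster cut at distance 1 − threshold |
| ratio threshold | 1.0 | route to RLS iff P_X ≤ ratio·N |
| solver tol / max_iter | 1e−5 / 5000 | KKT residual stop / iteration cap |

Both significance thresholds are strict inequalities ("below" / "above");
boundary values fail. The per-μ split-error SD uses the population
convention (ddof 0), so a single split reports SD 0. MCC uses the
zero-denominator → 0 convention. Sorting of unified lists is by error
estimate ascending with term-id tie-break, making outputs reproducible.

## Semantic clustering

The information content of a term is IC(t) = −log(a(t)/a(root)), where
a(t) sums direct annotation counts over t and all DAG descendants within
the domain. By default the term→probeset map itself serves as the
annotation corpus (each probeset annotation counts once), so no external
association download is needed; an external corpus can be supplied.
Terms subsuming zero annotations have undefined IC and are excluded from
similarity with a warning. Resnik similarity is the IC of the
most-informative common ancestor (a term is its own ancestor, so
sim(t,t) = IC(t) and sim ≤ min(IC) always). The pairwise matrix over the
significant terms — diagonal included — is normalized by its maximum
entry; an all-zero matrix cannot be normalized and is returned as-is
with a warning. Clustering is agglomerative with average linkage on
distance 1 − similarity, cut at 1 − semantic-threshold; the IC log base
is natural (nats), and because similarities are normalized, any base
yields identical clusters. Cluster labels are contiguous integers in
order of first appearance, and the DOT emitter colors significant terms
from a fixed 12-color cycle so output is deterministic.

Only is_a edges build the DAG by default (part_of can be enabled for OBO
input); each domain must have exactly one root and edges may not cross
domains.

## Determinism and parallelism

Each GO term is an independent task whose random stream derives from
(run seed, CRC32 of the term id), so results are identical regardless of
task order or worker count; workers only change wall time. The
experiment phase writes a completion marker only after every mapped term
has a stored result; postprocess refuses incomplete ensembles, works
exclusively on the frozen ensemble, and reproduces its outputs byte for
byte on re-run. Floats in outputs are formatted with %.10g.

## The synthetic generator

`gosig.synthetic` emulates a normalized two-class microarray experiment:
i.i.d. Gaussian baseline (σ = 1 by default; Student-t(3) optionally for
robustness checks), balanced labels, and an additive shift of
±effect·σ/2 per class on the probesets of designated informative terms,
giving a class-mean gap of `effect` standard deviations (default 3).
Term sizes are log-uniform in [3, 200] so both the RLS and l1l2 routes
are exercised; informative probesets are exclusive to their term, so all
other subsets are pure noise. The gene-name table plants a few stale
platform symbols (previous symbols and aliases) to exercise HGNC
resolution, and benchmark lists mix the informative genes/terms with
decoys. A fixed seed yields byte-identical bundles.

What it does *not* emulate: probe-level physics, normalization
artifacts, batch effects, correlated noise between probesets of one
gene, or realistic annotation incompleteness. Passing the verification
suite therefore shows the machinery is correct and calibrated under the
stated noise model, not that any particular biological dataset will
yield signal.

## Verification design

The standard verification conditions are 40 samples, one informative
term of five probesets at a 3-SD gap among pure-noise terms of 45–70
probesets, outer_K = 4, significance threshold 0.30, evaluated over 20
seeded bundles with a 10-point λ₁ grid and μ = 1 (the grouping end of
the default grid, the setting whose purpose is stable co-selection of a
correlated informative group). Under these conditions the informative
term is recovered with its full probeset set at frequency K, noise terms
essentially never pass, and the mean cross-validated error on pure-noise
subsets sits at 1/2. The solver is checked against an independent
coordinate-descent oracle (scikit-learn's ElasticNet under the objective
mapping α = λ₁/2 + μ, l1_ratio = (λ₁/2)/α) on 200 random instances;
agreement is at the 1e−6 objective level with KKT residuals at
tolerance.

## Known limitations

- Two-class problems only; regression and multi-class are out of scope.
- No multiple-testing correction across terms: significance is a fixed
  error threshold by design, so the per-term false-positive rate, not a
  family-wise rate, is controlled.
- The RLS route has no intercept; strongly unbalanced classes shift the
  sign-rule operating point.
- Alias resolution is conservative: a platform symbol matching several
  approved records stays unresolved rather than guessing.
- DOT output is emitted, not rendered; use graphviz externally.
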