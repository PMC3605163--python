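"""End-to-end run on a synthetic bundle with one planted informative term.

Generates a two-class expression dataset (40 samples) in which one GO
term's probesets carry a 3-SD class shift, runs the experiment phase
(ingest, integration, per-term subsetting, nested-CV l1l2 selection) and
the postprocess phase (significance at error < 0.30, properly selected
variables, benchmark coverage), then prints the unified term list.
"""

import os
import tempfile

import yaml

from gosig import run_experiment, run_postprocess
from gosig.synthetic import FixtureSpec, InformativeTerm, make_bundle

with tempfile.TemporaryDirectory() as work:
    spec = FixtureSpec(
        n_samples=40,
        n_noise_probesets=120,
        n_terms=6,
        term_size_range=(45, 70),
        informative_terms=[InformativeTerm("GO:9000001", 5, effect_size=3.0)],
        seed=17,
    )
    paths = make_bundle(spec, os.path.join(work, "bundle"))

    config = {
        "inputs": {k: paths[k] for k in ("gedm", "annotations", "labels",
                                         "gene_names", "go")},
        "class_map": {"case": 1, "control": -1},
        "domain": "BP",
        "solver": {"mu_values": [1.0], "n_l1": 10, "inner_k": 3,
                   "outer_k": 4, "seed": 17},
    }
    cfg_path = os.path.join(work, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh)

    ensemble = run_experiment(cfg_path, os.path.join(work, "ensemble"))
    outdir = run_postprocess(
        ensemble,
        benchmark_genes=paths["benchmark_genes"],
        benchmark_terms=paths["benchmark_terms"],
    )

    print("--- unified term list (mu index 0) ---")
    print(open(os.path.join(outdir, "unified_terms_mu0.tsv")).read())
    print("--- benchmark coverage ---")
    print(open(os.path.join(outdir, "coverage_mu0.tsv")).read())

print(
    "Each unified-list row is one significant GO term: its subset size,\n"
    "how many probesets were properly selected (outer-fold frequency > 0.5),\n"
    "the mean outer-CV error used for the significance call, pooled\n"
    "confusion counts and the MCC. Coverage rows report the fraction of the\n"
    "benchmark gene/term lists the run recovered."
)
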