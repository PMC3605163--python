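"""Shared fixtures: synthetic bundles, toy DAGs, and small learning problems."""

import numpy as np
import pytest
import yaml

from gosig import GODag
from gosig.synthetic import FixtureSpec, InformativeTerm, make_bundle, make_toy_dag


@pytest.fixture(scope="session")
def toy_dag_bundle():
    """(dag, corpus, manifest) for an 8-term single-domain DAG with
    enumerated ground-truth IC values."""
    return make_toy_dag(8, seed=3)


@pytest.fixture(scope="session")
def hand_dag():
    """A tiny hand-built DAG: root R with children A, B; C below both A and B.

    domain BP throughout; known ancestor closures for closed-form checks.
    """
    terms = {
        "R": ("root", "BP"),
        "A": ("a", "BP"),
        "B": ("b", "BP"),
        "C": ("c", "BP"),
        "D": ("d", "BP"),
    }
    edges = [("A", "R"), ("B", "R"), ("C", "A"), ("C", "B"), ("D", "A")]
    return GODag(terms, edges)


@pytest.fixture(scope="session")
def signal_bundle(tmp_path_factory):
    """A bundle with one clearly informative term (5 probesets at 3 SD,
    40 samples) among noise terms; plus its config file."""
    outdir = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(
        n_samples=40,
        n_noise_probesets=120,
        n_terms=6,
        term_size_range=(45, 70),  # all subsets route to l1l2 at N=40
        informative_terms=[InformativeTerm("GO:9000001", 5, 3.0)],
        seed=11,
    )
    paths = make_bundle(spec, str(outdir))
    cfg = {
        "inputs": {k: paths[k] for k in ("gedm", "annotations", "labels", "gene_names", "go")},
        "class_map": {"case": 1, "control": -1},
        "domain": "BP",
        "solver": {"outer_k": 4, "inner_k": 3, "n_l1": 8, "mu_values": [0.1], "seed": 5},
    }
    cfg_path = outdir / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {"paths": paths, "config": str(cfg_path), "spec": spec}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
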