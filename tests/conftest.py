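import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import metaboprop as mp

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def toy_network():
    """Path A-B-C with unit weights."""
    edges = pd.DataFrame(
        {"gene1": ["A", "B"], "gene2": ["B", "C"], "weight": [1.0, 1.0]}
    )
    return mp.Network(edges=edges)


@pytest.fixture
def toy_map():
    return mp.GeneMetaboliteMap(
        gene_to_mets={
            "A": {"M1", "M2"},
            "B": {"M2", "M3"},
            "C": {"M4"},
        },
        met_masses={"M1": 100.0, "M2": 200.0, "M3": 300.0, "M4": 400.0},
    )


@pytest.fixture(scope="session")
def synth_world():
    """One shared 500-gene synthetic network + annotation map."""
    cfg = mp.simulate.SynthConfig(seed=11)
    net = mp.simulate.make_network(cfg)
    gm_map = mp.simulate.make_gene_metabolite_map(cfg, net)
    return cfg, net, gm_map


def random_network(rng, n_nodes, p=0.1, lo=1.0, hi=10.0):
    """Random weighted undirected graph as a Network (may have isolates)."""
    names = [f"N{i:03d}" for i in range(n_nodes)]
    rows = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                rows.append((names[i], names[j], float(rng.uniform(lo, hi))))
    if not rows:
        rows = [(names[0], names[1], 1.0)]
    edges = pd.DataFrame(rows, columns=["gene1", "gene2", "weight"])
    return mp.Network(edges=edges, extra_nodes=tuple(names))
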