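from __future__ import annotations

import numpy as np
import pytest
from skbio import TreeNode

from splicevo.gene_models import GeneModel, GenomicInterval
from splicevo.simulate import SimulationConfig, simulate_family
from splicevo.cli import bundled_scenario  # noqa: F401  (used via fixture)


@pytest.fixture(scope="session")
def scenario_family():
    """The bundled SR-like replacement scenario, simulated once."""
    import yaml

    with open(bundled_scenario()) as fh:
        data = yaml.safe_load(fh)
    cfg = SimulationConfig.from_dict(data["simulate"])
    cfg.seed = 11
    return simulate_family(cfg)


@pytest.fixture()
def three_exon_gene():
    """Plus-strand gene: exons [0,100), [200,300), [400,500); CDS [10,490)."""
    return GeneModel(
        gene_id="G1",
        species="testus",
        locus=GenomicInterval("chr1", 0, 500),
        exons=[
            GenomicInterval("chr1", 0, 100),
            GenomicInterval("chr1", 200, 300),
            GenomicInterval("chr1", 400, 500),
        ],
        cds_start=10,
        cds_end=490,
    ).validate()


def random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random binary rooted tree built by successive joins."""
    nodes = [TreeNode(name=f"L{i}", length=1.0) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        parent = TreeNode(length=1.0)
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root
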