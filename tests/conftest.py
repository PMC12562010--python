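"""Shared fixtures.

The heavy planted-signal experiments (5-seed sweeps) are session-scoped so
the acceptance tests that look at different aspects of the same runs share
one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from pathokg.experiments import run_baseline, run_gcn
from pathokg.graph_store import HeteroGraph, NodeRef
from pathokg.pipeline import TrainConfig
from pathokg.seq_context import ChromSeq
from pathokg.synth import SynthConfig

#: epoch budget used for the planted-signal study runs in this suite
SWEEP_EPOCHS = 100
SWEEP_SEEDS = [1, 2, 3, 4, 5]


@pytest.fixture()
def toy_chrom() -> ChromSeq:
    rng = np.random.default_rng(7)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200)])
    return ChromSeq("toy", seq)


@pytest.fixture()
def small_graph() -> HeteroGraph:
    """Pre-split PrimeKG-style graph: 2 proteins, a pathway, a disease."""
    g = HeteroGraph()
    g.add_node(NodeRef("P1", "protein", "GENE1"))
    g.add_node(NodeRef("P2", "protein", "GENE2"))
    g.add_node(NodeRef("PW1", "pathway", "apoptosis"))
    g.add_node(NodeRef("D1", "disease", "Fabry disease"))
    g.add_edge("P1", "P2", "Protein-Protein (transient PPI)")
    g.add_edge("PW1", "P1", "Pathway-Gene (interacts with)")
    g.add_edge("D1", "P1", "Disease-Gene (associated with)")
    return g


@pytest.fixture(scope="session")
def relational_sweep():
    """GCN and pair-baseline results on the relational planted-signal study.

    Five seeds at alpha = 0.9 (50 genes, 2 diseases/gene, 40 variants/gene);
    each seed regenerates data, split and initialization.
    """
    results = []
    for seed in SWEEP_SEEDS:
        sc = SynthConfig(seed=seed)
        tc = TrainConfig(seed=seed, epochs=SWEEP_EPOCHS)
        gcn = run_gcn(sc, tc)
        base = run_baseline(sc, tc, pair_input=True, dataset=gcn.dataset, split=gcn.split)
        results.append((gcn, base))
    return results


@pytest.fixture(scope="session")
def null_sweep():
    """GCN results with the planted signal removed (alpha = 0), five seeds."""
    results = []
    for seed in SWEEP_SEEDS:
        sc = SynthConfig(seed=seed, signal_strength=0.0)
        tc = TrainConfig(seed=seed, epochs=SWEEP_EPOCHS)
        results.append(run_gcn(sc, tc))
    return results
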