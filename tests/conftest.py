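"""Shared fixtures: planted-partition graphs and synthetic input tables.

Everything is generated in memory at session start from fixed seeds; no data
files ship with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from netgen.fixtures import (
    EvidenceSpec,
    FixtureSpec,
    GraphSpec,
    generate_gwas_qtl,
    generate_interactome,
)


@pytest.fixture(scope="session")
def two_block():
    """2 x 30 planted-partition graph with ground-truth labels."""
    g, labels = generate_interactome(GraphSpec(n_blocks=2, block_size=30), seed=1)
    return g, labels


@pytest.fixture(scope="session")
def five_block():
    """5 x 30 planted-partition graph; evidence module is a minority of the graph."""
    spec = GraphSpec(n_blocks=5, block_size=30, p_in=0.3, p_out=0.01)
    g, labels = generate_interactome(spec, seed=1)
    return g, labels


@pytest.fixture(scope="session")
def five_block_qtl(five_block):
    """GWAS/QTL/LD/annotation tables planted on the 5-block graph."""
    g, labels = five_block
    fix = FixtureSpec(seed=1, graph=GraphSpec(n_blocks=5, block_size=30),
                      evidence=EvidenceSpec(n_evidence=10, module=0))
    return generate_gwas_qtl(fix, g, labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
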