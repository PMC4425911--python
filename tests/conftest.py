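"""Shared fixtures: one seed-pinned study genome and read library.

Session-scoped so the full-depth simulation is paid once across the suite.
"""

import pytest

import pericerv as pv

GENOME_SEED = 1
READS_SEED = 2


@pytest.fixture(scope="session")
def templates():
    return pv.build_default_templates(seed=0)


@pytest.fixture(scope="session")
def primers():
    return {p.name: p for p in pv.load_primer_panel()}


@pytest.fixture(scope="session")
def genome():
    """Default 9-chromosome genome with 19 junction-bearing loci."""
    return pv.simulate_genome(seed=GENOME_SEED)


@pytest.fixture(scope="session")
def library30x(genome):
    """Error-free 30x read library with per-read ground truth."""
    return pv.simulate_reads(
        genome, read_length=100, depth=30, error_rate=0.0, seed=READS_SEED
    )


@pytest.fixture(scope="session")
def models(genome):
    return pv.junction_models(genome)
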