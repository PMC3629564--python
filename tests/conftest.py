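import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aluclip.synthetic import SimConfig, generate_genome, simulate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_genes=12, gene_length_range=(4000, 5000), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small synthetic dataset shared across tests (read-only)."""
    genome, truth, tracks, counts = simulate_dataset(small_config)
    return dict(
        config=small_config, genome=genome, truth=truth, tracks=tracks, counts=counts
    )


@pytest.fixture(scope="session")
def tiny_genome():
    cfg = SimConfig(n_genes=4, gene_length_range=(4000, 4500), seed=3)
    genome, genes, alus, truth = generate_genome(cfg)
    return dict(config=cfg, genome=genome, genes=genes, alus=alus, truth=truth)
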