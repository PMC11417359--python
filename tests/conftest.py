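import numpy as np
import pytest

from pachydyn import (
    KineticGene,
    MotifSpec,
    SimulationConfig,
    default_gene_panel,
    simulate_dataset,
    simulate_genome,
)


@pytest.fixture(scope="session")
def small_panel():
    return default_gene_panel(n_repression=8, n_induction=6, n_steady=6, seed=1)


@pytest.fixture(scope="session")
def noiseless_pair(small_panel):
    cfg = SimulationConfig(
        n_cells_per_sample=150,
        n_genes=20,
        noise_model="none",
        round_counts=False,
        qc_outlier_fraction=0.0,
        seed=2,
    )
    return simulate_dataset(small_panel, cfg)


@pytest.fixture(scope="session")
def noisy_pair(small_panel):
    cfg = SimulationConfig(n_cells_per_sample=150, n_genes=20, seed=3)
    return simulate_dataset(small_panel, cfg)


@pytest.fixture(scope="session")
def toy_genome(small_panel):
    bound = [g.gene_id for g in small_panel if g.gene_class != "steady"][:6]
    return simulate_genome(small_panel, MotifSpec(bound_genes=bound), seed=4)


@pytest.fixture
def demo_gene():
    return KineticGene("demo", alpha_on=2.0, beta=1.0, gamma=0.5,
                       t_switch=0.5, gene_class="induction")
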