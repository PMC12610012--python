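import numpy as np
import pytest

from wntomics.synthetic import SimulationConfig, gen_cell_tables, gen_cohort_pair


SMALL_COHORT = SimulationConfig(
    n_proteins=300, n_validation_features=400, frac_true_de=0.1,
    n_gene_sets=30, set_size_range=(5, 20), seed=11,
)

# reduced cell densities keep the spatial tests fast while preserving the
# planted WT/MUT CD8 contrast and the regime geometry
SMALL_DENSITIES = {
    "tumor": 350.0, "CD8_T_WT": 220.0, "CD8_T_MUT": 120.0,
    "macrophage": 90.0, "Treg": 40.0, "other": 200.0,
}


@pytest.fixture(scope="session")
def small_cohort():
    """Discovery/validation matrices with planted truth, small scale."""
    return gen_cohort_pair(SMALL_COHORT)


@pytest.fixture(scope="session")
def small_cells():
    """10-image cell table, mixed regimes, shift-free for gating tests."""
    cfg = SimulationConfig(n_images=10, batch_shift_sd=0.0,
                           interaction_regime="cycle",
                           phenotype_densities=dict(SMALL_DENSITIES), seed=7)
    return gen_cell_tables(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
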