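import numpy as np
import pytest

from trimix import (
    AlleleFrequencyPanel,
    SimulationConfig,
    simulate_cohort,
    simulate_reference_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    """3 populations x 5 loci with well-separated frequencies."""
    freqs = np.array(
        [
            [0.9, 0.8, 0.2, 0.3, 0.5],
            [0.1, 0.3, 0.9, 0.7, 0.4],
            [0.5, 0.6, 0.4, 0.1, 0.9],
        ]
    )
    return AlleleFrequencyPanel(
        pop_ids=["european", "african", "amerindian"],
        locus_ids=[f"L{i}" for i in range(1, 6)],
        freqs=freqs,
    )


@pytest.fixture
def sim_config():
    return SimulationConfig(
        fst=0.15,
        n_loci=40,
        ancestral_freq_range=(0.1, 0.9),
        dirichlet_params={
            ("North", "Brown"): (3.0, 1.0, 1.0),
            ("South", "Brown"): (1.0, 1.0, 3.0),
        },
        cohort_sizes={("North", "Brown"): 25, ("South", "Brown"): 25},
        seed=2024,
    )


@pytest.fixture
def sim_cohort(sim_config):
    panel = simulate_reference_panel(sim_config)
    return panel, simulate_cohort(panel, sim_config)
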