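import numpy as np
import pandas as pd
import pytest

from phenometab.simulate import (
    SimConfig,
    simulate_metabolome,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study (metabolome + phenotypes) shared by tests."""
    cfg = SimConfig(seed=11)
    matrix, truth = simulate_metabolome(cfg)
    series, post = simulate_phenotypes(cfg, truth, matrix)
    return cfg, matrix, truth, series, post


@pytest.fixture()
def small_matrix():
    """Tiny raw intensity matrix with blanks, one timepoint."""
    cfg = SimConfig(seed=3, n_features=40, n_drought_responsive=8,
                    n_causal_markers=2, timepoints=(22,),
                    replicates_control={22: 5}, replicates_drought={22: 7})
    matrix, truth = simulate_metabolome(cfg)
    return cfg, matrix, truth


def logistic_series(plant="P1", trait="biomass", noise_sd=0.03, seed=0,
                    n_days=22, amplitude=1e6):
    """Smooth logistic growth series with multiplicative noise."""
    rng = np.random.default_rng(seed)
    days = np.arange(1, n_days + 1)
    curve = amplitude / (1 + np.exp(-0.25 * (days - 18)))
    vals = curve * (1 + rng.normal(0, noise_sd, n_days))
    return pd.DataFrame({
        "plant": plant, "genotype": "G1", "treatment": "control",
        "day": days, "trait": trait, "value": vals,
    })
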