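import numpy as np
import pandas as pd
import pytest

from interactdeg.design import DesignSpec
from interactdeg.simulate import NBScenario, simulate_counts


@pytest.fixture
def saturated_2x2():
    """A 2x2 dataset whose observed cell means are exactly (100, 200, 100, 800).

    Two identical replicates per cell, unit size factors: the saturated
    log-link NB GLM must reproduce these cell means exactly, so the log2
    coefficients are known in closed form.
    """
    counts = pd.DataFrame(
        [[100, 100, 200, 200, 100, 100, 800, 800]],
        index=pd.Index(["g1"], name="gene_id"),
        columns=[f"s{i}" for i in range(8)],
    )
    metadata = pd.DataFrame(
        {
            "diet": ["SD", "SD", "WD", "WD", "SD", "SD", "WD", "WD"],
            "weeks": [3, 3, 3, 3, 6, 6, 6, 6],
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return counts, metadata


@pytest.fixture
def small_nb_dataset():
    """120 genes, 2x2 design, 6 samples per cell, known effects."""
    rng = np.random.default_rng(2024)
    G = 120
    scenario = NBScenario.two_by_two(
        baseline_log2=rng.uniform(6, 11, G),
        diet_effect_wk3=np.where(rng.random(G) < 0.3, rng.normal(0, 1, G), 0.0),
        diet_effect_wk6=np.where(rng.random(G) < 0.3, rng.normal(0, 1, G), 0.0),
        week_effect=0.3,
        dispersion=0.05,
        n_per_cell=6,
        seed=515,
    )
    counts, metadata = simulate_counts(scenario)
    return counts, metadata, scenario


@pytest.fixture
def interaction_design():
    return DesignSpec.with_interaction("diet", "weeks")
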