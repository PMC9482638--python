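import numpy as np
import pandas as pd
import pytest

from mmras import simulate as sim


@pytest.fixture(scope="session")
def screen_data():
    """Seeded dropout screen: 1,000 genes, 50 essentials at effect -2."""
    cfg = sim.ScreenSimConfig(
        n_genes=1000, guides_per_gene=4, n_essential=50, essential_effect=-2.0, seed=1
    )
    counts, truth = sim.simulate_crispr_screen(cfg)
    return counts, truth


@pytest.fixture(scope="session")
def silac_data():
    cfg = sim.SilacSimConfig(
        n_proteins=1000, n_true_interactors=50, interactor_log2fc_mean=3.0,
        interactor_log2fc_sd=0.5, seed=2,
    )
    return sim.simulate_silac_table(cfg)


@pytest.fixture
def toy_points():
    """Tight y ~ x cloud plus one gross outlier at (-3, 0)."""
    rng = np.random.default_rng(11)
    x = rng.normal(0, 1, 199)
    y = x + rng.normal(0, 0.05, 199)
    pts = pd.DataFrame(
        {"gene": [f"g{i}" for i in range(200)],
         "x": np.append(x, -3.0), "y": np.append(y, 0.0)}
    )
    return pts
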