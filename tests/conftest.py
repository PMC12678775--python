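import numpy as np
import pandas as pd
import pytest

from metadiet.synthio import SynthConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """A small planted-signal cohort pair shared across test modules."""
    cfg = SynthConfig(
        n_discovery=150, n_replication=150, n_metabolites=60, n_species=40,
        n_informative_metabolites=12, effect_size_beta=0.4, seed=7,
    )
    return generate_cohorts(cfg)


@pytest.fixture(scope="session")
def twin_frame():
    """Simple twin-pair regression dataset with a known mixed-model truth."""
    rng = np.random.default_rng(11)
    n_fam = 120
    fam = np.repeat(np.arange(n_fam), 2)
    n = fam.size
    u = np.repeat(rng.standard_normal(n_fam), 2) * np.sqrt(0.4)
    x = rng.standard_normal(n)
    covs = rng.standard_normal((n, 2))
    y = 0.3 * x + 0.2 * covs[:, 0] + u + rng.standard_normal(n) * np.sqrt(0.6)
    return pd.DataFrame(
        {"y": y, "x": x, "c1": covs[:, 0], "c2": covs[:, 1], "family": fam}
    )
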