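import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fourthcorner as fc

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def one_species_per_site():
    """Five sites, one exclusive species each, trait equal to the site's
    environmental value: the textbook perfect-correlation community."""
    sites = [f"site{i}" for i in range(1, 6)]
    species = [f"sp{i}" for i in range(1, 6)]
    R = fc.EnvMatrix(pd.DataFrame({"env": [1.0, 2, 3, 4, 5]}, index=sites))
    L = fc.AbundanceMatrix(
        pd.DataFrame(np.eye(5, dtype=int) * 3, index=sites, columns=species)
    )
    Q = fc.TraitMatrix(pd.DataFrame({"trait": [1.0, 2, 3, 4, 5]}, index=species))
    return R, L, Q


@pytest.fixture
def small_dataset():
    return fc.generate(
        fc.SyntheticConfig(n_sites=10, n_species=20, n_env=3, n_traits=4, seed=11)
    )


def random_triple(rng, n_sites, n_species, n_env=2, n_traits=2, max_count=5):
    """A random aligned triple with at least one nonzero abundance cell and
    non-constant env/trait columns."""
    while True:
        counts = rng.integers(0, max_count + 1, size=(n_sites, n_species))
        if counts.sum() == 0:
            continue
        keep_sites = counts.sum(axis=1) > 0
        keep_sp = counts.sum(axis=0) > 0
        counts = counts[np.ix_(keep_sites, keep_sp)]
        if counts.shape[0] < 1 or counts.shape[1] < 2:
            continue
        break
    sites = [f"s{i}" for i in range(counts.shape[0])]
    species = [f"p{j}" for j in range(counts.shape[1])]
    R = fc.EnvMatrix(
        pd.DataFrame(
            rng.normal(size=(counts.shape[0], n_env)),
            index=sites,
            columns=[f"e{k}" for k in range(n_env)],
        )
    )
    L = fc.AbundanceMatrix(pd.DataFrame(counts, index=sites, columns=species))
    Q = fc.TraitMatrix(
        pd.DataFrame(
            rng.normal(size=(counts.shape[1], n_traits)),
            index=species,
            columns=[f"t{m}" for m in range(n_traits)],
        )
    )
    return R, L, Q
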