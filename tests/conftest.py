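import numpy as np
import pytest

import metimpute as mi


@pytest.fixture(scope="session")
def small_complete():
    """Complete 60x30 labeled matrix, rank-5 log-factor structure."""
    return mi.generate_complete(
        mi.SynthSpec(n_samples=60, n_metabolites=30, latent_rank=5,
                     noise_sd=0.1, seed=101)
    )


@pytest.fixture(scope="session")
def labeled_complete():
    """Complete labeled matrix with group-shifted metabolites."""
    return mi.generate_complete(
        mi.SynthSpec(n_samples=80, n_metabolites=40, latent_rank=5,
                     noise_sd=0.1, n_affected=8, effect_size=1.5, seed=202)
    )


@pytest.fixture
def tiny_matrix():
    values = np.array([
        [1.0, 4.0, 7.0],
        [2.0, 5.0, 8.0],
        [3.0, 6.0, 9.0],
        [4.0, 7.0, 10.0],
    ])
    return mi.AbundanceMatrix(values, ["s1", "s2", "s3", "s4"],
                              ["m1", "m2", "m3"])
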