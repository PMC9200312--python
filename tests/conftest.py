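import numpy as np
import pytest

from proxymeta.ldsc import GenCovStructure
from proxymeta.sem import implied_sigma
from proxymeta.simulate import condition_registry, synth_ldscores


@pytest.fixture(scope="session")
def registry():
    return condition_registry()


@pytest.fixture(scope="session")
def ld20k():
    """Shared synthetic LD-score panel of 20k SNPs."""
    return synth_ldscores(20_000, seed=42)


@pytest.fixture(scope="session")
def ld100k():
    return synth_ldscores(100_000, seed=42)


@pytest.fixture()
def exact_gcs():
    """Noise-free genetic covariance structure from the empirical loadings."""
    S = implied_sigma([1.0, 0.463, 0.366], 0.073, [0.0, 0.0, 0.0])
    return GenCovStructure(
        S=S, V=np.eye(6) * 1e-6, intercepts=np.eye(3),
        labels=["direct", "maternal", "paternal"],
    )
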