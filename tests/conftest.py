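import numpy as np
import pandas as pd
import pytest

from ldpgs import GenotypePanel


def make_panel(n=50, m=20, seed=0, missing_rate=0.0, chrom="1", spacing=5000):
    """Random biallelic panel with optional missingness, Binomial(2, maf) dosages."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, size=m)
    dos = rng.binomial(2, maf, size=(n, m)).astype(float)
    if missing_rate > 0:
        dos[rng.random((n, m)) < missing_rate] = np.nan
    bases = np.array(list("ACGT"))
    a1 = bases[rng.integers(0, 4, m)]
    a0 = np.array([bases[(list(bases).index(x) + 1) % 4] for x in a1])
    variants = pd.DataFrame(
        {
            "chr": chrom,
            "pos": (1 + np.arange(m)) * spacing,
            "a0": a0,
            "a1": a1,
            "id": [f"v{j}" for j in range(m)],
        }
    )
    return GenotypePanel(dosages=dos, variants=variants)


@pytest.fixture
def small_panel():
    return make_panel(n=50, m=20, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
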