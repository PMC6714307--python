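import numpy as np
import pandas as pd
import pytest

from tnpipe.expression import CountMatrix
from tnpipe.simdata import SimConfig

#: package default seed, used everywhere a test needs one
SEED = 20190828


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort that still exercises every planted feature."""
    return SimConfig(n_sites=2000, n_genes=600, n_somatic=100, seed=SEED)


def make_null_count_matrix(
    n_genes: int = 2000,
    n_tumors: int = 4,
    n_controls: int = 5,
    dispersion: float = 0.1,
    seed: int = SEED,
) -> CountMatrix:
    """Both groups drawn from the identical NB law (no DE signal)."""
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(np.log(100.0), 1.0, n_genes))
    r = 1.0 / dispersion
    mu = np.tile(base[:, None], (1, n_tumors + n_controls))
    counts = rng.negative_binomial(r, r / (r + mu))
    samples = [f"T{i}" for i in range(n_tumors)] + [f"C{i}" for i in range(n_controls)]
    genes = [f"g{i}" for i in range(n_genes)]
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(1000.0, index=genes),
        groups=pd.Series(["tumor"] * n_tumors + ["control"] * n_controls, index=samples),
    )
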