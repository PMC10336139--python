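import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from codal.data import CountMatrix, CovariateDesign, encode_covariates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """40 cells x 25 genes with two latent groups and non-degenerate depths."""
    rates = np.ones(25)
    profile_a, profile_b = rates.copy(), rates.copy()
    profile_a[:8] *= 6.0
    profile_b[8:16] *= 6.0
    rows = []
    for i in range(40):
        p = profile_a if i < 20 else profile_b
        rows.append(rng.poisson(20 * p / p.sum() * 25))
    counts = sp.csr_matrix(np.array(rows))
    return CountMatrix(counts, feature_ids=[f"g{j}" for j in range(25)],
                       cell_ids=[f"c{i}" for i in range(40)], modality="RNA")


@pytest.fixture
def small_design(small_counts):
    n = small_counts.shape[0]
    table = pd.DataFrame({"batch": ["A"] * (n // 2) + ["B"] * (n - n // 2)},
                         index=small_counts.cell_ids)
    return encode_covariates(table, {"batch": "categorical"},
                             batch_key="batch")
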