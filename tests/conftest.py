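import numpy as np
import pandas as pd
import pytest

from refstab import datasets, to_quantities, to_log_quantities


@pytest.fixture(scope="session")
def schima_ct():
    return datasets.load_schima_ct()


@pytest.fixture(scope="session")
def schima_matrix(schima_ct):
    return schima_ct.to_matrix()


@pytest.fixture(scope="session")
def schima_summary():
    return datasets.load_schima_summary()


@pytest.fixture(scope="session")
def schima_q(schima_matrix):
    return to_quantities(schima_matrix)


@pytest.fixture(scope="session")
def schima_logq(schima_matrix):
    return to_log_quantities(schima_matrix)


@pytest.fixture(scope="session")
def published_bestkeeper():
    return datasets.load_published_bestkeeper()


@pytest.fixture(scope="session")
def published_consensus():
    return datasets.load_published_consensus()


@pytest.fixture(scope="session")
def published_overall():
    return datasets.load_published_overall()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_ct_matrix(rng, n_genes=5, n_samples=6, noise=0.8):
    """Small random Ct matrix for oracle comparisons."""
    base = rng.uniform(18, 26, n_genes)[:, None]
    shift = rng.normal(0, 1.0, n_samples)[None, :]
    eps = rng.normal(0, noise, (n_genes, n_samples))
    return pd.DataFrame(
        base + shift + eps,
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
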