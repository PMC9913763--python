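import numpy as np
import pandas as pd
import pytest

from atfdep import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated mycelium scenario shared across tests."""
    cfg = SimConfig(n_genes=400, seed=123)
    counts, sheet, truth = simulate_experiment(cfg)
    return cfg, counts, sheet, truth


@pytest.fixture()
def two_group_sheet():
    """3 vs 3 sample sheet for direct two-group DE tests."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "strain": ["control"] * 3 + ["atfA_del"] * 3,
            "treatment": "untreated",
            "cell_type": "mycelium",
            "batch": "b1",
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


def nb_counts(rng, means, n_samples, dispersion):
    """Negative-binomial count matrix with one mean per gene."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(np.repeat(means[:, None], n_samples, axis=1))
    size = 1.0 / dispersion
    p = size / (size + means[:, None])
    return rng.negative_binomial(size, np.repeat(p, n_samples, axis=1))


@pytest.fixture()
def make_counts():
    def _make(gene_means, columns, seed=0, dispersion=0.05):
        rng = np.random.default_rng(seed)
        mat = nb_counts(rng, gene_means, len(columns), dispersion)
        return pd.DataFrame(
            mat, index=[f"g{i:04d}" for i in range(len(gene_means))], columns=columns
        )

    return _make
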