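from __future__ import annotations

import numpy as np
import pytest

import ferrocup as fc


def random_matrix(rng, n_genes, n_samples, mode="log_intensity"):
    vals = rng.normal(7.0, 1.0, size=(n_genes, n_samples))
    if mode == "counts":
        vals = np.abs(np.round(vals))
    return fc.ExpressionMatrix(
        vals,
        [f"g{i:03d}" for i in range(n_genes)],
        [f"s{j:02d}" for j in range(n_samples)],
        mode=mode,
    )


def scale_free_matrix(n_genes=300, n_samples=350, beta=6, gamma=1.5, seed=11):
    """Expression whose sample correlations are exactly one-factor with
    loadings chosen so connectivity follows an exact power law."""
    rng = np.random.default_rng(seed)
    u = (np.arange(n_genes) + 0.5) / n_genes
    k_target = (1 - u) ** (-1 / gamma)  # Pareto quantiles
    rho = np.clip((k_target / k_target.max()) ** (1 / beta), None, 0.98)
    corr = np.outer(rho, rho)
    np.fill_diagonal(corr, 1.0)
    z = rng.normal(size=(n_genes, n_samples))
    z -= z.mean(axis=1, keepdims=True)
    sample_cov = z @ z.T / (n_samples - 1)
    w, v = np.linalg.eigh(sample_cov)
    z_white = v @ np.diag(w**-0.5) @ v.T @ z
    x = np.linalg.cholesky(corr) @ z_white
    return fc.ExpressionMatrix(
        x, [f"g{i}" for i in range(n_genes)], [f"s{j}" for j in range(n_samples)]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def cpi_pair():
    return fc.cpi_definition().pair


@pytest.fixture
def bulk_with_modules():
    cfg = fc.BulkSimConfig(
        n_genes=450,
        planted_modules=((60, 0.85), (50, 0.85), (40, 0.85)),
        noise_sd=0.5,
        seed=7,
    )
    return fc.simulate_bulk(cfg)
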