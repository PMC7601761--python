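"""Shared fixtures: standard-design fits are expensive, so the ten-seed
battery is computed once per session and reused by the recovery,
significance and fit-diagnostic tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import phenomap as pm

STANDARD_SEEDS = tuple(range(1, 11))


def match_columns(W_est: np.ndarray, W_true: np.ndarray):
    """Best column matching (permutation + |corr|) of estimated loadings
    onto the truth; returns (per-column |corr| list, column permutation)."""
    q = W_true.shape[1]
    C = np.corrcoef(W_est.T, W_true.T)[:q, q:]
    rows, cols = linear_sum_assignment(-np.abs(C))
    corrs = [abs(C[i, j]) for i, j in zip(rows, cols)]
    return corrs, cols


@pytest.fixture(scope="session")
def standard_fits():
    """Aligned 4000-sweep fits of the standard synthetic design, seeds 1-10.

    Returns a dict seed -> (chain, summary, truth, expr, X).
    """
    out = {}
    for seed in STANDARD_SEEDS:
        expr, pheno, truth = pm.standard_design_dataset(seed=seed)
        X = pm.build_design_matrix(pheno)
        chain = pm.align_chain(pm.run_mcmc(
            expr, X, 3, pm.Hyperparameters(),
            pm.McmcConfig(n_iter=4000, burn_in=2000, thin=5, seed=seed)))
        summary = pm.summarize_posterior(chain, column_names=X.column_names)
        out[seed] = (chain, summary, truth, expr, X)
    return out


@pytest.fixture(scope="session")
def small_fit():
    """One quick aligned fit on a small synthetic dataset for API-level tests."""
    expr, pheno, truth = pm.simulate_dataset(p=80, n=50, q=2, c=2,
                                             n_active_covariates=1, seed=4)
    X = pm.build_design_matrix(pheno)
    chain = pm.align_chain(pm.run_mcmc(
        expr, X, 2, pm.Hyperparameters(),
        pm.McmcConfig(n_iter=3000, burn_in=1500, thin=3, seed=4)))
    summary = pm.summarize_posterior(chain, column_names=X.column_names)
    return chain, summary, truth, expr, X
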