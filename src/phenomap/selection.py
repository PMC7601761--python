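"""Choosing the number of CMVs and calling significant features/phenotypes.

Two routes select the number of latent CMVs:

* a regularized BIC grid search — ``BIC = 2*ll - C*log(n)`` with ``ll``
  the marginal log-likelihood at the maximum-a-posteriori draw (the MAP
  plug-in is the regularization) and ``C`` a parameter count; the
  highest BIC wins;
* a spike-and-slab fit at a single generous ``q_max`` whose per-column
  inclusion indicators count the active CMVs directly.

Significance of features and phenotypes is called from the scaled
posterior scores z = mean/SD: covariates at a 5% two-sided normal level
(|z| >= 1.96) and features at a much stricter 0.01% level (|z| >= 3.89)
by default, reflecting the very different numbers of tests involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import (
    Hyperparameters,
    McmcConfig,
    PosteriorChain,
    PosteriorSummary,
    align_chain,
    marginal_loglik,
    run_mcmc,
    summarize_posterior,
)

__all__ = [
    "BicTable",
    "SignificanceCall",
    "regularized_bic",
    "select_q",
    "spike_slab_effective_q",
    "column_inclusion_probabilities",
    "call_significance",
]

#: |z| above which a loading counts as an effective parameter in the BIC
EFFECTIVE_LOADING_Z = 2.0


def _child_seed(master: int, key: int) -> int:
    return int(np.random.SeedSequence([int(master), int(key)]).generate_state(1)[0] % (2 ** 31))


def regularized_bic(chain: PosteriorChain, Y, X, q: int, effective: bool = False) -> float:
    """Regularized BIC of a fitted chain: ``2*ll - C*log(n)``.

    ``ll`` is the marginal log-likelihood (U integrated out) evaluated at
    the maximum-a-posteriori draw — the regularization enters through the
    MAP plug-in rather than a maximum-likelihood estimate.  By default
    ``C`` is the full parameter count p*q + q*(c+1) + p + q.  With
    ``effective=True`` only loadings whose scaled score |z_W| >= 2 are
    charged (ARD-shrunk loadings cost nothing); this count is reported
    alongside the default in :class:`BicTable` but under-penalizes
    surplus CMV columns, which improve the plug-in likelihood by fitting
    noise without producing stable loadings, so it is not the default.
    """
    if chain.n_draws == 0:
        raise ValueError("empty chain")
    from .model import _as_design, _as_matrix

    Ym, Xm = _as_matrix(Y), _as_design(X)
    p, n = Ym.shape
    l = Xm.shape[1]
    s = chain.map_index()
    ll = marginal_loglik(Ym, Xm, chain.W[s], chain.Beta[s], chain.sigma2[s], chain.phi2[s])
    if effective:
        summary = summarize_posterior(chain if chain.aligned else align_chain(chain))
        with np.errstate(invalid="ignore"):
            n_loadings = int((np.abs(np.nan_to_num(summary.z_W)) >= EFFECTIVE_LOADING_Z).sum())
    else:
        n_loadings = p * q
    C = n_loadings + q * l + p + q
    return float(2.0 * ll - C * np.log(n))


@dataclass
class BicTable:
    """Regularized-BIC grid search results."""

    q_grid: list[int]
    bic: np.ndarray
    bic_effective: np.ndarray
    map_log_posterior: np.ndarray
    selected_q: int
    chains: dict[int, PosteriorChain] = field(default_factory=dict, repr=False)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "q": self.q_grid,
            "bic": self.bic,
            "bic_effective": self.bic_effective,
            "map_log_posterior": self.map_log_posterior,
            "selected": [q == self.selected_q for q in self.q_grid],
        })


def select_q(Y, X, q_grid, hyper: Hyperparameters | None = None,
             mcmc: McmcConfig | None = None, keep_chains: bool = True) -> BicTable:
    """Fit the model at every q in the grid and pick the BIC maximizer.

    Each q gets an independent seed derived from the master seed; ties
    are broken toward smaller q.
    """
    q_grid = sorted(set(int(q) for q in q_grid))
    if not q_grid:
        raise ValueError("empty q grid")
    hyper = hyper or Hyperparameters()
    mcmc = mcmc or McmcConfig()
    bics, bics_effective, lps = [], [], []
    chains: dict[int, PosteriorChain] = {}
    for q in q_grid:
        cfg = McmcConfig(n_iter=mcmc.n_iter, burn_in=mcmc.burn_in, thin=mcmc.thin,
                         seed=_child_seed(mcmc.seed, q))
        try:
            chain = run_mcmc(Y, X, q, hyper, cfg)
        except Exception as err:
            raise RuntimeError(f"model fit failed at q={q}: {err}") from err
        chain = align_chain(chain)
        bics.append(regularized_bic(chain, Y, X, q))
        bics_effective.append(regularized_bic(chain, Y, X, q, effective=True))
        lps.append(float(chain.log_posterior[chain.map_index()]))
        if keep_chains:
            chains[q] = chain
    bics_arr = np.asarray(bics)
    selected = q_grid[int(np.argmax(bics_arr))]  # argmax returns first (smallest q) on ties
    return BicTable(q_grid=q_grid, bic=bics_arr, bic_effective=np.asarray(bics_effective),
                    map_log_posterior=np.asarray(lps), selected_q=selected, chains=chains)


def column_inclusion_probabilities(chain: PosteriorChain) -> np.ndarray:
    """Posterior probability that each CMV column sits in the slab."""
    if chain.gamma is None:
        raise ValueError("chain has no inclusion indicators; fit with mode='spike_slab'")
    return chain.gamma.mean(axis=0)


def spike_slab_effective_q(Y, X, q_max: int, hyper: Hyperparameters | None = None,
                           mcmc: McmcConfig | None = None) -> int:
    """Automatic CMV-count selection via column-wise spike-and-slab.

    Fits once at ``q_max`` with per-column inclusion indicators; a column
    is active when its posterior inclusion probability is >= 0.5.
    """
    hyper = hyper or Hyperparameters()
    if hyper.mode != "spike_slab":
        hyper = Hyperparameters(**{**hyper.__dict__, "mode": "spike_slab"})
    mcmc = mcmc or McmcConfig()
    chain = run_mcmc(Y, X, q_max, hyper, mcmc)
    pip = column_inclusion_probabilities(chain)
    return int((pip >= 0.5).sum())


# ---------------------------------------------------------------------------
# significance calling
# ---------------------------------------------------------------------------

@dataclass
class SignificanceCall:
    """Feature-CMV and covariate-CMV pairs passing their |z| thresholds."""

    feature_calls: pd.DataFrame     # columns: feature, cmv, z, mean, sign
    covariate_calls: pd.DataFrame   # columns: covariate, cmv, z, mean, sign
    feature_threshold: float
    covariate_threshold: float
    n_undefined: int

    def significant_features(self, cmv: int) -> list[str]:
        sub = self.feature_calls[self.feature_calls["cmv"] == cmv]
        return list(sub["feature"])

    def significant_covariates(self, cmv: int) -> list[str]:
        sub = self.covariate_calls[self.covariate_calls["cmv"] == cmv]
        return list(sub["covariate"])


def _bh_keep(z: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg keep-mask over two-sided normal p-values."""
    pvals = 2.0 * norm.sf(np.abs(z))
    m = len(pvals)
    order = np.argsort(pvals)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = pvals[order] <= thresh
    keep = np.zeros(m, dtype=bool)
    if passed.any():
        kmax = np.max(np.flatnonzero(passed))
        keep[order[: kmax + 1]] = True
    return keep


def call_significance(
    summary: PosteriorSummary,
    alpha_features: float = 1e-4,
    alpha_covariates: float = 0.05,
    feature_ids: list[str] | None = None,
    covariate_names: list[str] | None = None,
    adjust: str = "none",
) -> SignificanceCall:
    """Call significant feature-CMV and covariate-CMV associations.

    Scaled scores are treated as standard-normal pivots: an entry is
    called when |z| >= the two-sided normal quantile of its alpha
    (defaults: 5% for phenotypes -> 1.96, 0.01% for features -> 3.89).
    The intercept column is never reported as a phenotype.  Entries with
    undefined z (posterior SD below tolerance) are excluded and counted.
    ``adjust='bh'`` applies a Benjamini-Hochberg layer instead of the raw
    thresholds (off by default).
    """
    p, q = summary.z_W.shape
    l = summary.z_Beta.shape[1]
    feature_ids = feature_ids or [f"feature{j + 1}" for j in range(p)]
    covariate_names = covariate_names or (
        summary.column_names or ["intercept"] + [f"covariate{k}" for k in range(1, l)]
    )
    thr_f = float(norm.ppf(1.0 - alpha_features / 2.0))
    thr_c = float(norm.ppf(1.0 - alpha_covariates / 2.0))

    n_undefined = int((~summary.W_defined).sum() + (~summary.Beta_defined[:, 1:]).sum())

    def _calls(z, mean, defined, names_axis0, axis0_label, thr, alpha):
        rows = []
        zf = np.where(defined, z, 0.0)
        if adjust == "bh":
            keep = np.zeros_like(defined)
            flat = defined.ravel()
            if flat.any():
                keep_flat = np.zeros(flat.size, dtype=bool)
                keep_flat[flat] = _bh_keep(zf.ravel()[flat], alpha)
                keep = keep_flat.reshape(defined.shape)
        elif adjust == "none":
            keep = defined & (np.abs(zf) >= thr)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        for i, k in zip(*np.nonzero(keep)):
            rows.append({axis0_label: names_axis0[i], "cmv": int(k),
                         "z": float(z[i, k]), "mean": float(mean[i, k]),
                         "sign": int(np.sign(mean[i, k]))})
        return rows

    feat_rows = _calls(summary.z_W, summary.W_mean, summary.W_defined,
                       feature_ids, "feature", thr_f, alpha_features)
    feature_calls = pd.DataFrame(feat_rows, columns=["feature", "cmv", "z", "mean", "sign"])

    # covariates: z_Beta is (q, l); transpose view so axis 0 indexes covariates
    zB = summary.z_Beta[:, 1:].T
    mB = summary.Beta_mean[:, 1:].T
    dB = summary.Beta_defined[:, 1:].T
    cov_names = [covariate_names[k] for k in range(1, l)]
    cov_rows = _calls(zB, mB, dB, cov_names, "covariate", thr_c, alpha_covariates)
    covariate_calls = pd.DataFrame(cov_rows, columns=["covariate", "cmv", "z", "mean", "sign"])
    return SignificanceCall(
        feature_calls=feature_calls, covariate_calls=covariate_calls,
        feature_threshold=thr_f, covariate_threshold=thr_c, n_undefined=n_undefined,
    )
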