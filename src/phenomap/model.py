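"""Bayesian joint factor-regression model and its Gibbs sampler.

The model maps a features x samples omics matrix ``Y`` and a sample
covariate design ``X`` onto ``q`` latent context-specific mapping
variables (CMVs)::

    y_i = W u_i + xi_i,      xi_i ~ N_p(0, Sigma),  Sigma = diag(sigma_1^2..sigma_p^2)
    u_i = Beta x_i + eps_i,  eps_i ~ N_q(0, Phi),   Phi   = diag(phi_1^2..phi_q^2)

with sparsity-inducing priors: an automatic relevance determination (ARD)
prior on each loading, ``w_jk ~ N(0, 1/lambda_jk)`` with
``lambda_jk ~ Gamma(a, b)``, and a Zellner g-prior on each row of the
regression coefficients, ``beta_k ~ MVN(0, g * phi_k^2 * (X'X)^-1)``.
Observation and CMV precisions carry gamma priors (equivalently,
inverse-gamma priors on the variances).

An alternative spike-and-slab mode places a two-component Gaussian
mixture on whole loading columns (one inclusion indicator per CMV) to
switch CMVs on or off, which is used for automatic selection of the
number of CMVs.

All full conditionals are conjugate; :func:`gibbs_sweep` performs one
cycle in the order U, Lambda, W, Sigma, Beta, Phi.  The individual
conditional draws are exposed as module-level ``draw_*`` functions so
that validation code (joint-distribution "getting it right" checks,
restricted samplers checked against quadrature) can exercise exactly the
same code paths.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict, replace
from typing import Literal

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .data_io import DesignMatrix, ExpressionMatrix

__all__ = [
    "Hyperparameters",
    "ModelState",
    "McmcConfig",
    "PosteriorChain",
    "PosteriorSummary",
    "initialize_state",
    "gibbs_sweep",
    "run_mcmc",
    "align_chain",
    "summarize_posterior",
    "marginal_loglik",
    "log_posterior",
    "save_chain",
    "load_chain",
]

VAR_FLOOR = 1e-12  # hard floor for all variance draws
Z_SD_TOL = 1e-10   # below this posterior SD a z-score is undefined


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters.

    ``a, b``: ARD gamma shape/rate on loading precisions.  The default
    a = b = 1 gives each loading a unit-scale Student-t(2) marginal; this
    carries the scale information that identifies the W-vs-U scale split
    (a scale-free choice such as a = b = 0.01 lets the chain drift along
    the (W*c, U/c) orbit, which distorts the Beta conditional through
    the phi2 prior once U collapses).
    ``a_sigma, b_sigma`` / ``a_phi, b_phi``: gamma shape/rate on
    observation / CMV precisions (inverse-gamma on the variances).
    ``g``: g-prior scale; ``None`` means the unit-information choice g = n.
    ``v0, v1, inclusion_prob``: spike/slab variances and the prior
    column-inclusion probability, used only in ``mode='spike_slab'``.
    """

    a: float = 1.0
    b: float = 1.0
    a_sigma: float = 0.01
    b_sigma: float = 0.01
    a_phi: float = 0.01
    b_phi: float = 0.01
    g: float | None = None
    v0: float = 0.005
    v1: float = 1.0
    inclusion_prob: float = 0.5
    mode: Literal["ard", "spike_slab"] = "ard"

    def __post_init__(self) -> None:
        for name in ("a", "b", "a_sigma", "b_sigma", "a_phi", "b_phi", "v0", "v1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be positive")
        if self.g is not None and self.g <= 0:
            raise ValueError("g must be positive")
        if not self.v0 < self.v1:
            raise ValueError("spike variance v0 must be smaller than slab variance v1")
        if not 0 < self.inclusion_prob < 1:
            raise ValueError("inclusion_prob must lie in (0, 1)")

    def resolve_g(self, n: int) -> float:
        return float(n) if self.g is None else float(self.g)


@dataclass
class ModelState:
    """One complete parameter configuration of the model."""

    W: np.ndarray        # (p, q) loadings
    U: np.ndarray        # (q, n) CMV scores
    Beta: np.ndarray     # (q, l) regression coefficients, l = c+1
    sigma2: np.ndarray   # (p,) observation variances
    phi2: np.ndarray     # (q,) CMV variances
    Lambda: np.ndarray   # (p, q) ARD precisions
    gamma: np.ndarray | None = None  # (q,) column inclusion indicators (spike-slab)

    def __post_init__(self) -> None:
        p, q = self.W.shape
        if self.U.shape[0] != q or self.Beta.shape[0] != q:
            raise ValueError("inconsistent q across W, U, Beta")
        if self.sigma2.shape != (p,) or self.phi2.shape != (q,) or self.Lambda.shape != (p, q):
            raise ValueError("inconsistent variance/precision shapes")
        if (self.sigma2 <= 0).any() or (self.phi2 <= 0).any() or (self.Lambda <= 0).any():
            raise ValueError("variances and ARD precisions must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        p, q = self.W.shape
        return p, self.U.shape[1], q, self.Beta.shape[1]

    def copy(self) -> "ModelState":
        return ModelState(
            W=self.W.copy(), U=self.U.copy(), Beta=self.Beta.copy(),
            sigma2=self.sigma2.copy(), phi2=self.phi2.copy(), Lambda=self.Lambda.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
        )


@dataclass(frozen=True)
class McmcConfig:
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorChain:
    """Retained Gibbs draws, stored as stacked arrays indexed by draw."""

    W: np.ndarray        # (S, p, q)
    U: np.ndarray        # (S, q, n)
    Beta: np.ndarray     # (S, q, l)
    sigma2: np.ndarray   # (S, p)
    phi2: np.ndarray     # (S, q)
    Lambda: np.ndarray   # (S, p, q)
    log_posterior: np.ndarray  # (S,)
    config: McmcConfig
    gamma: np.ndarray | None = None  # (S, q)
    aligned: bool = False

    @property
    def n_draws(self) -> int:
        return self.W.shape[0]

    def draw(self, s: int) -> ModelState:
        return ModelState(
            W=self.W[s], U=self.U[s], Beta=self.Beta[s],
            sigma2=self.sigma2[s], phi2=self.phi2[s], Lambda=self.Lambda[s],
            gamma=None if self.gamma is None else self.gamma[s],
        )

    def map_index(self) -> int:
        """Index of the maximum-a-posteriori draw."""
        return int(np.argmax(self.log_posterior))


@dataclass
class PosteriorSummary:
    """Elementwise posterior means, SDs and scaled scores (z = mean/SD).

    z entries where the posterior SD is below tolerance are NaN and the
    matching ``*_defined`` mask is False.
    """

    W_mean: np.ndarray
    W_sd: np.ndarray
    z_W: np.ndarray
    W_defined: np.ndarray
    Beta_mean: np.ndarray
    Beta_sd: np.ndarray
    z_Beta: np.ndarray
    Beta_defined: np.ndarray
    U_mean: np.ndarray
    U_sd: np.ndarray
    column_names: list[str] | None = None


# ---------------------------------------------------------------------------
# conditional draws (one Gibbs step each)
# ---------------------------------------------------------------------------

def _chol_with_jitter(A: np.ndarray):
    """Cholesky with escalating diagonal jitter (1e-10 -> 1e-6)."""
    if not np.isfinite(A).all():
        raise FloatingPointError("non-finite conditional precision matrix")
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError("conditional covariance not positive definite even with jitter")


def draw_cmvs(Y, X, W, Beta, sigma2, phi2, rng) -> np.ndarray:
    """U | rest: Gaussian with shared precision W'S^-1 W + Phi^-1."""
    q = W.shape[1]
    Ws = W / sigma2[:, None]                      # Sigma^-1 W
    P = W.T @ Ws + np.diag(1.0 / phi2)            # (q, q)
    B = Ws.T @ Y + (Beta @ X.T) / phi2[:, None]   # (q, n)
    c, low = _chol_with_jitter(P)
    M = cho_solve((c, low), B)
    Z = rng.standard_normal(B.shape)
    return M + solve_triangular(c, Z, lower=True, trans="T")


def draw_ard_precisions(W, a, b, rng) -> np.ndarray:
    """lambda_jk | w_jk ~ Gamma(a + 1/2, b + w_jk^2/2)."""
    rate = b + 0.5 * W ** 2
    return np.maximum(rng.gamma(a + 0.5, 1.0 / rate), VAR_FLOOR)


def draw_loadings(Y, U, sigma2, prior_prec, rng) -> np.ndarray:
    """W | rest, row-wise Gaussian; ``prior_prec`` is the (p, q) matrix of
    per-element prior precisions (ARD Lambda, or spike/slab precisions)."""
    p = Y.shape[0]
    q = U.shape[0]
    UUt = U @ U.T                                          # (q, q)
    P = UUt[None, :, :] / sigma2[:, None, None]            # (p, q, q)
    P = P + np.einsum("pq,qr->pqr", prior_prec, np.eye(q))
    B = (U @ Y.T).T / sigma2[:, None]                      # (p, q)
    try:
        L = np.linalg.cholesky(P)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(P + 1e-8 * np.eye(q)[None])
    mean = np.linalg.solve(P, B[:, :, None])               # (p, q, 1)
    Z = rng.standard_normal((p, q, 1))
    dev = np.linalg.solve(np.transpose(L, (0, 2, 1)), Z)
    return (mean + dev)[:, :, 0]


def draw_noise_variances(Y, W, U, a_sigma, b_sigma, rng) -> np.ndarray:
    """sigma_j^2 | rest ~ InvGamma(a_sigma + n/2, b_sigma + RSS_j/2)."""
    n = Y.shape[1]
    rss = ((Y - W @ U) ** 2).sum(axis=1)
    shape = a_sigma + 0.5 * n
    rate = b_sigma + 0.5 * rss
    return np.maximum(1.0 / rng.gamma(shape, 1.0 / rate), VAR_FLOOR)


def draw_coefficients(U, X, phi2, g, rng) -> np.ndarray:
    """beta_k | rest: Gaussian shrunk toward 0 by g/(g+1) around the
    least-squares fit of u_k. on X, covariance (g/(g+1)) phi_k^2 (X'X)^-1."""
    XtX = X.T @ X
    shrink = g / (g + 1.0)
    c, low = _chol_with_jitter(XtX)
    Bhat = cho_solve((c, low), X.T @ U.T)                  # (l, q)
    mean = shrink * Bhat.T                                  # (q, l)
    Z = rng.standard_normal((X.shape[1], U.shape[0]))       # (l, q)
    dev = solve_triangular(c, Z, lower=True, trans="T")     # (X'X)^-1/2 z
    return mean + (np.sqrt(shrink * phi2)[:, None]) * dev.T


def draw_cmv_variances(U, X, Beta, g, a_phi, b_phi, rng) -> np.ndarray:
    """phi_k^2 | rest: inverse-gamma absorbing the CMV residuals and the
    g-prior quadratic form beta_k' X'X beta_k / g."""
    n, l = X.shape
    resid = U - Beta @ X.T
    XtX = X.T @ X
    quad = np.einsum("kl,lm,km->k", Beta, XtX, Beta)
    shape = a_phi + 0.5 * (n + l)
    rate = b_phi + 0.5 * (resid ** 2).sum(axis=1) + quad / (2.0 * g)
    return np.maximum(1.0 / rng.gamma(shape, 1.0 / rate), VAR_FLOOR)


def draw_column_indicators(Y, W, U, sigma2, hyper: Hyperparameters, rng):
    """Spike-and-slab: jointly refresh (gamma_k, W column k) for each CMV.

    The indicator is drawn with the column's loadings integrated out
    (conditional on U, Sigma and the other columns), which lets columns
    escape the spike; the column is then redrawn under the chosen
    component.  Returns (gamma, W).
    """
    p, q = W.shape
    W = W.copy()
    gamma = np.zeros(q, dtype=int)
    logit_pi = np.log(hyper.inclusion_prob) - np.log1p(-hyper.inclusion_prob)
    for k in range(q):
        others = [j for j in range(q) if j != k]
        R = Y - W[:, others] @ U[others, :]                 # (p, n)
        u = U[k]
        s = float(u @ u)
        b_j = (R @ u) / sigma2                              # (p,)
        prec_data = s / sigma2                              # (p,)

        def log_marg(v: float) -> float:
            post_prec = prec_data + 1.0 / v
            return float(0.5 * (-np.log(v) - np.log(post_prec) + b_j ** 2 / post_prec).sum())

        log_odds = logit_pi + log_marg(hyper.v1) - log_marg(hyper.v0)
        active = rng.random() < 1.0 / (1.0 + np.exp(-np.clip(log_odds, -500, 500)))
        gamma[k] = int(active)
        v = hyper.v1 if active else hyper.v0
        post_prec = prec_data + 1.0 / v
        mean = b_j / post_prec
        W[:, k] = mean + rng.standard_normal(p) / np.sqrt(post_prec)
    return gamma, W


# ---------------------------------------------------------------------------
# sampler driver
# ---------------------------------------------------------------------------

def _as_matrix(Y) -> np.ndarray:
    return Y.values if isinstance(Y, ExpressionMatrix) else np.asarray(Y, dtype=float)


def _as_design(X) -> np.ndarray:
    return X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)


def initialize_state(Y, X, q: int, seed: int = 0) -> ModelState:
    """Deterministic (given seed) initialization from the top-q principal
    directions of Y, with least-squares Beta and moment-based variances."""
    Ym, Xm = _as_matrix(Y), _as_design(X)
    p, n = Ym.shape
    if not 1 <= q < min(p, n):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(p, n) = {min(p, n)}")
    rng = np.random.default_rng(seed)
    A, s, Bt = np.linalg.svd(Ym, full_matrices=False)
    W = A[:, :q] * (s[:q] / np.sqrt(n))
    U = np.sqrt(n) * Bt[:q, :]
    W = W + 0.01 * rng.standard_normal(W.shape)
    XtX = Xm.T @ Xm
    Beta = np.linalg.solve(XtX, Xm.T @ U.T).T
    sigma2 = np.maximum(((Ym - W @ U) ** 2).mean(axis=1), 1e-6)
    phi2 = np.maximum(((U - Beta @ Xm.T) ** 2).mean(axis=1), 1e-6)
    Lambda = np.ones((p, q))
    return ModelState(W=W, U=U, Beta=Beta, sigma2=sigma2, phi2=phi2, Lambda=Lambda,
                      gamma=np.ones(q, dtype=int))


def gibbs_sweep(state: ModelState, Y, X, hyper: Hyperparameters, rng) -> ModelState:
    """One full cycle of the six conditional draws (U, Lambda, W, Sigma, Beta, Phi)."""
    Ym, Xm = _as_matrix(Y), _as_design(X)
    n = Ym.shape[1]
    g = hyper.resolve_g(n)

    def _checked(name, fn):
        try:
            arr = fn()
        except FloatingPointError as err:
            raise FloatingPointError(f"parameter {name}: {err}") from err
        except ValueError as err:
            # scipy's own finiteness checks surface as ValueError
            if "inf" in str(err).lower() or "nan" in str(err).lower():
                raise FloatingPointError(f"parameter {name}: {err}") from err
            raise
        if not np.isfinite(arr).all():
            raise FloatingPointError(f"non-finite draw in parameter {name}")
        return arr

    U = _checked("U", lambda: draw_cmvs(Ym, Xm, state.W, state.Beta,
                                        state.sigma2, state.phi2, rng))
    if hyper.mode == "spike_slab":
        Lambda = state.Lambda
        gamma, W = draw_column_indicators(Ym, state.W, U, state.sigma2, hyper, rng)
        _checked("W", lambda: W)
    else:
        Lambda = _checked("Lambda", lambda: draw_ard_precisions(state.W, hyper.a, hyper.b, rng))
        W = _checked("W", lambda: draw_loadings(Ym, U, state.sigma2, Lambda, rng))
        gamma = state.gamma
    sigma2 = _checked("sigma2", lambda: draw_noise_variances(Ym, W, U, hyper.a_sigma,
                                                             hyper.b_sigma, rng))
    Beta = _checked("Beta", lambda: draw_coefficients(U, Xm, state.phi2, g, rng))
    phi2 = _checked("phi2", lambda: draw_cmv_variances(U, Xm, Beta, g, hyper.a_phi,
                                                       hyper.b_phi, rng))
    return ModelState(W=W, U=U, Beta=Beta, sigma2=sigma2, phi2=phi2, Lambda=Lambda, gamma=gamma)


def run_mcmc(Y, X, q: int, hyper: Hyperparameters | None = None,
             mcmc: McmcConfig | None = None) -> PosteriorChain:
    """Run the Gibbs sampler; returns the thinned post-burn-in chain.

    Fixed seed implies a bit-identical chain.
    """
    hyper = hyper or Hyperparameters()
    mcmc = mcmc or McmcConfig()
    Ym, Xm = _as_matrix(Y), _as_design(X)
    rng = np.random.default_rng(mcmc.seed)
    state = initialize_state(Ym, Xm, q, seed=mcmc.seed)

    S = mcmc.n_retained
    p, n = Ym.shape
    l = Xm.shape[1]
    out = PosteriorChain(
        W=np.empty((S, p, q)), U=np.empty((S, q, n)), Beta=np.empty((S, q, l)),
        sigma2=np.empty((S, p)), phi2=np.empty((S, q)), Lambda=np.empty((S, p, q)),
        log_posterior=np.empty(S), config=mcmc,
        gamma=np.empty((S, q), dtype=int) if hyper.mode == "spike_slab" else None,
    )
    kept = 0
    for sweep in range(mcmc.n_iter):
        try:
            state = gibbs_sweep(state, Ym, Xm, hyper, rng)
        except FloatingPointError as err:
            raise FloatingPointError(f"sweep {sweep}: {err}") from err
        if sweep >= mcmc.burn_in and (sweep - mcmc.burn_in) % mcmc.thin == 0:
            out.W[kept] = state.W
            out.U[kept] = state.U
            out.Beta[kept] = state.Beta
            out.sigma2[kept] = state.sigma2
            out.phi2[kept] = state.phi2
            out.Lambda[kept] = state.Lambda
            if out.gamma is not None:
                out.gamma[kept] = state.gamma
            out.log_posterior[kept] = log_posterior(state, Ym, Xm, hyper)
            kept += 1
    return out


# ---------------------------------------------------------------------------
# identifiability: sign/permutation alignment across draws
# ---------------------------------------------------------------------------

def _greedy_match(ref: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy max-|correlation| matching of W's columns onto ref's columns.

    Returns (perm, signs) such that W[:, perm] * signs best matches ref.
    """
    q = ref.shape[1]
    C = np.nan_to_num(np.corrcoef(ref.T, W.T)[:q, q:])
    perm = np.empty(q, dtype=int)
    signs = np.empty(q)
    absC = np.abs(C).copy()
    for _ in range(q):
        k, j = np.unravel_index(np.argmax(absC), absC.shape)
        perm[k] = j
        signs[k] = 1.0 if C[k, j] >= 0 else -1.0
        absC[k, :] = -1.0
        absC[:, j] = -1.0
    return perm, signs


def align_chain(chain: PosteriorChain) -> PosteriorChain:
    """Resolve column permutation/sign and scale non-identifiability.

    The likelihood is invariant under permuting CMVs, flipping the sign
    of a CMV (in W, U and Beta together), and rescaling a CMV by c
    (W*c, U/c); a Gibbs chain therefore wanders over these orbits, which
    would corrupt elementwise summaries.  Each draw is mapped to a
    canonical representative: CMV columns are greedily matched to the
    maximum-a-posteriori draw by absolute loading correlation (reference
    columns ordered by decreasing explained variance of Y, signed so each
    column's largest-magnitude loading is positive), then rescaled so
    every CMV has unit standard deviation across samples.  All reported
    quantities (scaled scores, marginal likelihood, clustering inputs)
    are functions of these scale-invariant representatives.
    Aligning an already-aligned chain is a no-op.
    """
    if chain.n_draws == 0:
        raise ValueError("cannot align an empty chain")
    ref_idx = chain.map_index()
    refW = chain.W[ref_idx].copy()
    # order reference columns by explained variance of Y
    expl = (refW ** 2).sum(axis=0) * chain.U[ref_idx].var(axis=1)
    order = np.argsort(-expl, kind="stable")
    refW = refW[:, order]
    ref_sign = np.sign(refW[np.argmax(np.abs(refW), axis=0), np.arange(refW.shape[1])])
    ref_sign[ref_sign == 0] = 1.0
    refW = refW * ref_sign

    out = PosteriorChain(
        W=chain.W.copy(), U=chain.U.copy(), Beta=chain.Beta.copy(),
        sigma2=chain.sigma2.copy(), phi2=chain.phi2.copy(), Lambda=chain.Lambda.copy(),
        log_posterior=chain.log_posterior.copy(), config=chain.config,
        gamma=None if chain.gamma is None else chain.gamma.copy(), aligned=True,
    )
    for s in range(chain.n_draws):
        perm, signs = _greedy_match(refW, chain.W[s])
        out.W[s] = chain.W[s][:, perm] * signs
        out.U[s] = chain.U[s][perm, :] * signs[:, None]
        out.Beta[s] = chain.Beta[s][perm, :] * signs[:, None]
        out.phi2[s] = chain.phi2[s][perm]
        out.Lambda[s] = chain.Lambda[s][:, perm]
        if out.gamma is not None:
            out.gamma[s] = chain.gamma[s][perm]
        # canonical scale: unit SD per CMV across samples
        c = out.U[s].std(axis=1)
        c = np.where(c > 0, c, 1.0)
        out.W[s] *= c
        out.U[s] /= c[:, None]
        out.Beta[s] /= c[:, None]
        out.phi2[s] /= c ** 2
        out.Lambda[s] /= c ** 2
    return out


def summarize_posterior(chain: PosteriorChain, column_names: list[str] | None = None) -> PosteriorSummary:
    """Elementwise posterior means, SDs and scaled scores over an aligned chain."""
    if not chain.aligned:
        raise ValueError("summarize_posterior requires an aligned chain (run align_chain first)")
    if chain.n_draws < 10:
        raise ValueError(f"need >= 10 retained draws, got {chain.n_draws}")

    def _msz(A):
        mean = A.mean(axis=0)
        sd = A.std(axis=0, ddof=1)
        defined = sd > Z_SD_TOL
        z = np.full(mean.shape, np.nan)
        np.divide(mean, sd, out=z, where=defined)
        return mean, sd, z, defined

    W_mean, W_sd, z_W, W_def = _msz(chain.W)
    B_mean, B_sd, z_B, B_def = _msz(chain.Beta)
    U_mean = chain.U.mean(axis=0)
    U_sd = chain.U.std(axis=0, ddof=1)
    return PosteriorSummary(
        W_mean=W_mean, W_sd=W_sd, z_W=z_W, W_defined=W_def,
        Beta_mean=B_mean, Beta_sd=B_sd, z_Beta=z_B, Beta_defined=B_def,
        U_mean=U_mean, U_sd=U_sd, column_names=column_names,
    )


# ---------------------------------------------------------------------------
# likelihood / posterior density evaluation
# ---------------------------------------------------------------------------

def marginal_loglik(Y, X, W, Beta, sigma2, phi2) -> float:
    """Marginal log-likelihood with U integrated out:

    y_i ~ MVN(W Beta x_i, W Phi W' + Sigma), evaluated via the Woodbury
    identity / matrix determinant lemma so only q x q factorizations are
    needed.
    """
    Ym, Xm = _as_matrix(Y), _as_design(X)
    p, n = Ym.shape
    q = W.shape[1]
    if (np.asarray(sigma2) <= 0).any() or (np.asarray(phi2) <= 0).any():
        raise ValueError("variances must be positive")
    R = Ym - W @ (Beta @ Xm.T)                       # residuals (p, n)
    Ws = W / sigma2[:, None]
    K = np.diag(1.0 / phi2) + W.T @ Ws               # (q, q)
    c, low = _chol_with_jitter(K)
    A = Ws.T @ R                                     # (q, n)
    quad = (R * R / sigma2[:, None]).sum() - (A * cho_solve((c, low), A)).sum()
    logdet = (np.log(sigma2).sum() + np.log(phi2).sum()
              + 2.0 * np.log(np.diag(c)).sum())
    return float(-0.5 * (n * p * np.log(2.0 * np.pi) + n * logdet + quad))


def _log_invgamma(x, shape, rate):
    from scipy.special import gammaln
    return shape * np.log(rate) - gammaln(shape) - (shape + 1) * np.log(x) - rate / x


def log_posterior(state: ModelState, Y, X, hyper: Hyperparameters) -> float:
    """Complete-data log joint density (likelihood of Eqs for Y and U plus
    all log-priors), up to a constant shared by states of equal dimension."""
    Ym, Xm = _as_matrix(Y), _as_design(X)
    p, n = Ym.shape
    q = state.W.shape[1]
    l = Xm.shape[1]
    g = hyper.resolve_g(n)
    W, U, Beta = state.W, state.U, state.Beta
    sigma2, phi2, Lam = state.sigma2, state.phi2, state.Lambda

    Robs = Ym - W @ U
    ll_y = -0.5 * (n * np.log(2 * np.pi * sigma2).sum()
                   + (Robs ** 2 / sigma2[:, None]).sum())
    Rcmv = U - Beta @ Xm.T
    ll_u = -0.5 * (n * np.log(2 * np.pi * phi2).sum()
                   + (Rcmv ** 2 / phi2[:, None]).sum())

    if hyper.mode == "spike_slab":
        gam = state.gamma if state.gamma is not None else np.ones(q, dtype=int)
        v = np.where(gam > 0, hyper.v1, hyper.v0)
        lp_W = -0.5 * (p * np.log(2 * np.pi * v).sum() + (W ** 2 / v[None, :]).sum())
        lp_W += (gam * np.log(hyper.inclusion_prob)
                 + (1 - gam) * np.log1p(-hyper.inclusion_prob)).sum()
        lp_Lam = 0.0
    else:
        from scipy.special import gammaln

        lp_W = 0.5 * (np.log(Lam) - np.log(2 * np.pi) - Lam * W ** 2).sum()
        lp_Lam = ((hyper.a - 1) * np.log(Lam) - hyper.b * Lam).sum() \
            + p * q * (hyper.a * np.log(hyper.b) - float(gammaln(hyper.a)))

    XtX = Xm.T @ Xm
    sign, logdet_XtX = np.linalg.slogdet(XtX)
    quad = np.einsum("kl,lm,km->k", Beta, XtX, Beta)
    lp_beta = float(
        -0.5 * q * l * np.log(2 * np.pi)
        - 0.5 * (l * np.log(g * phi2)).sum()
        + 0.5 * q * logdet_XtX
        - 0.5 * (quad / (g * phi2)).sum()
    )
    lp_sigma = _log_invgamma(sigma2, hyper.a_sigma, hyper.b_sigma).sum()
    lp_phi = _log_invgamma(phi2, hyper.a_phi, hyper.b_phi).sum()
    return float(ll_y + ll_u + lp_W + lp_Lam + lp_beta + lp_sigma + lp_phi)


# ---------------------------------------------------------------------------
# chain persistence
# ---------------------------------------------------------------------------

def save_chain(chain: PosteriorChain, directory: str, extra_manifest: dict | None = None) -> None:
    """Serialize a chain as named numeric arrays plus a JSON manifest."""
    os.makedirs(directory, exist_ok=True)
    arrays = dict(W=chain.W, U=chain.U, Beta=chain.Beta, sigma2=chain.sigma2,
                  phi2=chain.phi2, Lambda=chain.Lambda, log_posterior=chain.log_posterior)
    if chain.gamma is not None:
        arrays["gamma"] = chain.gamma
    np.savez_compressed(os.path.join(directory, "chain.npz"), **arrays)
    S, p, q = chain.W.shape
    manifest = {
        "p": p, "n": int(chain.U.shape[2]), "q": q, "l": int(chain.Beta.shape[2]),
        "n_draws": S, "aligned": chain.aligned, "config": asdict(chain.config),
    }
    manifest.update(extra_manifest or {})
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_chain(directory: str) -> PosteriorChain:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    data = np.load(os.path.join(directory, "chain.npz"))
    return PosteriorChain(
        W=data["W"], U=data["U"], Beta=data["Beta"], sigma2=data["sigma2"],
        phi2=data["phi2"], Lambda=data["Lambda"], log_posterior=data["log_posterior"],
        config=McmcConfig(**manifest["config"]),
        gamma=data["gamma"] if "gamma" in data.files else None,
        aligned=bool(manifest.get("aligned", False)),
    )
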