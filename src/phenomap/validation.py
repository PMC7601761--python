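"""Model-faithful synthetic data and sampler/fit diagnostics.

Three kinds of checks live here:

* :func:`simulate_dataset` draws data exactly from the generative model
  (sparse loadings, active/inactive covariates, heteroscedastic noise,
  optional planted sample clusters) with the full truth recorded, so
  recovery can be measured.
* :func:`getting_it_right_check` is a joint-distribution test of the
  Gibbs sampler: it compares marginal-conditional simulation (parameters
  from the prior, data from the model) against successive-conditional
  simulation (alternating Gibbs sweeps and data redraws).  If every full
  conditional is correct the two simulators share the same distribution,
  so z-statistics of monitored moments stay small; an incorrect
  conditional shows up as a large |z|.
* :func:`posterior_predictive_mad` and :func:`trace_summary` are the
  model-fit and convergence diagnostics: the mean absolute deviation
  between observed and replicate feature-feature covariances, and
  windowed trace summaries with a split-half statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import Covariate, ExpressionMatrix, PhenotypeTable
from .model import (
    Hyperparameters,
    ModelState,
    PosteriorChain,
    draw_ard_precisions,
    draw_cmv_variances,
    draw_cmvs,
    draw_coefficients,
    draw_column_indicators,
    draw_loadings,
    draw_noise_variances,
    gibbs_sweep,
)

__all__ = [
    "SyntheticTruth",
    "STANDARD_DESIGN",
    "simulate_dataset",
    "standard_design_dataset",
    "getting_it_right_check",
    "posterior_predictive_mad",
    "trace_summary",
]

#: The frozen "standard synthetic design" used throughout the validation
#: suite: moderate dimensions with a clear but not overwhelming signal
#: (unit effect sizes against unit-scale noise, 80% sparse loadings,
#: two of three covariates active).
STANDARD_DESIGN = dict(
    p=300, n=80, q=3, c=3, n_active_covariates=2,
    loading_sparsity=0.8, effect_size=1.0, noise_scale=1.0,
)


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    W: np.ndarray
    Beta: np.ndarray           # (q, c+1) including intercept column 0
    U: np.ndarray
    X: np.ndarray              # (n, c+1) with intercept
    sigma2: np.ndarray
    phi2: np.ndarray
    active_covariates: list[int]    # indices into the c raw covariates (0-based)
    cluster_labels: np.ndarray | None
    seed: int
    dims: tuple[int, int, int, int]  # (p, n, q, c)


def simulate_dataset(
    p: int,
    n: int,
    q: int,
    c: int,
    n_active_covariates: int = 0,
    loading_sparsity: float = 0.8,
    effect_size: float = 1.0,
    noise_scale: float = 1.0,
    phi2: float = 1.0,
    n_clusters: int = 0,
    cluster_separation: float = 5.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, PhenotypeTable, SyntheticTruth]:
    """Draw one dataset from the generative model.

    Covariates are standard normal; the first ``n_active_covariates`` get
    coefficient ``effect_size`` on every CMV, the rest exactly 0.  Each
    loading column has ``ceil((1 - loading_sparsity) * p)`` nonzero
    entries with magnitudes ~ N(effect_size, 0.1^2) and random signs.
    Observation variances are heteroscedastic, ``noise_scale^2 *
    Uniform(0.5, 1.5)`` per feature.  With ``n_clusters > 0``, samples are
    split evenly into clusters whose centers (drawn once, scaled by
    ``cluster_separation``) shift the CMV means, planting discrete
    structure on top of the covariate effects.
    """
    if not 1 <= q < min(p, n):
        raise ValueError(f"q={q} must satisfy 1 <= q < min(p, n)")
    if n_active_covariates > c:
        raise ValueError("n_active_covariates cannot exceed c")
    if not 0 <= loading_sparsity < 1:
        raise ValueError("loading_sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)

    Xcov = rng.standard_normal((n, c))
    X = np.column_stack([np.ones(n), Xcov])
    Beta = np.zeros((q, c + 1))
    active = list(range(n_active_covariates))
    for j in active:
        Beta[:, j + 1] = effect_size

    n_nonzero = int(np.ceil((1.0 - loading_sparsity) * p))
    W = np.zeros((p, q))
    for k in range(q):
        rows = rng.choice(p, size=n_nonzero, replace=False)
        mags = rng.normal(effect_size, 0.1, size=n_nonzero)
        W[rows, k] = mags * rng.choice([-1.0, 1.0], size=n_nonzero)

    phi2_vec = np.full(q, float(phi2))
    Umean = Beta @ X.T
    labels = None
    if n_clusters > 0:
        labels = np.arange(n) % n_clusters
        rng.shuffle(labels)
        centers = cluster_separation * rng.standard_normal((n_clusters, q))
        Umean = Umean + centers[labels].T
    U = Umean + np.sqrt(phi2_vec)[:, None] * rng.standard_normal((q, n))

    sigma2 = noise_scale ** 2 * rng.uniform(0.5, 1.5, size=p)
    Y = W @ U + np.sqrt(sigma2)[:, None] * rng.standard_normal((p, n))

    feature_ids = [f"gene{j + 1:04d}" for j in range(p)]
    sample_ids = [f"sample{i + 1:03d}" for i in range(n)]
    expr = ExpressionMatrix(feature_ids, sample_ids, Y)
    pheno = PhenotypeTable(
        sample_ids=sample_ids,
        covariates=[Covariate(f"cov{j + 1}", "quantitative", Xcov[:, j]) for j in range(c)],
    )
    truth = SyntheticTruth(
        W=W, Beta=Beta, U=U, X=X, sigma2=sigma2, phi2=phi2_vec,
        active_covariates=active, cluster_labels=labels, seed=seed, dims=(p, n, q, c),
    )
    return expr, pheno, truth


def standard_design_dataset(seed: int, **overrides):
    """The frozen standard design at a given seed (overrides allowed)."""
    params = {**STANDARD_DESIGN, **overrides}
    return simulate_dataset(seed=seed, **params)


# ---------------------------------------------------------------------------
# joint-distribution ("getting it right") sampler check
# ---------------------------------------------------------------------------

#: moderate-tail hyperparameters for the joint-distribution check: all
#: monitored moments need finite fourth moments under the prior, which
#: vague Gamma(0.01, 0.01) priors do not give.
GIR_HYPER = Hyperparameters(a=3.0, b=3.0, a_sigma=3.0, b_sigma=3.0,
                            a_phi=3.0, b_phi=3.0, g=5.0,
                            v0=0.05, v1=1.0, inclusion_prob=0.5)


def _prior_draw(X, p, q, hyper: Hyperparameters, rng) -> ModelState:
    n, l = X.shape
    g = hyper.resolve_g(n)
    XtX_inv = np.linalg.inv(X.T @ X)
    Lchol = np.linalg.cholesky(XtX_inv)
    sigma2 = 1.0 / rng.gamma(hyper.a_sigma, 1.0 / hyper.b_sigma, size=p)
    phi2 = 1.0 / rng.gamma(hyper.a_phi, 1.0 / hyper.b_phi, size=q)
    gamma = np.ones(q, dtype=int)
    if hyper.mode == "spike_slab":
        gamma = (rng.random(q) < hyper.inclusion_prob).astype(int)
        v = np.where(gamma > 0, hyper.v1, hyper.v0)
        Lam = np.ones((p, q))
        W = np.sqrt(v)[None, :] * rng.standard_normal((p, q))
    else:
        Lam = rng.gamma(hyper.a, 1.0 / hyper.b, size=(p, q))
        W = rng.standard_normal((p, q)) / np.sqrt(Lam)
    Beta = np.sqrt(g * phi2)[:, None] * (rng.standard_normal((q, l)) @ Lchol.T)
    U = Beta @ X.T + np.sqrt(phi2)[:, None] * rng.standard_normal((q, n))
    return ModelState(W=W, U=U, Beta=Beta, sigma2=sigma2, phi2=phi2, Lambda=Lam, gamma=gamma)


def _data_draw(state: ModelState, rng) -> np.ndarray:
    p, n, _, _ = state.shape
    return state.W @ state.U + np.sqrt(state.sigma2)[:, None] * rng.standard_normal((p, n))


def _monitored(state: ModelState, Y: np.ndarray, mode: str) -> dict[str, float]:
    stats = {
        "mean_W": float(state.W.mean()),
        "mean_W2": float((state.W ** 2).mean()),
        "mean_Beta": float(state.Beta.mean()),
        "mean_Beta2": float((state.Beta ** 2).mean()),
        "mean_sigma2": float(state.sigma2.mean()),
        "mean_phi2": float(state.phi2.mean()),
        "mean_U2": float((state.U ** 2).mean()),
        "mean_Y": float(Y.mean()),
        "mean_Y2": float((Y ** 2).mean()),
    }
    if mode == "spike_slab":
        stats["mean_gamma"] = float(state.gamma.mean())
    else:
        stats["mean_Lambda"] = float(state.Lambda.mean())
    return stats


def _corrupted_sweep(state: ModelState, Y, X, hyper: Hyperparameters, rng) -> ModelState:
    # same composition as gibbs_sweep, but the ARD shape is a instead of a + 1/2
    g = hyper.resolve_g(Y.shape[1])
    U = draw_cmvs(Y, X, state.W, state.Beta, state.sigma2, state.phi2, rng)
    Lambda = draw_ard_precisions(state.W, hyper.a - 0.5, hyper.b, rng)
    W = draw_loadings(Y, U, state.sigma2, Lambda, rng)
    sigma2 = draw_noise_variances(Y, W, U, hyper.a_sigma, hyper.b_sigma, rng)
    Beta = draw_coefficients(U, X, state.phi2, g, rng)
    phi2 = draw_cmv_variances(U, X, Beta, g, hyper.a_phi, hyper.b_phi, rng)
    return ModelState(W=W, U=U, Beta=Beta, sigma2=sigma2, phi2=phi2, Lambda=Lambda,
                      gamma=state.gamma)


def _batch_se(series: np.ndarray, n_batches: int = 50) -> float:
    usable = (len(series) // n_batches) * n_batches
    means = series[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def getting_it_right_check(
    dims: tuple[int, int, int, int] = (6, 8, 2, 1),
    hyper: Hyperparameters = GIR_HYPER,
    n_outer: int = 5000,
    n_inner: int = 5000,
    seed: int = 0,
    corrupt: str | None = None,
) -> pd.DataFrame:
    """Joint-distribution test of the Gibbs conditionals.

    ``dims = (p, n, q, c)`` should be small.  ``corrupt='lambda_shape'``
    deliberately mis-specifies the ARD shape in the successive simulator;
    this is used to verify that the check itself has power to detect a
    wrong conditional.

    Returns a table with one row per monitored statistic: the two
    simulator means, the pooled standard error, and the z-statistic of
    their difference.  A correct sampler keeps every |z| small.
    """
    p, n, q, c = dims
    if corrupt not in (None, "lambda_shape"):
        raise ValueError(f"unknown corruption {corrupt!r}")
    if corrupt == "lambda_shape" and hyper.mode != "ard":
        raise ValueError("lambda_shape corruption applies to ARD mode only")
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.standard_normal((n, c))])

    marginal: list[dict[str, float]] = []
    for _ in range(n_outer):
        state = _prior_draw(X, p, q, hyper, rng)
        Y = _data_draw(state, rng)
        marginal.append(_monitored(state, Y, hyper.mode))

    successive: list[dict[str, float]] = []
    state = _prior_draw(X, p, q, hyper, rng)
    Y = _data_draw(state, rng)
    for _ in range(n_inner):
        if corrupt == "lambda_shape":
            state = _corrupted_sweep(state, Y, X, hyper, rng)
        else:
            state = gibbs_sweep(state, Y, X, hyper, rng)
        Y = _data_draw(state, rng)
        successive.append(_monitored(state, Y, hyper.mode))

    names = list(marginal[0])
    rows = []
    for name in names:
        m = np.array([d[name] for d in marginal])
        s = np.array([d[name] for d in successive])
        se = float(np.sqrt((m.std(ddof=1) / np.sqrt(len(m))) ** 2 + _batch_se(s) ** 2))
        z = (m.mean() - s.mean()) / se if se > 0 else 0.0
        rows.append(dict(statistic=name, mean_marginal=m.mean(),
                         mean_successive=s.mean(), se=se, z=float(z)))
    return pd.DataFrame(rows).set_index("statistic")


# ---------------------------------------------------------------------------
# posterior-predictive and convergence diagnostics
# ---------------------------------------------------------------------------

def posterior_predictive_mad(
    chain: PosteriorChain,
    Y,
    X,
    seed: int = 0,
    max_features: int = 500,
    unit_scale: bool = True,
) -> np.ndarray:
    """Per-draw mean absolute deviation between observed and replicate
    feature-feature covariance matrices.

    For each retained draw a replicate dataset is simulated from that
    draw's parameters (same design X); both observed and replicate
    matrices are divided by the observed per-feature SD first (so the
    "< 1" fit criterion refers to unit-scaled features).  If p exceeds
    ``max_features``, a seeded random feature subset is used.
    """
    from .model import _as_design, _as_matrix

    Ym, Xm = _as_matrix(Y), _as_design(X)
    p, n = Ym.shape
    rng = np.random.default_rng(seed)
    idx = np.arange(p)
    if p > max_features:
        idx = np.sort(rng.choice(p, size=max_features, replace=False))
    scale = Ym.std(axis=1, ddof=1) if unit_scale else np.ones(p)
    scale = np.where(scale == 0, 1.0, scale)
    obs_cov = np.cov(Ym[idx] / scale[idx, None])
    mads = np.empty(chain.n_draws)
    for s in range(chain.n_draws):
        W, Beta = chain.W[s], chain.Beta[s]
        sigma2, phi2 = chain.sigma2[s], chain.phi2[s]
        q = W.shape[1]
        Urep = Beta @ Xm.T + np.sqrt(phi2)[:, None] * rng.standard_normal((q, n))
        Yrep = W[idx] @ Urep + np.sqrt(sigma2[idx])[:, None] * rng.standard_normal((len(idx), n))
        rep_cov = np.cov(Yrep / scale[idx, None])
        mads[s] = np.abs(obs_cov - rep_cov).mean()
    return mads


_TRACEABLE = ("log_posterior", "W", "U", "Beta", "sigma2", "phi2", "Lambda")


@dataclass
class TraceSummary:
    parameter: str
    window_means: np.ndarray
    split_half_z: float
    table: pd.DataFrame = field(repr=False)


def trace_summary(chain: PosteriorChain, parameter: str, window_size: int = 50) -> TraceSummary:
    """Windowed means of a per-draw scalar trace plus a split-half
    mean-comparison z (a Geweke-style convergence statistic).

    Array-valued parameters are traced through their per-draw elementwise
    mean; ``log_posterior`` is traced directly.
    """
    if parameter not in _TRACEABLE:
        raise ValueError(f"unknown parameter {parameter!r}; valid names: {_TRACEABLE}")
    if parameter == "log_posterior":
        series = chain.log_posterior.copy()
    else:
        arr = getattr(chain, parameter)
        series = arr.reshape(arr.shape[0], -1).mean(axis=1)
    S = len(series)
    n_windows = -(-S // window_size)
    means = np.array([series[w * window_size:(w + 1) * window_size].mean() for w in range(n_windows)])
    half = S // 2
    a, b = series[:half], series[half:]
    n_b = max(2, min(20, half // 5))
    se = np.sqrt(_batch_se(a, n_batches=n_b) ** 2 + _batch_se(b, n_batches=n_b) ** 2)
    z = float((a.mean() - b.mean()) / se) if se > 0 else 0.0
    table = pd.DataFrame({"window": np.arange(n_windows), "mean": means, "parameter": parameter})
    return TraceSummary(parameter=parameter, window_means=means, split_half_z=z, table=table)
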