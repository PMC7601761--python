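"""Discrete "functional" subtypes from consensus k-means over CMVs.

Samples are clustered on their posterior-mean CMV scores, optionally
joined with the unit-scaled quantitative phenotypes (e.g. -log10 GI50
drug responses) significantly associated with those CMVs.  Repeated
subsampled k-means runs are aggregated into an n x n consensus
(co-assignment) matrix per candidate k; cluster number is chosen by
combining the cophenetic coefficient of the consensus matrix with the
mean silhouette width.  A permutation score flags subtypes whose
centroid sits further from random same-sized sample sets than one
unit-scaled Euclidean distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .data_io import PhenotypeTable
from .selection import SignificanceCall

__all__ = [
    "ConsensusResult",
    "unit_scale",
    "consensus_kmeans",
    "cophenetic_coefficient",
    "silhouette_width",
    "build_subtype_input",
    "drug_response_groups",
    "permutation_robustness",
]

DEFAULT_K_GRID = tuple(range(2, 8))
DEFAULT_REPS = 1000
DEFAULT_SUBSAMPLE_FRACTION = 0.8
ROBUSTNESS_THRESHOLD = 1.0


def unit_scale(M, column_names: Sequence[str] | None = None) -> np.ndarray:
    """Standardize each column to mean 0, SD 1 (SD with n-1 denominator)."""
    A = np.asarray(M, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    sd = A.std(axis=0, ddof=1)
    if (flat := np.flatnonzero(sd == 0)).size:
        name = column_names[flat[0]] if column_names else f"column {flat[0]}"
        raise ValueError(f"cannot unit-scale constant column: {name}")
    return (A - A.mean(axis=0)) / sd


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and stability metrics."""

    k_grid: list[int]
    consensus: dict[int, np.ndarray]
    assignments: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    silhouette: dict[int, float]
    selected_k: int
    reps: int
    subsample_fraction: float
    seed: int

    @property
    def labels(self) -> np.ndarray:
        """Hard assignments at the selected k."""
        return self.assignments[self.selected_k]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_grid,
            "cophenetic": [self.cophenetic[k] for k in self.k_grid],
            "silhouette": [self.silhouette[k] for k in self.k_grid],
            "selected": [k == self.selected_k for k in self.k_grid],
        })


def _consensus_assignments(consensus: np.ndarray, k: int) -> np.ndarray:
    D = 1.0 - consensus
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust") - 1


def consensus_kmeans(
    M,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    reps: int = DEFAULT_REPS,
    subsample_fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means over a samples x dims matrix.

    Per repetition a fraction of samples is drawn without replacement and
    clustered by k-means with a fresh random initialization; the
    consensus matrix is the co-assignment count divided by the
    co-sampling count.  Hard assignments come from average-linkage
    hierarchical clustering of (1 - consensus).  The selected k
    maximizes the rank-sum of cophenetic coefficient and mean silhouette
    width over the grid (ties toward smaller k).
    """
    A = np.asarray(M, dtype=float)
    n = A.shape[0]
    k_grid = sorted(set(int(k) for k in k_grid))
    m = int(round(subsample_fraction * n))
    for k in k_grid:
        if k >= m:
            raise ValueError(f"k={k} too large for subsample size {m} (n={n}, fraction={subsample_fraction})")
    rng = np.random.default_rng(seed)

    consensus: dict[int, np.ndarray] = {}
    assignments: dict[int, np.ndarray] = {}
    coph: dict[int, float] = {}
    sil: dict[int, float] = {}
    for k in k_grid:
        co = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(reps):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=1, init="k-means++",
                        random_state=int(rng.integers(2 ** 31)))
            labels = km.fit_predict(A[idx])
            same = labels[:, None] == labels[None, :]
            co[np.ix_(idx, idx)] += same
            sampled[np.ix_(idx, idx)] += 1.0
        C = np.divide(co, sampled, out=np.zeros_like(co), where=sampled > 0)
        np.fill_diagonal(C, 1.0)
        C = 0.5 * (C + C.T)
        consensus[k] = C
        assignments[k] = _consensus_assignments(C, k)
        coph[k] = cophenetic_coefficient(C)
        sil[k] = silhouette_width(A, assignments[k])

    ranks_c = pd.Series([coph[k] for k in k_grid]).rank().to_numpy()
    ranks_s = pd.Series([sil[k] for k in k_grid]).rank().to_numpy()
    selected = k_grid[int(np.argmax(ranks_c + ranks_s))]  # first argmax -> smaller k on ties
    return ConsensusResult(
        k_grid=k_grid, consensus=consensus, assignments=assignments,
        cophenetic=coph, silhouette=sil, selected_k=selected,
        reps=reps, subsample_fraction=subsample_fraction, seed=seed,
    )


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Pearson correlation between consensus dissimilarities (1 - C) and
    the cophenetic distances of their average-linkage dendrogram.

    Returns NaN when the dissimilarities are all equal (degenerate)."""
    C = np.asarray(consensus, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus matrix must be square")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    if np.ptp(condensed) == 0:
        return float("nan")
    Z = linkage(condensed, method="average")
    r, _ = cophenet(Z, condensed)
    return float(r)


def silhouette_width(M, assignments) -> float:
    """Mean silhouette width (b - a)/max(a, b) with Euclidean distances;
    samples in singleton clusters contribute 0."""
    labels = np.asarray(assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette width needs at least 2 clusters")
    return float(silhouette_samples(np.asarray(M, dtype=float), labels).mean())


def build_subtype_input(
    U_mean: np.ndarray,
    calls: SignificanceCall,
    pheno: PhenotypeTable,
    mode: Literal["universal", "per_cmv"] = "universal",
    cmv: int | None = None,
) -> pd.DataFrame:
    """Assemble the unit-scaled samples x dims clustering input.

    ``universal``: every CMV plus every quantitative phenotype that is
    significantly associated with any CMV.  ``per_cmv``: the chosen CMV
    plus only its own significant phenotypes (possibly none, in which
    case the matrix is that CMV alone).
    """
    q, n = U_mean.shape
    if pheno.n_samples != n:
        raise ValueError("phenotype table does not match the number of samples")
    cols: list[np.ndarray] = []
    names: list[str] = []
    if mode == "universal":
        for k in range(q):
            cols.append(U_mean[k])
            names.append(f"CMV{k + 1}")
        wanted = list(dict.fromkeys(calls.covariate_calls["covariate"]))
    elif mode == "per_cmv":
        if cmv is None or not 0 <= cmv < q:
            raise ValueError(f"per_cmv mode needs a CMV index in 0..{q - 1}")
        cols.append(U_mean[cmv])
        names.append(f"CMV{cmv + 1}")
        wanted = list(dict.fromkeys(calls.significant_covariates(cmv)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    for name in wanted:
        base = name.split("[")[0]  # indicator columns point back to their covariate
        cov = pheno.covariate(base)  # raises KeyError when absent
        if cov.kind != "quantitative":
            continue  # only quantitative phenotypes enter the joint clustering
        cols.append(np.asarray(cov.values, dtype=float))
        names.append(base)
    scaled = unit_scale(np.column_stack(cols), column_names=names)
    return pd.DataFrame(scaled, index=list(pheno.sample_ids), columns=names)


def drug_response_groups(values) -> np.ndarray:
    """Split one drug's -log10(GI50) values into H/M/L sensitivity groups.

    Exact 1-D 3-means on the unit-scaled values (optimal clusters are
    contiguous in sorted order, found by exhaustive breakpoint search);
    groups are labeled H, M, L by decreasing group mean, so H = most
    sensitive.  Each drug is grouped separately.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(np.unique(v)) < 3:
        raise ValueError("need at least 3 distinct values to form 3 response groups")
    x = unit_scale(v)[:, 0]
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csum2 = np.concatenate([[0.0], np.cumsum(xs ** 2)])

    def seg_ss(i, j):  # within-SS of xs[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csum2[j] - csum2[i]) - s * s / m

    best, best_ij = np.inf, None
    for i in range(1, n - 1):
        ss1 = seg_ss(0, i)
        for j in range(i + 1, n):
            ss = ss1 + seg_ss(i, j) + seg_ss(j, n)
            if ss < best - 1e-12:
                best, best_ij = ss, (i, j)
    i, j = best_ij
    groups_sorted = np.empty(n, dtype=int)
    groups_sorted[:i], groups_sorted[i:j], groups_sorted[j:] = 0, 1, 2
    # sorted ascending -> group 2 has the largest values -> H
    letter = {2: "H", 1: "M", 0: "L"}
    out = np.empty(n, dtype=object)
    out[order] = [letter[gr] for gr in groups_sorted]
    return out.astype(str)


def permutation_robustness(
    M,
    assignments,
    n_perm: int = 1000,
    seed: int = 0,
    threshold: float = ROBUSTNESS_THRESHOLD,
) -> pd.DataFrame:
    """Permutation score of subtype-centroid displacement.

    For each subtype, the Euclidean distance between its observed
    centroid and the centroid of an equal-sized random sample of rows,
    averaged over ``n_perm`` draws; a subtype is robust when this average
    distance exceeds ``threshold`` (default 1) on unit-scaled input.
    """
    A = np.asarray(M, dtype=float)
    labels = np.asarray(assignments)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    rows = []
    for s in np.unique(labels):
        members = np.flatnonzero(labels == s)
        if members.size == 0:
            raise ValueError(f"subtype {s} has no members")
        centroid = A[members].mean(axis=0)
        dists = np.empty(n_perm)
        for t in range(n_perm):
            idx = rng.choice(n, size=members.size, replace=False)
            dists[t] = np.linalg.norm(centroid - A[idx].mean(axis=0))
        score = float(dists.mean())
        rows.append(dict(subtype=s, size=int(members.size), score=score,
                         robust=bool(score > threshold)))
    return pd.DataFrame(rows)
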