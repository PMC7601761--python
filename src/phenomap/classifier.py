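"""Nearest-centroid (PAM-style) subtype classifiers on gene signatures.

A classifier is trained on the signature genes selected by the factor
model: per-gene standardization parameters are fitted on the training
cohort, shrunken-centroid training is cross-validated over a shrinkage
grid, and the chosen shrinkage is the smallest cross-validated-error
value that still retains every signature gene (typically 0).  New
samples are assigned to the subtype whose centroid has the highest
Pearson correlation with the sample's (standardized) signature
expression.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestCentroid

from .data_io import ExpressionMatrix

__all__ = ["CentroidClassifier", "build_pam_centroids", "classify_samples",
           "save_classifier", "load_classifier"]

DEFAULT_FOLDS = 5
DEFAULT_SHRINKAGE_GRID = (0.0, 0.25, 0.5, 1.0, 2.0)
MIN_SIGNATURE_OVERLAP = 0.5


@dataclass
class CentroidClassifier:
    """Trained nearest-centroid classifier over a gene signature."""

    gene_ids: list[str]
    subtypes: list[str]
    centroids: np.ndarray          # (n_genes, n_subtypes), standardized scale
    center: np.ndarray             # per-gene training mean
    scale: np.ndarray              # per-gene training SD
    n_per_subtype: dict[str, int]
    folds: int
    cv_error: float
    shrinkage: float

    def __post_init__(self) -> None:
        if self.centroids.shape != (len(self.gene_ids), len(self.subtypes)):
            raise ValueError("centroid matrix shape does not match genes x subtypes")
        if len(self.subtypes) < 2:
            raise ValueError("need at least 2 subtypes")


def _retains_all_genes(model: NearestCentroid, overall: np.ndarray) -> bool:
    dev = model.centroids_ - overall[None, :]
    return bool((np.abs(dev).max(axis=0) > 0).all())


def build_pam_centroids(
    expr: ExpressionMatrix,
    labels,
    folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    shrinkage_grid=DEFAULT_SHRINKAGE_GRID,
) -> CentroidClassifier:
    """Train a shrunken-centroid classifier on signature expression.

    ``expr`` is restricted to the signature (features x samples);
    ``labels`` gives one subtype per sample.  Cross-validated
    misclassification is computed per shrinkage value; among values that
    retain the full signature, the one with the least CV error wins
    (ties toward less shrinkage).  Classes smaller than the fold count
    trigger a stratified fold reduction with a warning; a singleton
    class is an error.
    """
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != expr.n_samples:
        raise ValueError("one label per sample required")
    subtypes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        bad = subtypes[counts.argmin()]
        raise ValueError(f"subtype {bad!r} has a single sample; cannot cross-validate")
    if counts.min() < folds:
        warnings.warn(
            f"smallest subtype has {counts.min()} samples < {folds} folds; "
            f"reducing to {counts.min()} folds"
        )
        folds = int(counts.min())

    center = expr.values.mean(axis=1)
    scale = expr.values.std(axis=1, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    Z = ((expr.values - center[:, None]) / scale[:, None]).T  # samples x genes
    overall = Z.mean(axis=0)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, labels))
    results = []
    for t in shrinkage_grid:
        thr = None if t == 0 else t
        errs = []
        for train, test in splits:
            m = NearestCentroid(shrink_threshold=thr).fit(Z[train], labels[train])
            errs.append(float(np.mean(m.predict(Z[test]) != labels[test])))
        full = NearestCentroid(shrink_threshold=thr).fit(Z, labels)
        results.append((t, float(np.mean(errs)), _retains_all_genes(full, overall), full))

    eligible = [r for r in results if r[2]]
    if not eligible:
        raise RuntimeError("no shrinkage value retains the full signature")
    chosen = min(eligible, key=lambda r: (r[1], r[0]))
    t, cv_error, _, model = chosen
    order = [list(model.classes_).index(s) for s in subtypes]
    centroids = model.centroids_[order].T  # genes x subtypes
    return CentroidClassifier(
        gene_ids=list(expr.feature_ids), subtypes=list(subtypes), centroids=centroids,
        center=center, scale=scale,
        n_per_subtype={s: int(c) for s, c in zip(subtypes, counts)},
        folds=folds, cv_error=cv_error, shrinkage=float(t),
    )


def classify_samples(
    clf: CentroidClassifier,
    expr_new: ExpressionMatrix,
    use_stored_scaling: bool = True,
) -> tuple[pd.Series, pd.DataFrame]:
    """Assign new samples to subtypes by Pearson correlation to centroids.

    Missing signature genes are dropped pairwise (at least 50% of the
    signature must be present).  Returns the per-sample labels and the
    samples x subtypes correlation matrix.  Ties go to the first subtype
    in declared order, with a warning.
    """
    idx = {g: i for i, g in enumerate(expr_new.feature_ids)}
    shared = [g for g in clf.gene_ids if g in idx]
    frac = len(shared) / len(clf.gene_ids)
    if frac < MIN_SIGNATURE_OVERLAP:
        raise ValueError(
            f"only {len(shared)}/{len(clf.gene_ids)} signature genes present "
            f"({frac:.0%} < {MIN_SIGNATURE_OVERLAP:.0%} required)"
        )
    if frac < 1.0:
        warnings.warn(f"{len(clf.gene_ids) - len(shared)} signature genes missing; "
                      f"using {frac:.0%} of the signature")
    sig_rows = [clf.gene_ids.index(g) for g in shared]
    new_rows = [idx[g] for g in shared]
    V = expr_new.values[new_rows, :]
    if use_stored_scaling:
        V = (V - clf.center[sig_rows, None]) / clf.scale[sig_rows, None]
    C = clf.centroids[sig_rows, :]                      # genes x subtypes

    def _std(A, axis):
        mu = A.mean(axis=axis, keepdims=True)
        sd = A.std(axis=axis, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        return (A - mu) / sd

    Vs = _std(V, axis=0)
    Cs = _std(C, axis=0)
    corr = (Vs.T @ Cs) / len(shared)                    # samples x subtypes
    corr_df = pd.DataFrame(corr, index=list(expr_new.sample_ids), columns=list(clf.subtypes))
    best = corr_df.to_numpy().argmax(axis=1)
    ties = (corr_df.to_numpy() == corr_df.to_numpy().max(axis=1, keepdims=True)).sum(axis=1)
    if (ties > 1).any():
        warnings.warn(f"{int((ties > 1).sum())} sample(s) had tied correlations; "
                      "assigned to the first subtype in declared order")
    labels = pd.Series([clf.subtypes[j] for j in best], index=list(expr_new.sample_ids),
                       name="subtype")
    return labels, corr_df


def save_classifier(clf: CentroidClassifier, directory: str) -> None:
    """Persist as a genes x subtypes centroid TSV plus JSON metadata."""
    os.makedirs(directory, exist_ok=True)
    df = pd.DataFrame(clf.centroids, index=clf.gene_ids, columns=clf.subtypes)
    df.insert(0, "_center", clf.center)
    df.insert(1, "_scale", clf.scale)
    df.to_csv(os.path.join(directory, "centroids.tsv"), sep="\t")
    meta = dict(subtypes=clf.subtypes, n_per_subtype=clf.n_per_subtype,
                folds=clf.folds, cv_error=clf.cv_error, shrinkage=clf.shrinkage)
    with open(os.path.join(directory, "classifier.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_classifier(directory: str) -> CentroidClassifier:
    df = pd.read_csv(os.path.join(directory, "centroids.tsv"), sep="\t", index_col=0)
    with open(os.path.join(directory, "classifier.json")) as fh:
        meta = json.load(fh)
    return CentroidClassifier(
        gene_ids=[str(g) for g in df.index], subtypes=list(meta["subtypes"]),
        centroids=df[meta["subtypes"]].to_numpy(),
        center=df["_center"].to_numpy(), scale=df["_scale"].to_numpy(),
        n_per_subtype=meta["n_per_subtype"], folds=int(meta["folds"]),
        cv_error=float(meta["cv_error"]), shrinkage=float(meta["shrinkage"]),
    )
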