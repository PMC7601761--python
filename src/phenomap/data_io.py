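"""Reading, validation and preparation of omics and phenotype inputs.

The modelling code consumes three containers built here:

* :class:`ExpressionMatrix` — a features x samples matrix of continuous
  (log-scale) omics values, e.g. gene expression.
* :class:`PhenotypeTable` — sample-matched covariates, quantitative or
  categorical, aligned to the expression sample order.
* :class:`DesignMatrix` — the model-ready covariate matrix with an
  intercept, standardized quantitative columns and reference-coded
  categorical indicators.  Full column rank is required so that
  (X^T X)^{-1} exists for the g-prior on regression coefficients.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "PhenotypeTable",
    "Covariate",
    "DesignMatrix",
    "FeatureTransform",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "select_variable_features",
    "preprocess_expression",
    "build_design_matrix",
]

#: default number of variable features kept when more are present
DEFAULT_N_VARIABLE_FEATURES = 1000


@dataclass
class ExpressionMatrix:
    """Features x samples continuous omics matrix."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (p, n)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = self.values.shape
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError(
                f"id/value shape mismatch: {len(self.feature_ids)} features, "
                f"{len(self.sample_ids)} samples, values {self.values.shape}"
            )
        if p < 2 or n < 3:
            raise ValueError(f"matrix too small: need p >= 2 and n >= 3, got p={p}, n={n}")
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at feature "
                f"{self.feature_ids[bad[0]]!r}, sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class Covariate:
    name: str
    kind: Literal["quantitative", "categorical"]
    values: np.ndarray | pd.Series

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r} for {self.name!r}")
        if self.kind == "quantitative":
            self.values = np.asarray(self.values, dtype=float)
        else:
            self.values = np.asarray([None if pd.isna(v) else str(v) for v in self.values], dtype=object)


@dataclass
class PhenotypeTable:
    """Sample-matched covariates, aligned to an expression sample order."""

    sample_ids: list[str]
    covariates: list[Covariate] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for cov in self.covariates:
            if len(cov.values) != n:
                raise ValueError(f"covariate {cov.name!r} has {len(cov.values)} values for {n} samples")
            if cov.kind == "categorical":
                levels = {v for v in cov.values if v is not None}
                if len(levels) < 2:
                    raise ValueError(f"categorical covariate {cov.name!r} has fewer than 2 observed levels")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def covariate(self, name: str) -> Covariate:
        for cov in self.covariates:
            if cov.name == name:
                return cov
        raise KeyError(f"no covariate named {name!r}; have {[c.name for c in self.covariates]}")

    def has_missing(self) -> bool:
        for cov in self.covariates:
            if cov.kind == "quantitative":
                if not np.isfinite(np.asarray(cov.values, dtype=float)).all():
                    return True
            elif any(v is None for v in cov.values):
                return True
        return False


@dataclass
class DesignMatrix:
    """n x (c+1) covariate matrix; column 0 is the intercept."""

    X: np.ndarray
    column_names: list[str]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.column_names):
            raise ValueError("design matrix shape does not match column names")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept of ones")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            deps = _dependent_columns(self.X, self.column_names)
            raise ValueError(f"design matrix is rank deficient (rank {rank} < {self.X.shape[1]}); dependent columns: {deps}")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # greedy: a column is dependent if adding it does not raise the rank
    deps, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, [j]]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            deps.append(name)
        else:
            kept = cand
    return deps


def _sniff_sep(path: str) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(64 * 1024)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_expression(
    path: str,
    orientation: Literal["features_in_rows", "samples_in_rows"] = "features_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV or CSV, auto-detected).

    The first row holds sample ids and the first column feature ids under the
    default ``features_in_rows`` orientation; ``samples_in_rows`` transposes.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"empty expression matrix in {path}")
    if orientation == "samples_in_rows":
        df = df.T
    elif orientation != "features_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(f"non-numeric cells in column {col!r} (e.g. row {bad[0]!r})")
    return ExpressionMatrix(
        feature_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def write_expression(expr: ExpressionMatrix, path: str, sep: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=sep)


def read_phenotypes(
    path: str,
    kinds: Mapping[str, str] | None = None,
    sample_order: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Read a sample x covariate phenotype table and align it.

    ``kinds`` maps covariate name to ``quantitative``/``categorical``; columns
    not listed default to quantitative when numeric, categorical otherwise.
    When ``sample_order`` is given (normally the expression sample ids) the
    rows are realigned to it and any symmetric difference is an error.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, float_precision="round_trip")
    df.index = df.index.map(str)
    if sample_order is not None:
        missing = [s for s in sample_order if s not in df.index]
        extra = [s for s in df.index if s not in set(sample_order)]
        if missing or extra:
            raise ValueError(
                f"phenotype/expression sample mismatch: missing from phenotypes {missing}, "
                f"not in expression {extra}"
            )
        df = df.loc[list(sample_order)]
    kinds = dict(kinds or {})
    covariates = []
    for col in df.columns:
        kind = kinds.get(col)
        if kind is None:
            kind = "quantitative" if pd.api.types.is_numeric_dtype(df[col]) else "categorical"
        if kind == "quantitative":
            vals = pd.to_numeric(df[col], errors="coerce").to_numpy()
        else:
            vals = df[col]
        covariates.append(Covariate(name=str(col), kind=kind, values=vals))
    return PhenotypeTable(sample_ids=[str(i) for i in df.index], covariates=covariates)


def select_variable_features(
    expr: ExpressionMatrix,
    k: int = DEFAULT_N_VARIABLE_FEATURES,
    criterion: Literal["variance", "mad"] = "variance",
) -> ExpressionMatrix:
    """Keep the ``k`` most variable features (by variance or MAD).

    Original feature order is preserved among survivors; ties are broken by
    feature id so the selection is deterministic.
    """
    p = expr.n_features
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range 1..{p}")
    if criterion == "variance":
        score = expr.values.var(axis=1, ddof=1)
    elif criterion == "mad":
        med = np.median(expr.values, axis=1, keepdims=True)
        score = np.median(np.abs(expr.values - med), axis=1)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    order = sorted(range(p), key=lambda j: (-score[j], expr.feature_ids[j]))
    keep = sorted(order[:k])
    return ExpressionMatrix(
        feature_ids=[expr.feature_ids[j] for j in keep],
        sample_ids=list(expr.sample_ids),
        values=expr.values[keep],
    )


@dataclass
class FeatureTransform:
    """Per-feature affine transform fitted on training data, reusable on new cohorts."""

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray

    def apply(self, expr: ExpressionMatrix) -> ExpressionMatrix:
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in expr.feature_ids if f not in idx]
        if missing:
            raise ValueError(f"features not seen in training transform: {missing[:5]}")
        rows = [idx[f] for f in expr.feature_ids]
        vals = (expr.values - self.center[rows, None]) / self.scale[rows, None]
        return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), vals)


def preprocess_expression(
    expr: ExpressionMatrix,
    mode: Literal["center", "standardize", "none"] = "center",
) -> tuple[ExpressionMatrix, FeatureTransform]:
    """Apply a per-feature transform; returns the transformed matrix and the
    fitted :class:`FeatureTransform` for reuse on new cohorts."""
    p = expr.n_features
    center = np.zeros(p)
    scale = np.ones(p)
    if mode in ("center", "standardize"):
        center = expr.values.mean(axis=1)
    if mode == "standardize":
        scale = expr.values.std(axis=1, ddof=1)
        if (flat := np.flatnonzero(scale == 0)).size:
            raise ValueError(f"zero-variance feature under standardize: {expr.feature_ids[flat[0]]!r}")
    elif mode not in ("center", "none"):
        raise ValueError(f"unknown preprocessing mode {mode!r}")
    tf = FeatureTransform(list(expr.feature_ids), center, scale)
    return tf.apply(expr), tf


def build_design_matrix(
    pheno: PhenotypeTable,
    reference_levels: Mapping[str, str] | None = None,
    impute: bool = False,
) -> DesignMatrix:
    """Construct the model design matrix X (n x (c+1)).

    Quantitative covariates are standardized to mean 0, SD 1; categorical
    covariates are expanded to L-1 indicators against a reference level
    (lexicographically smallest unless given).  Missing values are refused
    unless ``impute`` is set (mean for quantitative, mode for categorical).
    """
    n = pheno.n_samples
    reference_levels = dict(reference_levels or {})
    cols = [np.ones(n)]
    names = ["intercept"]
    refs: dict[str, str] = {}
    for cov in pheno.covariates:
        if cov.kind == "quantitative":
            v = np.asarray(cov.values, dtype=float)
            if not np.isfinite(v).all():
                if not impute:
                    raise ValueError(f"missing values in quantitative covariate {cov.name!r} (set impute=True to mean-impute)")
                v = np.where(np.isfinite(v), v, np.nanmean(v))
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant quantitative covariate {cov.name!r}")
            cols.append((v - v.mean()) / sd)
            names.append(cov.name)
        else:
            vals = list(cov.values)
            if any(x is None for x in vals):
                if not impute:
                    raise ValueError(f"missing values in categorical covariate {cov.name!r} (set impute=True to mode-impute)")
                observed = [x for x in vals if x is not None]
                mode_level = max(sorted(set(observed)), key=observed.count)
                vals = [mode_level if x is None else x for x in vals]
            levels = sorted(set(vals))
            ref = reference_levels.get(cov.name, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not observed for {cov.name!r}; levels {levels}")
            refs[cov.name] = ref
            for lvl in levels:
                if lvl == ref:
                    continue
                cols.append(np.asarray([1.0 if x == lvl else 0.0 for x in vals]))
                names.append(f"{cov.name}[{lvl}]")
    return DesignMatrix(X=np.column_stack(cols), column_names=names, reference_levels=refs)
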