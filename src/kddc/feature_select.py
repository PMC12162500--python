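"""Dimension reduction of k-mer count matrices.

Two stages, in order:

1. zero-count screening — a feature is dropped when the fraction of rows in
   which it is zero reaches a threshold (default 0.95); sparse concatemer
   columns carry little class information and inflate the feature space;
2. per-feature one-way ANOVA across disease-state groups — a feature is
   retained when its F-test p-value is below the significance level
   (default 0.05, no multiple-testing adjustment; Benjamini-Hochberg is
   available as an option).

Features with zero variance overall are degenerate (the F statistic is
undefined) and are always dropped, as are features whose F statistic is
non-finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .kmer_features import KmerCountMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "zero_filter",
    "anova_f",
    "anova_select",
    "select_features",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the two-stage feature screen."""

    zero_fraction_threshold: float = 0.95
    alpha: float = 0.05
    adjust: str = "none"  # "none" | "benjamini_hochberg"

    def __post_init__(self) -> None:
        if not 0.0 <= self.zero_fraction_threshold <= 1.0:
            raise ValueError(
                f"zero_fraction_threshold must be in [0, 1], got "
                f"{self.zero_fraction_threshold}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.adjust not in {"none", "benjamini_hochberg"}:
            raise ValueError(f"unknown adjust method {self.adjust!r}")


@dataclass
class SelectionResult:
    """Per-feature screening outcome.

    ``f_stat`` and ``p_value`` are NaN for features removed by the zero
    filter (ANOVA is not computed for them) and for degenerate features.
    """

    zero_fraction: np.ndarray
    f_stat: np.ndarray
    p_value: np.ndarray
    kept: np.ndarray
    config: SelectionConfig = field(default_factory=SelectionConfig)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)

    def to_frame(self, feature_names=None) -> pd.DataFrame:
        """Report table: feature, zero_fraction, F, p, kept."""
        n = len(self.kept)
        names = list(feature_names) if feature_names is not None else list(range(n))
        return pd.DataFrame(
            {
                "feature": names,
                "zero_fraction": self.zero_fraction,
                "F": self.f_stat,
                "p": self.p_value,
                "kept": self.kept,
            }
        )

    def save(self, path: str | Path, feature_names=None) -> None:
        self.to_frame(feature_names).to_csv(path, index=False)


def _as_array_like(matrix):
    if isinstance(matrix, KmerCountMatrix):
        return matrix.counts
    return matrix


def zero_fractions(matrix) -> np.ndarray:
    """Fraction of rows in which each feature is exactly zero."""
    X = _as_array_like(matrix)
    if X.shape[0] < 1:
        raise ValueError("matrix must have at least one row")
    if sparse.issparse(X):
        X = X.tocsc(copy=True)
        X.eliminate_zeros()
        nnz = np.diff(X.indptr)
    else:
        nnz = np.count_nonzero(np.asarray(X), axis=0)
    return 1.0 - nnz / X.shape[0]


def zero_filter(matrix, threshold: float = 0.95) -> np.ndarray:
    """Boolean mask of features whose zero fraction is strictly below ``threshold``.

    The inequality is strict: with 10 rows, 9 zeros and threshold 0.9 the
    feature is dropped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return zero_fractions(matrix) < threshold


def anova_f(X, labels) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA per column of X across label groups.

    Returns (F, p) arrays; columns with zero variance everywhere yield NaN.
    Degrees of freedom are (g - 1, n - g) for g groups over n rows.
    """
    X = np.asarray(X.toarray() if sparse.issparse(X) else X, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if any((labels == g).sum() < 1 for g in groups):  # pragma: no cover
        raise ValueError("every group needs at least one row")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns warn; handled via NaN
        res = stats.f_oneway(*[X[labels == g] for g in groups], axis=0)
    return np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)


def anova_select(
    matrix,
    labels=None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> SelectionResult:
    """Retain features whose ANOVA p-value across state groups is below alpha.

    Degenerate features (NaN or non-finite F) are dropped. ``matrix`` may be
    a :class:`KmerCountMatrix` (labels taken from it) or an array with
    ``labels`` given explicitly.
    """
    if isinstance(matrix, KmerCountMatrix):
        X = matrix.counts
        labels = matrix.labels if labels is None else labels
    else:
        X = matrix
    if labels is None:
        raise ValueError("labels are required for ANOVA selection")
    f, p = anova_f(X, labels)
    if adjust == "benjamini_hochberg":
        defined = np.isfinite(p)
        p = p.copy()
        if defined.any():
            p[defined] = stats.false_discovery_control(p[defined], method="bh")
    finite = np.isfinite(f)
    kept = finite & np.isfinite(p) & (p < alpha)
    zf = zero_fractions(X)
    return SelectionResult(
        zero_fraction=zf,
        f_stat=f,
        p_value=p,
        kept=kept,
        config=SelectionConfig(alpha=alpha, adjust=adjust),
    )


def select_features(
    matrix,
    labels=None,
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Zero-count screen followed by ANOVA, fitted in one pass.

    ANOVA is computed only on features surviving the zero screen; the
    others report NaN F/p and are never kept.
    """
    config = config or SelectionConfig()
    if isinstance(matrix, KmerCountMatrix):
        X = matrix.counts
        labels = matrix.labels if labels is None else labels
    else:
        X = matrix
    if labels is None:
        raise ValueError("labels are required for feature selection")

    zf = zero_fractions(X)
    zmask = zf < config.zero_fraction_threshold
    n_feat = X.shape[1]
    f = np.full(n_feat, np.nan)
    p = np.full(n_feat, np.nan)
    kept = np.zeros(n_feat, dtype=bool)
    if zmask.any():
        sub = X[:, zmask]
        fi, pi = anova_f(sub, labels)
        if config.adjust == "benjamini_hochberg":
            defined = np.isfinite(pi)
            if defined.any():
                pi[defined] = stats.false_discovery_control(pi[defined], method="bh")
        f[zmask] = fi
        p[zmask] = pi
        kept[zmask] = np.isfinite(fi) & np.isfinite(pi) & (pi < config.alpha)
    return SelectionResult(zero_fraction=zf, f_stat=f, p_value=p, kept=kept,
                           config=config)
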