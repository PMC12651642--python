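"""Feature-relevance scoring and the Combined Importance Index.

Two complementary relevance views are computed: a model-based score (mean
impurity decrease over a random-forest ensemble, renormalized to sum to 1)
and a univariate class-separability score (the ratio of between-class to
within-class variation, with an optional classical degrees-of-freedom
scaling and a mutual-information alternative).  Each score table is min-max
rescaled to [0, 1]; the Combined Importance Index is the arithmetic mean of
the rescaled tables, with ranks in descending combined score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif

from .errors import AlignmentError, ConfigError, DegenerateLabelError
from .schema import EncodedMatrix

F_VARIANTS = ("raw_ratio", "df_adjusted", "mutual_information")


def minmax_rescale(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    out = np.zeros_like(raw)
    finite = np.isfinite(raw)
    if finite.any():
        lo, hi = raw[finite].min(), raw[finite].max()
        if hi > lo:
            out[finite] = (raw[finite] - lo) / (hi - lo)
    out[np.isposinf(raw)] = 1.0  # infinite separability saturates the scale
    return np.clip(out, 0.0, 1.0)


def _ranks_descending(scores: np.ndarray) -> np.ndarray:
    """1-based ranks, ties broken by input (schema) order."""
    order = np.argsort(-scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


@dataclass
class FeatureScoreTable:
    """Raw and min-max rescaled relevance scores for one method."""

    method: str
    features: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    ranks: np.ndarray

    @classmethod
    def from_raw(cls, method: str, features, raw) -> "FeatureScoreTable":
        raw = np.asarray(raw, dtype=float)
        norm = minmax_rescale(raw)
        return cls(
            method=method,
            features=tuple(features),
            raw=raw,
            normalized=norm,
            ranks=_ranks_descending(norm),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "method": self.method,
                "raw": self.raw,
                "normalized": self.normalized,
                "rank": self.ranks,
            }
        )


@dataclass
class CombinedImportance:
    """Fused relevance: mean of the contributing normalized score tables."""

    features: tuple[str, ...]
    combined: np.ndarray
    ranks: np.ndarray
    tables: tuple[FeatureScoreTable, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "combined": self.combined, "rank": self.ranks}
        )


def _check_labels(matrix: EncodedMatrix, labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(labels) != len(matrix.values):
        raise AlignmentError("labels length does not match matrix rows")
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("need at least 2 classes")
    return labels


def impurity_importance(
    matrix: EncodedMatrix,
    labels,
    trees: int = 200,
    seed: int = 0,
) -> FeatureScoreTable:
    """Mean impurity-decrease importances from a random forest.

    The ensemble's per-feature impurity reductions are renormalized to sum
    to 1 so scores are comparable across forests of different sizes.
    """
    labels = _check_labels(matrix, labels)
    forest = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
    forest.fit(matrix.to_numpy(), labels)
    raw = forest.feature_importances_.astype(float)
    total = raw.sum()
    if total > 0:
        raw = raw / total
    return FeatureScoreTable.from_raw("impurity", matrix.columns, raw)


def univariate_f_scores(
    matrix: EncodedMatrix,
    labels,
    variant: str = "raw_ratio",
    seed: int = 0,
) -> FeatureScoreTable:
    """Univariate class-separability scores.

    ``raw_ratio`` computes F_j = S_B / S_W, the raw ratio of
    between-class to within-class sums of squares (no degrees-of-freedom
    scaling).  ``df_adjusted`` multiplies by (n - k)/(k - 1), recovering the
    classical one-way ANOVA F statistic; both variants induce identical
    rankings.  ``mutual_information`` delegates to a k-NN mutual-information
    estimator.  Zero within-class variation with nonzero between-class
    variation yields +inf, flagged rather than raised.
    """
    if variant not in F_VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {F_VARIANTS}")
    labels = _check_labels(matrix, labels)
    X = matrix.to_numpy()
    if variant == "mutual_information":
        raw = mutual_info_classif(X, labels, random_state=seed)
        return FeatureScoreTable.from_raw("mutual_information", matrix.columns, raw)

    classes, inverse = np.unique(labels, return_inverse=True)
    n, k = X.shape[0], len(classes)
    grand = X.mean(axis=0)
    s_b = np.zeros(X.shape[1])
    s_w = np.zeros(X.shape[1])
    for c in range(k):
        sub = X[inverse == c]
        mu = sub.mean(axis=0)
        s_b += len(sub) * (mu - grand) ** 2
        s_w += ((sub - mu) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(s_w > 0, s_b / np.where(s_w > 0, s_w, 1.0), np.where(s_b > 0, np.inf, 0.0))
    if variant == "df_adjusted":
        raw = raw * (n - k) / (k - 1)
    return FeatureScoreTable.from_raw(variant, matrix.columns, raw)


def combine(tables: list[FeatureScoreTable]) -> CombinedImportance:
    """Average >= 2 normalized score tables into the Combined Importance Index."""
    if len(tables) < 2:
        raise ConfigError("combine needs at least 2 score tables")
    base = tables[0].features
    for t in tables[1:]:
        if set(t.features) != set(base):
            raise AlignmentError(
                f"score tables cover different features: {set(base) ^ set(t.features)}"
            )
    stacked = np.stack(
        [
            t.normalized[[t.features.index(f) for f in base]]
            for t in tables
        ]
    )
    combined = stacked.mean(axis=0)
    return CombinedImportance(
        features=base,
        combined=combined,
        ranks=_ranks_descending(combined),
        tables=tuple(tables),
    )


def top_k(combined: CombinedImportance, k: int) -> list[str]:
    """First k features in rank order."""
    m = len(combined.features)
    if not (1 <= k <= m):
        raise ConfigError(f"k must lie in 1..{m}, got {k}")
    order = np.argsort(combined.ranks)
    return [combined.features[i] for i in order[:k]]
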