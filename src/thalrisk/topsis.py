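"""TOPSIS scoring and Pareto risk stratification.

Each patient is scored by relative closeness to an ideal profile: criteria
are min-max scaled, multiplied by AHP weights, and compared against the
positive ideal (columnwise max of the weighted matrix) and negative ideal
(columnwise min) by Euclidean distance.  Closeness C = D- / (D+ + D-) lies
in [0, 1]; higher closeness means higher assessed risk.  Closeness is then
thresholded into High (>= 0.66), Medium ([0.33, 0.66)) and Low (< 0.33)
risk strata, a Pareto-style cut that concentrates clinical attention on the
tail of the score distribution.

All criteria are treated as benefit-direction by default (larger weighted
value = closer to the positive ideal), matching the framework's published
formulation; a per-criterion ``directions`` flag can flip chosen criteria
to cost-direction by reflecting their scaled values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ahp import WeightVector
from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateCohortError,
    DegenerateCriterionError,
)

HIGH_RISK = "High Risk"
MEDIUM_RISK = "Medium Risk"
LOW_RISK = "Low Risk"


@dataclass
class DecisionMatrix:
    """Samples x criteria matrix with scaling bookkeeping."""

    values: np.ndarray
    criteria: tuple[str, ...]
    normalized: bool = False
    weighted: bool = False
    mins: np.ndarray | None = None  # per-criterion extremes used for scaling
    maxs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.criteria):
            raise AlignmentError("decision matrix shape does not match criteria")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DecisionMatrix":
        return cls(values=frame.to_numpy(dtype=float), criteria=tuple(frame.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.criteria)


@dataclass(frozen=True)
class IdealPair:
    """Positive- and negative-ideal profiles of a weighted matrix."""

    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.positive < self.negative):
            raise ConfigError("positive ideal must dominate negative ideal")


@dataclass(frozen=True)
class StratificationConfig:
    """Closeness thresholds for the three risk strata."""

    high: float = 0.66
    low: float = 0.33

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high < 1.0):
            raise ConfigError(f"need 0 < low < high < 1, got {self.low}, {self.high}")


@dataclass
class TopsisResult:
    """Per-sample distances, closeness, rank and risk category."""

    d_plus: np.ndarray
    d_minus: np.ndarray
    closeness: np.ndarray
    ranks: np.ndarray | None = None  # 1 = highest closeness
    categories: np.ndarray | None = None
    config: StratificationConfig | None = None

    def category_counts(self) -> dict[str, int]:
        if self.categories is None:
            raise ConfigError("stratify() has not been applied")
        return {
            cat: int(np.sum(self.categories == cat))
            for cat in (HIGH_RISK, MEDIUM_RISK, LOW_RISK)
        }

    def category_fractions(self) -> dict[str, float]:
        n = len(self.closeness)
        return {k: v / n for k, v in self.category_counts().items()}

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"d_plus": self.d_plus, "d_minus": self.d_minus, "closeness": self.closeness}
        )
        if self.ranks is not None:
            out["rank"] = self.ranks
        if self.categories is not None:
            out["category"] = self.categories
        return out


def minmax_normalize(
    M: DecisionMatrix,
    extremes: tuple[np.ndarray, np.ndarray] | None = None,
) -> DecisionMatrix:
    """Min-max scale each criterion to [0, 1], recording the extremes used.

    With ``extremes`` given (training-fold minima/maxima), new samples are
    scaled against those frozen bounds instead of their own — required when
    scoring held-out data without information leakage.  Frozen scaling can
    produce values outside [0, 1]; they are left unclipped.
    """
    if extremes is None:
        if M.values.shape[0] < 2:
            raise DegenerateCriterionError("need >= 2 samples to fit extremes")
        mins = M.values.min(axis=0)
        maxs = M.values.max(axis=0)
        span = maxs - mins
        flat = np.where(span == 0)[0]
        if len(flat):
            raise DegenerateCriterionError(
                f"criterion {M.criteria[flat[0]]!r} has zero range"
            )
    else:
        mins, maxs = (np.asarray(e, dtype=float) for e in extremes)
        if len(mins) != len(M.criteria) or len(maxs) != len(M.criteria):
            raise AlignmentError("extremes length does not match criteria")
        if np.any(maxs - mins <= 0):
            raise DegenerateCriterionError("frozen extremes have zero range")
    scaled = (M.values - mins) / (maxs - mins)
    return DecisionMatrix(
        values=scaled, criteria=M.criteria, normalized=True, mins=mins, maxs=maxs
    )


def apply_weights(
    M: DecisionMatrix,
    w: WeightVector,
    directions: dict[str, str] | None = None,
) -> DecisionMatrix:
    """Multiply each normalized criterion by its weight.

    ``directions`` may mark criteria as ``"cost"`` — their scaled values are
    reflected (1 - x) before weighting, so that clinically adverse low
    values (e.g. microcytic MCV) can be made risk-increasing.  Default is
    benefit-direction everywhere.
    """
    if not M.normalized:
        raise ConfigError("apply_weights expects a min-max normalized matrix")
    if tuple(w.criteria) != tuple(M.criteria):
        raise AlignmentError(
            f"weight criteria {list(w.criteria)} do not match matrix {list(M.criteria)}"
        )
    vals = M.values.copy()
    if directions:
        unknown = set(directions) - set(M.criteria)
        if unknown:
            raise AlignmentError(f"directions name unknown criteria: {sorted(unknown)}")
        for k, (name) in enumerate(M.criteria):
            if directions.get(name) == "cost":
                vals[:, k] = 1.0 - vals[:, k]
    vals = vals * w.weights
    return DecisionMatrix(
        values=vals, criteria=M.criteria, normalized=True, weighted=True,
        mins=M.mins, maxs=M.maxs,
    )


def ideals(W: DecisionMatrix) -> IdealPair:
    """Columnwise best/worst profiles of the weighted matrix."""
    if W.values.shape[0] < 1:
        raise DegenerateCohortError("need at least one sample")
    return IdealPair(positive=W.values.max(axis=0), negative=W.values.min(axis=0))


def closeness(W: DecisionMatrix, ideal_pair: IdealPair) -> TopsisResult:
    """Euclidean distances to the ideals and relative closeness."""
    if len(ideal_pair.positive) != len(W.criteria):
        raise AlignmentError("ideal length does not match criteria")
    d_plus = np.sqrt(((W.values - ideal_pair.positive) ** 2).sum(axis=1))
    d_minus = np.sqrt(((W.values - ideal_pair.negative) ** 2).sum(axis=1))
    denom = d_plus + d_minus
    if np.any(denom == 0):
        raise DegenerateCohortError(
            "a sample is equidistant-zero from both ideals (all samples identical?)"
        )
    return TopsisResult(d_plus=d_plus, d_minus=d_minus, closeness=d_minus / denom)


def rank(result: TopsisResult) -> TopsisResult:
    """Rank by descending closeness; ties keep input order (stable)."""
    order = np.argsort(-result.closeness, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return replace(result, ranks=ranks)


def stratify(
    result: TopsisResult, cfg: StratificationConfig | None = None
) -> TopsisResult:
    """Assign risk categories: High >= high, Low < low, else Medium."""
    cfg = cfg or StratificationConfig()
    c = result.closeness
    cats = np.where(c >= cfg.high, HIGH_RISK, np.where(c < cfg.low, LOW_RISK, MEDIUM_RISK))
    return replace(result, categories=cats.astype(object), config=cfg)


def score_cohort(
    frame: pd.DataFrame,
    weights: WeightVector,
    *,
    extremes: tuple[np.ndarray, np.ndarray] | None = None,
    ideal_pair: IdealPair | None = None,
    cfg: StratificationConfig | None = None,
    directions: dict[str, str] | None = None,
) -> tuple[TopsisResult, DecisionMatrix, IdealPair]:
    """Convenience pipeline: scale -> weight -> ideals -> closeness -> strata.

    When ``extremes``/``ideal_pair`` are provided (frozen from a training
    fold) they are reused instead of being refit, so held-out samples are
    scored without touching their own statistics.
    """
    M = DecisionMatrix.from_frame(frame[list(weights.criteria)])
    W = apply_weights(minmax_normalize(M, extremes=extremes), weights, directions)
    pair = ideal_pair if ideal_pair is not None else ideals(W)
    res = stratify(rank(closeness(W, pair)), cfg)
    return res, W, pair
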