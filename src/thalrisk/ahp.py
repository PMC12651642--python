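"""Analytic Hierarchy Process: expert weights with consistency diagnostics.

Weights are derived by the column-normalization / row-averaging method:
each matrix entry is divided by its column sum, and the weight of a
criterion is the mean of its normalized row.  Consistency is checked via
the weighted-sum estimate of the principal eigenvalue,

    lambda_max = mean_i (A w)_i / w_i,
    CI = (lambda_max - n) / (n - 1),     CR = CI / RI(n),

with CR < 0.1 the conventional acceptability gate.  The principal
eigenvalue itself is exposed only as a diagnostic cross-check; the
ratio-average estimate is the primary statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ScaleError, ThalriskError

#: Saaty random-consistency index by matrix order.
RANDOM_INDEX = {
    1: 0.0, 2: 0.0, 3: 0.58, 4: 0.90, 5: 1.12,
    6: 1.24, 7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
    11: 1.51, 12: 1.48, 13: 1.56, 14: 1.57, 15: 1.59,
}

RECIPROCITY_TOL = 1e-9


@dataclass(frozen=True)
class PairwiseJudgments:
    """Upper-triangle expert judgments on the 1-9 intensity scale.

    ``values[(i, j)]`` with i < j holds the judgment of criterion i over
    criterion j; reciprocals and the unit diagonal are implicit.  Values
    below 1 (e.g. 1/3) are allowed and mean the column criterion dominates.
    """

    criteria: tuple[str, ...]
    values: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.criteria)
        if n < 2:
            raise ThalriskError("need at least 2 criteria")
        if len(set(self.criteria)) != n:
            raise ThalriskError("criteria names must be unique")
        for (i, j), v in self.values.items():
            if not (0 <= i < j < n):
                raise ThalriskError(f"bad judgment index ({i}, {j})")
            if v <= 0:
                raise ScaleError(f"judgment ({i},{j})={v} must be positive")
            if not (1 / 9 - 1e-12 <= v <= 9 + 1e-12):
                warnings.warn(
                    f"judgment ({i},{j})={v} outside the 1/9..9 Saaty range",
                    stacklevel=2,
                )

    @classmethod
    def from_long_csv(cls, path) -> "PairwiseJudgments":
        """Read (row, column, value) judgments; criteria ordered by first use."""
        df = pd.read_csv(path)
        order: list[str] = []
        for name in list(df["row"]) + list(df["column"]):
            if name not in order:
                order.append(name)
        idx = {name: k for k, name in enumerate(order)}
        values: dict[tuple[int, int], float] = {}
        for _, rec in df.iterrows():
            i, j, v = idx[rec["row"]], idx[rec["column"]], float(rec["value"])
            if i == j:
                continue
            if i > j:
                i, j, v = j, i, 1.0 / v
            values[(i, j)] = v
        return cls(criteria=tuple(order), values=values)

    @classmethod
    def from_matrix(cls, matrix: pd.DataFrame) -> "PairwiseJudgments":
        """Build from a full printed matrix, snapping rounded reciprocals.

        For each pair the entry that is >= 1 (the Saaty-scale integer) is
        taken as authoritative and its reciprocal is recomputed exactly, so
        3-decimal roundings like 0.333 do not leak into the arithmetic.
        """
        names = tuple(matrix.columns)
        A = matrix.to_numpy(dtype=float)
        values = {}
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                values[(i, j)] = A[i, j] if A[i, j] >= 1 else 1.0 / A[j, i]
        return cls(criteria=names, values=values)


@dataclass(frozen=True)
class PairwiseMatrix:
    """Full positive reciprocal comparison matrix."""

    criteria: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        A = self.values
        n = len(self.criteria)
        if A.shape != (n, n):
            raise AlignmentError("matrix shape does not match criteria")
        if np.any(A <= 0):
            raise ScaleError("pairwise matrix entries must be positive")
        if np.max(np.abs(np.diag(A) - 1.0)) > RECIPROCITY_TOL:
            raise ScaleError("pairwise matrix diagonal must be 1")
        if np.max(np.abs(A * A.T - 1.0)) > 1e-6:
            raise ScaleError("pairwise matrix is not reciprocal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.criteria, columns=self.criteria)


@dataclass(frozen=True)
class NormalizedMatrix:
    """Column-stochastic normalization of a pairwise matrix."""

    criteria: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if np.max(np.abs(self.values.sum(axis=0) - 1.0)) > RECIPROCITY_TOL:
            raise ThalriskError("normalized matrix columns must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.criteria, columns=self.criteria)


@dataclass(frozen=True)
class WeightVector:
    """Per-criterion weights, summing to 1."""

    criteria: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.criteria):
            raise AlignmentError("weights/criteria length mismatch")
        if np.any(self.weights <= 0):
            raise ThalriskError("weights must be positive")
        if abs(self.weights.sum() - 1.0) > RECIPROCITY_TOL:
            raise ThalriskError("weights must sum to 1")

    def to_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.criteria, name="weight")


@dataclass(frozen=True)
class ConsistencyReport:
    """Weighted-sum consistency diagnostics for a judgment matrix."""

    weighted_sum: np.ndarray  # A @ w
    lambda_max: float
    ci: float
    ri: float
    cr: float
    acceptable: bool
    principal_eigenvalue: float  # diagnostic cross-check only

    def to_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "ci": self.ci,
            "ri": self.ri,
            "cr": self.cr,
            "acceptable": self.acceptable,
            "principal_eigenvalue": self.principal_eigenvalue,
        }


def build_matrix(judgments: PairwiseJudgments) -> PairwiseMatrix:
    """Expand upper-triangle judgments into a full reciprocal matrix."""
    n = len(judgments.criteria)
    A = np.ones((n, n))
    for (i, j), v in judgments.values.items():
        A[i, j] = v
        A[j, i] = 1.0 / v
    return PairwiseMatrix(criteria=judgments.criteria, values=A)


def normalize_matrix(A: PairwiseMatrix) -> NormalizedMatrix:
    """Divide every entry by its column sum (column-stochastic form)."""
    N = A.values / A.values.sum(axis=0, keepdims=True)
    return NormalizedMatrix(criteria=A.criteria, values=N)


def compute_weights(N: NormalizedMatrix) -> WeightVector:
    """Row means of the normalized matrix; sums to 1 by construction."""
    w = N.values.mean(axis=1)
    w = w / w.sum()  # remove last-bit float drift
    return WeightVector(criteria=N.criteria, weights=w)


def consistency(A: PairwiseMatrix, w: WeightVector) -> ConsistencyReport:
    """Consistency diagnostics from the ratio-average lambda_max."""
    if A.criteria != w.criteria:
        raise AlignmentError("matrix and weights cover different criteria")
    n = len(A.criteria)
    aw = A.values @ w.weights
    lambda_max = float(np.mean(aw / w.weights))
    eig = float(np.max(np.real(np.linalg.eigvals(A.values))))
    if n <= 2:
        ci = 0.0
        ri = RANDOM_INDEX[n]
        cr = 0.0
    else:
        ci = (lambda_max - n) / (n - 1)
        try:
            ri = RANDOM_INDEX[n]
        except KeyError:
            raise ThalriskError(f"no random index tabulated for n={n}") from None
        cr = ci / ri
    return ConsistencyReport(
        weighted_sum=aw,
        lambda_max=lambda_max,
        ci=ci,
        ri=ri,
        cr=cr,
        acceptable=cr < 0.1,
        principal_eigenvalue=eig,
    )


def derive_weights(judgments: PairwiseJudgments) -> tuple[WeightVector, ConsistencyReport]:
    """Full pipeline: judgments -> matrix -> normalization -> weights + CR."""
    A = build_matrix(judgments)
    w = compute_weights(normalize_matrix(A))
    return w, consistency(A, w)
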