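"""Attribution orchestration and statistical validation.

Global per-sample feature attributions are obtained from the boosting
backends' native tree-path Shapley-value decompositions (each prediction
margin equals a base value plus the per-feature contributions).  Local
explanations use a perturbation-based linear surrogate: binary feature
masks are drawn around the instance, the model is queried on the perturbed
points, and a distance-kernel-weighted ridge regression on the masks gives
per-feature local weights.

Attribution differences are then validated statistically: a
Kruskal-Wallis test per feature across risk classes, and a symmetric
matrix of two-sided Mann-Whitney U p-values over all feature pairs,
optionally Benjamini-Hochberg adjusted, exportable as a heatmap in which
darker cells mean lower p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, ThalriskError
from .schema import EncodedMatrix

EXACT_MWU_MAX_N = 8  # exact null enumeration up to this group size


@dataclass
class ExplanationSet:
    """Samples x features attribution matrix plus the model's base value."""

    values: pd.DataFrame  # signed attributions
    base_value: float
    class_label: object = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ThalriskError("attribution values must be finite")

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def mean_abs(self) -> pd.Series:
        return self.values.abs().mean(axis=0).sort_values(ascending=False)


@dataclass
class LocalExplanation:
    """Kernel-weighted surrogate coefficients for one instance."""

    instance_id: object
    weights: pd.Series  # per-feature local weight (signed)
    directions: pd.Series  # "supports" / "opposes"
    n_perturb: int
    seed: int


@dataclass
class SignificanceReport:
    """Kruskal-Wallis and pairwise Mann-Whitney results on attributions."""

    kruskal: pd.DataFrame | None = None  # feature, H, p
    mwu_matrix: pd.DataFrame | None = None  # symmetric p-value matrix
    alpha: float = 0.05
    correction: str = "none"
    tie_flags: tuple[tuple[str, str], ...] = ()

    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.mwu_matrix is None:
            raise ConfigError("pairwise matrix not computed")
        out = []
        cols = list(self.mwu_matrix.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if self.mwu_matrix.loc[a, b] < self.alpha:
                    out.append((a, b))
        return out


def _margin_contributions(model, X: np.ndarray):
    """Backend tree-path (Shapley) contributions; (n, features+1) array(s)."""
    name = type(model).__name__
    if name == "XGBClassifier":
        import xgboost as xgb

        booster = model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return np.asarray(contrib)
    if name == "LGBMClassifier":
        contrib = model.predict(X, pred_contrib=True)
        contrib = np.asarray(contrib)
        n_class = len(model.classes_)
        if n_class > 2 and contrib.ndim == 2:
            contrib = contrib.reshape(len(X), n_class, -1)
        return contrib
    raise ConfigError(
        f"no native tree-path attribution backend for {name}; "
        "use a gradient-boosted model"
    )


def global_attributions(
    model,
    matrix: EncodedMatrix,
    class_label: object = None,
) -> ExplanationSet:
    """Per-sample signed attributions from the trained boosting backend.

    For multiclass models ``class_label`` selects which class margin to
    decompose (default: the first model class).  Additivity holds: base
    value + row sum equals the model's raw margin for that class.
    """
    n_features = len(matrix.columns)
    if getattr(model, "n_features_in_", n_features) != n_features:
        raise AlignmentError("model was trained on a different column set")
    contrib = _margin_contributions(model, matrix.to_numpy())
    classes = list(getattr(model, "classes_", []))
    if contrib.ndim == 3:  # (n, class, feature+1)
        if class_label is None:
            class_index = 0
        else:
            class_index = classes.index(class_label)
        contrib = contrib[:, class_index, :]
        label = classes[class_index]
    else:
        label = class_label if class_label is not None else (classes[-1] if classes else None)
    values = pd.DataFrame(contrib[:, :-1], columns=matrix.columns)
    base = float(contrib[:, -1].mean())
    return ExplanationSet(values=values, base_value=base, class_label=label)


def local_explanation(
    model,
    instance: np.ndarray,
    background: np.ndarray,
    *,
    n_perturb: int = 1000,
    seed: int = 0,
    kernel_width: float | None = None,
    top_k: int | None = None,
    instance_id: object = None,
    ridge: float = 1e-3,
) -> LocalExplanation:
    """Local surrogate explanation of one prediction.

    Perturbed samples replace a random subset of features with the
    background (training-set) mean; each perturbation is weighted by an
    exponential kernel exp(-d^2 / sigma^2) on the mask distance to the
    instance, and a weighted ridge fit of the model's predicted probability
    on the masks yields signed local weights.
    """
    if n_perturb < 10:
        raise ConfigError(f"n_perturb must be >= 10, got {n_perturb}")
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    m = len(instance)
    if background.shape[1] != m:
        raise AlignmentError("background columns do not match instance length")
    mean_bg = background.mean(axis=0)

    rng = np.random.default_rng(seed)
    masks = rng.integers(0, 2, size=(n_perturb, m)).astype(float)
    masks[0] = 1.0  # anchor: the instance itself
    perturbed = masks * instance + (1 - masks) * mean_bg

    proba = model.predict_proba(perturbed)
    target = int(np.argmax(model.predict_proba(instance.reshape(1, -1))[0]))
    y = proba[:, target]

    sigma = kernel_width if kernel_width is not None else np.sqrt(m) * 0.75
    d2 = ((1 - masks) ** 2).sum(axis=1)
    kernel = np.exp(-d2 / sigma**2)

    # weighted ridge on the binary masks
    W = np.diag(kernel)
    Z = np.column_stack([np.ones(n_perturb), masks])
    A = Z.T @ W @ Z + ridge * np.eye(m + 1)
    coef = np.linalg.solve(A, Z.T @ W @ y)[1:]

    names = [f"x{i}" for i in range(m)]
    weights = pd.Series(coef, index=names)
    if top_k is not None:
        keep = weights.abs().sort_values(ascending=False).index[:top_k]
        weights = weights.loc[keep]
    directions = weights.map(lambda v: "supports" if v >= 0 else "opposes")
    return LocalExplanation(
        instance_id=instance_id,
        weights=weights,
        directions=directions,
        n_perturb=n_perturb,
        seed=seed,
    )


def kruskal_by_class(explanations: ExplanationSet, classes) -> SignificanceReport:
    """Per-feature Kruskal-Wallis H across risk classes."""
    classes = np.asarray(classes)
    if len(classes) != len(explanations.values):
        raise AlignmentError("class vector length does not match attributions")
    uniq, counts = np.unique(classes, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ConfigError("need >= 2 classes with >= 2 samples each")
    rows = []
    for feat in explanations.features:
        groups = [
            explanations.values[feat].to_numpy()[classes == c] for c in uniq
        ]
        if np.ptp(np.concatenate(groups)) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append({"feature": feat, "H": float(h), "p": float(p)})
    return SignificanceReport(kruskal=pd.DataFrame(rows))


def mann_whitney_p(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided Mann-Whitney U p-value with the package's method rule.

    Exact null enumeration when both groups have <= 8 observations and the
    pooled sample is tie-free; normal approximation with tie correction
    otherwise.  Returns (p, tie_degenerate) where the flag marks a pair
    whose pooled values are all identical (p fixed at 1).
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0, True
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MWU_MAX_N and len(y) <= EXACT_MWU_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0)), False


def pairwise_mwu(
    explanations: ExplanationSet,
    *,
    use_absolute: bool = False,
    correction: str = "none",
    alpha: float = 0.05,
) -> SignificanceReport:
    """Symmetric matrix of two-sided Mann-Whitney U p-values over feature pairs.

    Compares the per-sample attribution distribution of every feature pair.
    ``use_absolute`` switches from signed to |attribution| values.
    ``correction="benjamini_hochberg"`` adjusts the upper triangle.
    """
    feats = explanations.features
    if len(feats) < 2:
        raise ConfigError("need >= 2 features")
    vals = explanations.values.abs() if use_absolute else explanations.values
    if len(vals) < 3:
        raise ConfigError("need >= 3 samples")
    n = len(feats)
    P = np.ones((n, n))
    tie_flags = []
    upper = []
    for i in range(n):
        for j in range(i + 1, n):
            p, tied = mann_whitney_p(vals.iloc[:, i].to_numpy(), vals.iloc[:, j].to_numpy())
            P[i, j] = P[j, i] = p
            if tied:
                tie_flags.append((feats[i], feats[j]))
            upper.append((i, j))
    if correction == "benjamini_hochberg":
        raw = np.array([P[i, j] for i, j in upper])
        adj = stats.false_discovery_control(raw, method="bh")
        for (i, j), p in zip(upper, adj):
            P[i, j] = P[j, i] = min(float(p), 1.0)
    elif correction != "none":
        raise ConfigError(f"unknown correction {correction!r}")
    matrix = pd.DataFrame(P, index=feats, columns=feats)
    return SignificanceReport(
        mwu_matrix=matrix, alpha=alpha, correction=correction, tie_flags=tuple(tie_flags)
    )


def heatmap_export(report: SignificanceReport, path) -> tuple[str, str]:
    """Render the p-value matrix (darker = lower p) and write it as CSV.

    Returns (image_path, csv_path).  The grayscale map is monotone in p:
    cell luminance equals the p-value, so p=0 is black and p=1 is white.
    """
    if report.mwu_matrix is None:
        raise ConfigError("pairwise matrix not computed")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    M = report.mwu_matrix
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * len(M)),) * 2)
    im = ax.imshow(M.to_numpy(), cmap="gray", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(len(M)), M.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(M)), M.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="p-value")
    ax.set_title(f"Pairwise Mann-Whitney U p-values ({report.correction})")
    fig.tight_layout()
    img_path = str(path)
    fig.savefig(img_path, dpi=150)
    plt.close(fig)
    csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    M.to_csv(csv_path)
    return img_path, csv_path
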