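"""Leakage-safe stratified cross-validation benchmark.

The harness reproduces the structure of the framework's validation
protocol: risk labels are TOPSIS strata, and every data-dependent step —
min-max extremes, feature scoring/selection, TOPSIS ideals — is fit on the
training part of each fold only.  Held-out samples are scored against the
frozen training-fold extremes and ideals, then each classifier is trained
on the (optionally MCDM-weighted) training features and evaluated on the
held-out fold.

Because the labels are a deterministic function of the features, held-out
accuracy is expected to be near-ceiling; the harness exists to compare
models and conditions under identical folds, not to certify clinical
generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold

from . import reference
from .ahp import PairwiseJudgments, WeightVector, derive_weights
from .errors import (
    AlignmentError,
    ConfigError,
    ConsistencyGateError,
    StratificationError,
    ThalriskError,
)
from .importance import combine, impurity_importance, top_k, univariate_f_scores
from .schema import Cohort, EncodedMatrix, encode
from .topsis import StratificationConfig, score_cohort

#: Concurrent hematologic manifestations of the disease.
DIAGNOSTIC_FEATURES = ("Hct", "MCV", "MCH", "MCHC", "RDW", "Hemoglobin_Level", "RBC_Count")
#: Antecedent / contextual predictors.
ETIOLOGY_FEATURES = (
    "Age",
    "BMI",
    "Family_History_Thalassemia",
    "Genetic_Marker_Presence",
    "Socioeconomic_Status",
    "Education_Level",
    "Residence",
    "Parity",
    "Carrier_Status",
)

MODES = ("diagnostic", "etiology", "all_features")
CONDITIONS = ("with_mcdm", "without_mcdm")


def _make_random_forest(seed: int, params: dict):
    defaults = {"n_estimators": 200, "random_state": seed, "n_jobs": 1}
    defaults.update(params)
    return RandomForestClassifier(**defaults)


def _make_xgboost(seed: int, params: dict):
    from xgboost import XGBClassifier

    defaults = {
        "n_estimators": 200,
        "max_depth": 4,
        "learning_rate": 0.2,
        "random_state": seed,
        "verbosity": 0,
        "n_jobs": 1,
    }
    defaults.update(params)
    return XGBClassifier(**defaults)


def _make_lightgbm(seed: int, params: dict):
    from lightgbm import LGBMClassifier

    defaults = {
        "n_estimators": 200,
        "max_depth": -1,
        "learning_rate": 0.1,
        "random_state": seed,
        "verbose": -1,
        "n_jobs": 1,
    }
    defaults.update(params)
    return LGBMClassifier(**defaults)


#: Registered classifier backends.  ``ordered_boosting`` is served by
#: LightGBM's gradient boosting implementation.
ALGORITHMS = {
    "random_forest": _make_random_forest,
    "extreme_gradient_boosting": _make_xgboost,
    "ordered_boosting": _make_lightgbm,
}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier id plus fixed params and an optional tuning grid."""

    algorithm: str
    params: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)  # name -> candidate values
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"unknown algorithm {self.algorithm!r}; registered: {sorted(ALGORITHMS)}"
            )

    def build(self):
        return ALGORITHMS[self.algorithm](self.seed, dict(self.params))


@dataclass(frozen=True)
class FoldPlan:
    """Stratified fold assignment per sample."""

    k: int
    seed: int
    stratified: bool
    assignment: np.ndarray  # fold index per sample

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.where(self.assignment == fold)[0]
        train = np.where(self.assignment != fold)[0]
        return train, test


def make_folds(labels, k: int = 20, seed: int = 0, stratified: bool = True) -> FoldPlan:
    """Deterministic (stratified) k-fold partition of the samples."""
    labels = np.asarray(labels)
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if stratified:
        _, counts = np.unique(labels, return_counts=True)
        if counts.min() < k:
            raise StratificationError(
                f"smallest class has {counts.min()} members < k={k}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(labels)), labels)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(labels))
        splits = ((None, chunk) for chunk in np.array_split(perm, k))
    assignment = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = f
    return FoldPlan(k=k, seed=seed, stratified=stratified, assignment=assignment)


@dataclass
class ConfusionCounts:
    """Class x class contingency table with one-vs-rest marginals."""

    classes: tuple
    table: np.ndarray  # rows = true class, columns = predicted class

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=None) -> "ConfusionCounts":
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        classes = tuple(classes)
        idx = {c: i for i, c in enumerate(classes)}
        table = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            table[idx[t], idx[p]] += 1
        return cls(classes=classes, table=table)

    def one_vs_rest(self, class_index: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for one class against the rest."""
        t = self.table
        tp = t[class_index, class_index]
        fp = t[:, class_index].sum() - tp
        fn = t[class_index, :].sum() - tp
        tn = t.sum() - tp - fp - fn
        return int(tp), int(tn), int(fp), int(fn)


@dataclass
class MetricsReport:
    """Accuracy, precision, recall, F1 and MCC, overall and per class."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    mcc: float
    per_class: pd.DataFrame
    averaging: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
            "averaging": self.averaging,
            "flags": list(self.flags),
        }


def _safe_div(num: float, den: float, flags: list, tag: str) -> float:
    if den == 0:
        flags.append(tag)
        return 0.0
    return num / den


def metrics(confusion: ConfusionCounts, averaging: str = "macro") -> MetricsReport:
    """Evaluate the metric suite from a contingency table.

    Per-class precision/recall/F1/MCC use one-vs-rest counts; overall
    values are macro (mean over classes) or micro averages.  The overall
    multiclass MCC uses the generalized contingency-table form, which
    reduces to the familiar binary formula for two classes.  Undefined
    ratios (zero denominators) are reported as 0 and flagged.
    """
    if averaging not in {"macro", "micro"}:
        raise ConfigError(f"averaging must be macro or micro, got {averaging!r}")
    t = confusion.table
    total = t.sum()
    if total == 0:
        raise ConfigError("empty confusion table")
    flags: list[str] = []

    rows = []
    for i, cname in enumerate(confusion.classes):
        tp, tn, fp, fn = confusion.one_vs_rest(i)
        prec = _safe_div(tp, tp + fp, flags, f"precision_zero_den:{cname}")
        rec = _safe_div(tp, tp + fn, flags, f"recall_zero_den:{cname}")
        f1 = _safe_div(2 * prec * rec, prec + rec, flags, f"f1_zero_den:{cname}")
        mcc_den = np.sqrt(
            float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
        )
        mcc = _safe_div(tp * tn - fp * fn, mcc_den, flags, f"mcc_zero_den:{cname}")
        rows.append(
            {
                "class": cname, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
                "precision": prec, "recall": rec, "f1": f1, "mcc": mcc,
            }
        )
    per_class = pd.DataFrame(rows)

    accuracy = np.trace(t) / total
    if averaging == "macro":
        precision = float(per_class["precision"].mean())
        recall = float(per_class["recall"].mean())
        f1 = float(per_class["f1"].mean())
    else:
        tp_sum = sum(confusion.one_vs_rest(i)[0] for i in range(len(confusion.classes)))
        fp_sum = sum(confusion.one_vs_rest(i)[2] for i in range(len(confusion.classes)))
        fn_sum = sum(confusion.one_vs_rest(i)[3] for i in range(len(confusion.classes)))
        precision = _safe_div(tp_sum, tp_sum + fp_sum, flags, "precision_zero_den:micro")
        recall = _safe_div(tp_sum, tp_sum + fn_sum, flags, "recall_zero_den:micro")
        f1 = _safe_div(2 * precision * recall, precision + recall, flags, "f1_zero_den:micro")

    # generalized multiclass MCC from the contingency table
    s = float(total)
    c = float(np.trace(t))
    t_k = t.sum(axis=1).astype(float)  # true-class totals
    p_k = t.sum(axis=0).astype(float)  # predicted-class totals
    den = np.sqrt(s**2 - (p_k**2).sum()) * np.sqrt(s**2 - (t_k**2).sum())
    mcc = _safe_div(c * s - (t_k * p_k).sum(), den, flags, "mcc_zero_den:overall")

    return MetricsReport(
        accuracy=float(accuracy),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        mcc=float(mcc),
        per_class=per_class,
        averaging=averaging,
        flags=tuple(flags),
    )


@dataclass
class FoldRecord:
    """Everything computed for one (model, condition, fold) cell."""

    model: str
    condition: str
    fold: int
    metrics: MetricsReport | None
    selected_features: tuple[str, ...]
    weights: dict[str, float]
    train_indices: np.ndarray
    scale_mins: np.ndarray
    scale_maxs: np.ndarray
    ideal_positive: np.ndarray
    ideal_negative: np.ndarray
    failed: bool = False
    failure_reason: str = ""


@dataclass
class BenchmarkReport:
    """Fold-wise records plus tidy/summary views."""

    records: list[FoldRecord]
    plan: FoldPlan
    mode: str
    criteria: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            if r.failed:
                continue
            for metric in ("accuracy", "precision", "recall", "f1", "mcc"):
                rows.append(
                    {
                        "model": r.model,
                        "condition": r.condition,
                        "fold": r.fold,
                        "metric": metric,
                        "value": getattr(r.metrics, metric),
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        tidy = self.to_frame()
        return (
            tidy.groupby(["model", "condition", "metric"])["value"]
            .agg(["mean", "std"])
            .reset_index()
        )


def _mode_columns(matrix: EncodedMatrix, cohort: Cohort, mode: str) -> list[str]:
    if mode == "all_features":
        names = cohort.schema.names
    elif mode == "diagnostic":
        names = list(DIAGNOSTIC_FEATURES)
    elif mode == "etiology":
        names = list(ETIOLOGY_FEATURES)
    else:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")
    cols: list[str] = []
    for name in names:
        enc = matrix.encoding[name]
        if enc["kind"] == "nominal":
            cols.extend(enc["columns"])
        else:
            cols.append(name)
    return cols


def run_cv(
    cohort: Cohort,
    modelspecs: list[ModelSpec],
    *,
    k: int = 20,
    seed: int = 0,
    condition: str = "with_mcdm",
    judgments: PairwiseJudgments | None = None,
    strat_cfg: StratificationConfig | None = None,
    mode: str = "all_features",
    n_selected: int = 10,
    importance_trees: int = 100,
    override_cr: bool = False,
) -> BenchmarkReport:
    """Benchmark classifiers on TOPSIS-derived risk strata.

    Per fold, fit on the training part only: min-max extremes, the AHP
    weights (data-independent), the TOPSIS ideals, the training strata
    labels, and the fold's feature scoring/selection.  Held-out samples are
    scaled and scored with the frozen training extremes/ideals and the same
    thresholds; classifiers never see held-out statistics.

    ``condition`` toggles MCDM feature weighting of the classifier inputs
    only — fold assignment and labels are shared across conditions, so the
    comparison is paired.
    """
    if condition not in CONDITIONS:
        raise ConfigError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    strat_cfg = strat_cfg or StratificationConfig()
    judgments = judgments or reference.load_table7_judgments()
    weights, report = derive_weights(judgments)
    if not report.acceptable and not override_cr:
        raise ConsistencyGateError(
            f"judgments fail the CR < 0.1 gate (CR={report.cr:.4f}); "
            "pass override_cr=True to proceed anyway"
        )

    matrix = encode(cohort)
    missing = [c for c in weights.criteria if c not in matrix.columns]
    if missing:
        raise AlignmentError(f"judgment criteria not in encoded cohort: {missing}")

    criteria_frame = matrix.values[list(weights.criteria)]
    # provisional whole-cohort strata are used ONLY to stratify the folds;
    # the evaluated labels are re-derived per fold from training data alone
    provisional, _, _ = score_cohort(criteria_frame, weights, cfg=strat_cfg)
    plan = make_folds(provisional.categories, k=k, seed=seed)

    candidate_cols = _mode_columns(matrix, cohort, mode)
    records: list[FoldRecord] = []
    for fold in range(plan.k):
        train_idx, test_idx = plan.indices(fold)
        train_crit = criteria_frame.iloc[train_idx]
        test_crit = criteria_frame.iloc[test_idx]

        train_res, train_W, ideal_pair = score_cohort(train_crit, weights, cfg=strat_cfg)
        extremes = (train_W.mins, train_W.maxs)
        test_res, _, _ = score_cohort(
            test_crit, weights, extremes=extremes, ideal_pair=ideal_pair, cfg=strat_cfg
        )
        y_train = train_res.categories
        y_test = test_res.categories

        common = dict(
            fold=fold,
            train_indices=train_idx,
            scale_mins=train_W.mins,
            scale_maxs=train_W.maxs,
            ideal_positive=ideal_pair.positive,
            ideal_negative=ideal_pair.negative,
            weights=dict(zip(weights.criteria, weights.weights)),
        )
        if len(np.unique(y_train)) < 2:
            for spec in modelspecs:
                records.append(
                    FoldRecord(
                        model=spec.algorithm, condition=condition, metrics=None,
                        selected_features=(), failed=True,
                        failure_reason="training fold has a single stratum", **common,
                    )
                )
            continue

        # in-fold feature scoring and selection over the mode's candidates
        sub = EncodedMatrix(
            values=matrix.values[candidate_cols].iloc[train_idx].reset_index(drop=True),
            encoding=matrix.encoding,
        )
        tables = [
            impurity_importance(sub, y_train, trees=importance_trees, seed=seed),
            univariate_f_scores(sub, y_train, variant="raw_ratio"),
        ]
        selected = tuple(top_k(combine(tables), min(n_selected, len(candidate_cols))))

        # scale classifier inputs with training-fold extremes only
        X_all = matrix.values[list(selected)].to_numpy(dtype=float)
        X_train_raw = X_all[train_idx]
        lo = X_train_raw.min(axis=0)
        hi = X_train_raw.max(axis=0)
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        X_scaled = (X_all - lo) / span
        if condition == "with_mcdm":
            w_map = dict(zip(weights.criteria, weights.weights))
            col_w = np.array([w_map.get(c, 1.0) for c in selected])
            X_scaled = X_scaled * col_w

        classes = sorted(set(y_train) | set(y_test))
        class_codes = {c: i for i, c in enumerate(classes)}
        yt = np.array([class_codes[c] for c in y_train])
        for spec in modelspecs:
            model = spec.build()
            model.fit(X_scaled[train_idx], yt)
            pred_codes = model.predict(X_scaled[test_idx])
            inv = {i: c for c, i in class_codes.items()}
            y_pred = np.array([inv[int(p)] for p in pred_codes], dtype=object)
            conf = ConfusionCounts.from_predictions(y_test, y_pred, classes=classes)
            records.append(
                FoldRecord(
                    model=spec.algorithm, condition=condition,
                    metrics=metrics(conf), selected_features=selected, **common,
                )
            )
    return BenchmarkReport(
        records=records, plan=plan, mode=mode, criteria=tuple(weights.criteria)
    )


def verify_no_leakage(
    report: BenchmarkReport,
    cohort: Cohort,
    judgments: PairwiseJudgments | None = None,
    *,
    strat_cfg: StratificationConfig | None = None,
    n_selected: int = 10,
    importance_trees: int = 100,
    seed: int = 0,
    atol: float = 1e-12,
) -> bool:
    """Audit a benchmark: recompute every fold's frozen statistics from the
    recorded training indices alone and compare with what was stored.

    Returns True when all extremes, ideals and selected feature lists are
    reproducible from training data; raises otherwise.
    """
    strat_cfg = strat_cfg or StratificationConfig()
    judgments = judgments or reference.load_table7_judgments()
    weights, _ = derive_weights(judgments)
    matrix = encode(cohort)
    criteria_frame = matrix.values[list(weights.criteria)]
    candidate_cols = _mode_columns(matrix, cohort, report.mode)

    seen: set[tuple[str, int]] = set()
    for rec in report.records:
        if rec.failed or (rec.condition, rec.fold) in seen:
            continue
        seen.add((rec.condition, rec.fold))
        train_crit = criteria_frame.iloc[rec.train_indices]
        res, W, pair = score_cohort(train_crit, weights, cfg=strat_cfg)
        if not (
            np.allclose(W.mins, rec.scale_mins, atol=atol)
            and np.allclose(W.maxs, rec.scale_maxs, atol=atol)
            and np.allclose(pair.positive, rec.ideal_positive, atol=atol)
            and np.allclose(pair.negative, rec.ideal_negative, atol=atol)
        ):
            raise ThalriskError(f"fold {rec.fold}: extremes/ideals not reproducible")
        sub = EncodedMatrix(
            values=matrix.values[candidate_cols].iloc[rec.train_indices].reset_index(drop=True),
            encoding=matrix.encoding,
        )
        tables = [
            impurity_importance(sub, res.categories, trees=importance_trees, seed=seed),
            univariate_f_scores(sub, res.categories, variant="raw_ratio"),
        ]
        selected = tuple(top_k(combine(tables), min(n_selected, len(candidate_cols))))
        if selected != rec.selected_features:
            raise ThalriskError(f"fold {rec.fold}: selected features not reproducible")
    return True


def grid_search(
    matrix: EncodedMatrix,
    labels,
    spec: ModelSpec,
    inner_k: int = 3,
) -> ModelSpec:
    """Pick the grid point with the best inner-CV mean accuracy (ties: first)."""
    if inner_k < 2:
        raise ConfigError(f"inner_k must be >= 2, got {inner_k}")
    if not spec.grid:
        return spec
    labels = np.asarray(labels)
    X = matrix.to_numpy()
    splitter = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=spec.seed)
    best_params, best_score = None, -np.inf
    for params in ParameterGrid(spec.grid):
        accs = []
        for train_idx, test_idx in splitter.split(X, labels):
            model = ALGORITHMS[spec.algorithm](spec.seed, {**spec.params, **params})
            model.fit(X[train_idx], labels[train_idx])
            accs.append(float(np.mean(model.predict(X[test_idx]) == labels[test_idx])))
        score = float(np.mean(accs))
        if score > best_score:  # strict: first grid point wins ties
            best_score, best_params = score, params
    return ModelSpec(
        algorithm=spec.algorithm,
        params={**spec.params, **best_params},
        grid={},
        seed=spec.seed,
    )
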