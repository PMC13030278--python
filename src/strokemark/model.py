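"""Binary mRS outcome modelling on the imaging feature table.

Protocol: median-impute nulls (training statistics only), univariate
one-way ANOVA F scores per feature with the top k (default 17) retained,
a stratified 80/20 train/test split, grid-searched tree-ensemble
classifiers under 5-fold cross-validation on the training set only, and
held-out evaluation with percentile-bootstrap 95% confidence intervals
plus impurity- and permutation-based feature importances.

The split happens first; every fitted statistic downstream (medians, F
scores, grid search) sees training rows only, so the held-out subset is
touched exactly once, at evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.inspection import permutation_importance
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .errors import DegenerateLabelsError, StrokemarkError

#: Modest default grids; the exact grids of the source protocol are not
#: published, so these are package defaults documented in the config.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random-forest": {
        "n_estimators": [200],
        "max_depth": [None, 4],
        "min_samples_leaf": [1, 3],
    },
    "gradient-boosting": {
        "n_estimators": [200],
        "max_depth": [2, 3],
        "learning_rate": [0.1],
    },
    "xgboost": {
        "n_estimators": [200],
        "max_depth": [2, 3],
        "learning_rate": [0.1],
    },
}


@dataclass(frozen=True)
class ModelConfig:
    k_select: int = 17
    test_fraction: float = 0.2
    cv_folds: int = 5
    family: str = "random-forest"
    grid: dict[str, list] | None = None
    bootstrap_reps: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0,1)")
        if self.k_select < 1:
            raise ValueError("k_select must be >= 1")


@dataclass
class EvaluationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_auc: float | None
    mcc: float
    ci: dict[str, tuple[float, float] | None]
    tp: int
    fp: int
    tn: int
    fn: int
    n_test: int


@dataclass
class ImportanceReport:
    feature_names: list[str]
    impurity: np.ndarray | None
    permutation_mean: np.ndarray
    permutation_std: np.ndarray

    @property
    def ranking(self) -> list[str]:
        """Features ordered by decreasing permutation importance."""
        order = np.argsort(-self.permutation_mean, kind="stable")
        return [self.feature_names[i] for i in order]


@dataclass
class OutcomeAnalysis:
    """Full result bundle of :func:`run_outcome_analysis`."""

    selected_features: list[str]
    f_scores: np.ndarray
    best_params: dict[str, Any]
    model: Any
    report: EvaluationReport
    importance: ImportanceReport
    n_train: int
    n_test: int


# ------------------------------------------------------------ building blocks


def impute_median(X: np.ndarray, medians: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN cells column-wise by the given (training) medians.

    When ``medians`` is None they are computed from ``X`` itself — callers
    must pass training medians when transforming held-out rows. Columns
    that are entirely NaN impute to 0.
    """
    X = np.asarray(X, dtype=float)
    if medians is None:
        with np.errstate(all="ignore"):
            medians = np.nanmedian(X, axis=0)
        medians = np.nan_to_num(medians, nan=0.0)
    out = X.copy()
    rows, cols = np.nonzero(np.isnan(out))
    out[rows, cols] = medians[cols]
    return out, medians


def anova_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each column between the two classes."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelsError("ANOVA needs both outcome classes present")
    # constant columns legitimately yield NaN F scores and rank last in
    # select_top_k; silence the library chatter about them
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, _ = f_classif(np.asarray(X, dtype=float), y)
    return np.asarray(F, dtype=float)


def select_top_k(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest scores; ties break toward lower index.

    Non-finite scores (constant features) rank last.
    """
    scores = np.asarray(scores, dtype=float)
    if k > len(scores):
        raise StrokemarkError(f"k={k} exceeds {len(scores)} features")
    keys = np.where(np.isfinite(scores), scores, -np.inf)
    order = np.argsort(-keys, kind="stable")
    return np.sort(order[:k])


def stratified_split(
    X: np.ndarray, y: np.ndarray, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """(train_idx, test_idx) with per-class proportional allocation."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DegenerateLabelsError("stratified split needs >= 2 members per class")
    idx = np.arange(len(y))
    train, test = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train), np.sort(test)


def _make_estimator(family: str, seed: int):
    if family == "random-forest":
        return RandomForestClassifier(random_state=seed)
    if family == "gradient-boosting":
        return GradientBoostingClassifier(random_state=seed)
    if family == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover
            raise StrokemarkError("xgboost backend not installed") from exc
        return XGBClassifier(random_state=seed, eval_metric="logloss")
    raise StrokemarkError(f"unknown classifier family {family!r}")


def train_with_cv(
    X_train: np.ndarray, y_train: np.ndarray, config: ModelConfig
) -> tuple[Any, dict[str, Any]]:
    """Grid search (mean CV F1) on the training set; refit the best point."""
    grid = config.grid if config.grid is not None else DEFAULT_GRIDS[config.family]
    if not grid:
        raise StrokemarkError("empty hyperparameter grid")
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        _make_estimator(config.family, config.seed),
        param_grid=grid,
        scoring="f1",
        cv=cv,
        refit=True,
    )
    search.fit(X_train, y_train)
    return search.best_estimator_, dict(search.best_params_)


_METRICS: dict[str, Callable] = {
    "accuracy": lambda yt, yp, ys: accuracy_score(yt, yp),
    "precision": lambda yt, yp, ys: precision_score(yt, yp, zero_division=0),
    "recall": lambda yt, yp, ys: recall_score(yt, yp, zero_division=0),
    "f1": lambda yt, yp, ys: f1_score(yt, yp, zero_division=0),
    "mcc": lambda yt, yp, ys: matthews_corrcoef(yt, yp),
    "roc_auc": lambda yt, yp, ys: roc_auc_score(yt, ys),
}


def bootstrap_ci(
    metric: Callable,
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float] | None:
    """Percentile bootstrap CI of a metric over test-set resamples.

    Resamples (with replacement, size n) of the test rows; resamples on
    which the metric is undefined (e.g. single-class for ROC-AUC) are
    skipped. Returns None when every resample was undefined.
    """
    if reps < 100:
        raise StrokemarkError("bootstrap needs >= 100 repetitions")
    import warnings

    rng = np.random.default_rng(seed)
    n = len(y_true)
    stats = []
    with warnings.catch_warnings():
        # single-class resamples are expected and handled; keep them quiet
        warnings.simplefilter("ignore")
        for _ in range(reps):
            pick = rng.integers(0, n, size=n)
            yt = y_true[pick]
            try:
                if len(np.unique(yt)) < 2 and metric is _METRICS["roc_auc"]:
                    continue
                stats.append(metric(yt, y_pred[pick], y_score[pick]))
            except ValueError:
                continue
    if not stats:
        return None
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def evaluate(
    model: Any,
    X_test: np.ndarray,
    y_test: np.ndarray,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> EvaluationReport:
    """Held-out metrics with bootstrap CIs.

    A single-class test set null-flags ROC-AUC but reports the
    confusion-matrix metrics.
    """
    if len(y_test) == 0:
        raise StrokemarkError("empty test set")
    y_pred = model.predict(X_test)
    y_score = model.predict_proba(X_test)[:, 1]
    cm = confusion_matrix(y_test, y_pred, labels=[0, 1])
    tn, fp, fn, tp = (int(v) for v in cm.ravel())
    single_class = len(np.unique(y_test)) < 2
    point = {
        name: (None if (name == "roc_auc" and single_class) else float(fn_(y_test, y_pred, y_score)))
        for name, fn_ in _METRICS.items()
    }
    cis = {
        name: (
            None
            if point[name] is None
            else bootstrap_ci(fn_, y_test, y_pred, y_score, reps, level, seed)
        )
        for name, fn_ in _METRICS.items()
    }
    return EvaluationReport(
        accuracy=point["accuracy"],
        precision=point["precision"],
        recall=point["recall"],
        f1=point["f1"],
        roc_auc=point["roc_auc"],
        mcc=point["mcc"],
        ci=cis,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        n_test=len(y_test),
    )


def feature_importance(
    model: Any,
    X_test: np.ndarray,
    y_test: np.ndarray,
    feature_names: list[str],
    reps: int = 20,
    seed: int = 0,
) -> ImportanceReport:
    """Impurity importances from the trees plus permutation importances
    measured on held-out data only."""
    impurity = getattr(model, "feature_importances_", None)
    if impurity is not None:
        impurity = np.asarray(impurity, dtype=float)
    perm = permutation_importance(
        model, X_test, y_test, n_repeats=reps, random_state=seed
    )
    return ImportanceReport(
        feature_names=list(feature_names),
        impurity=impurity,
        permutation_mean=np.asarray(perm.importances_mean),
        permutation_std=np.asarray(perm.importances_std),
    )


# --------------------------------------------------------------- orchestrator


def run_outcome_analysis(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    config: ModelConfig | None = None,
    importance_reps: int = 20,
) -> OutcomeAnalysis:
    """The full protocol: split, impute, select, tune, evaluate, explain.

    All fitted statistics (imputation medians, F scores, grid search) are
    computed on training rows only; the held-out rows enter exactly once,
    at evaluation and permutation-importance time.
    """
    config = config or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    train_idx, test_idx = stratified_split(X, y, config.test_fraction, config.seed)
    X_train, medians = impute_median(X[train_idx])
    X_test, _ = impute_median(X[test_idx], medians)
    y_train, y_test = y[train_idx], y[test_idx]

    k = min(config.k_select, X.shape[1])
    scores = anova_f_scores(X_train, y_train)
    keep = select_top_k(scores, k)
    names_kept = [feature_names[i] for i in keep]

    model, best = train_with_cv(X_train[:, keep], y_train, config)
    report = evaluate(
        model, X_test[:, keep], y_test, config.bootstrap_reps, config.ci_level, config.seed
    )
    importance = feature_importance(
        model, X_test[:, keep], y_test, names_kept, reps=importance_reps, seed=config.seed
    )
    return OutcomeAnalysis(
        selected_features=names_kept,
        f_scores=scores,
        best_params=best,
        model=model,
        report=report,
        importance=importance,
        n_train=len(train_idx),
        n_test=len(test_idx),
    )
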