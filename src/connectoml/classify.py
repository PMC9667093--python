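"""Classifier tuning, nested resampling evaluation and permutation testing.

Four classifier families — support vector machine, L1-regularized logistic
regression, random forest and Gaussian naive Bayes — are tuned by
exhaustive grid search under stratified 10-fold cross-validated accuracy on
the training split, refit on all training rows, and scored on the held-out
split.  The whole procedure (stratified 70/30 split, selection cascade,
tuning, test scoring) is repeated over many outer loops; performance is
summarized as mean +/- SD, and significance is assessed by re-running the
procedure on label-shuffled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .features import SelectionTrace, select_features, stratified_split

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "auc")


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray
) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, balanced accuracy); positives = 1."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0:
        raise ValueError("empty label vector")
    pos, neg = y_true == 1, y_true == 0
    if not pos.any() or not neg.any():
        raise ValueError("sensitivity/specificity undefined without both classes")
    tp = int(np.sum(pos & (y_pred == 1)))
    tn = int(np.sum(neg & (y_pred == 0)))
    fp = int(np.sum(neg & (y_pred == 1)))
    fn = int(np.sum(pos & (y_pred == 0)))
    accuracy = (tp + tn) / (tp + tn + fp + fn)
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    return accuracy, sensitivity, specificity, (sensitivity + specificity) / 2


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Rank AUC: P(random positive outscores random negative), ties count 1/2."""
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC AUC needs both classes")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameter grid.

    The grid is an ordered list of parameter dicts, smallest capacity first,
    so grid-search ties resolve toward the simpler model.
    """

    kind: str  # svm | lr | rf | gnb
    grid: tuple[dict, ...]
    inner_cv: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "lr", "rf", "gnb"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def build(self, params: dict, seed: int):
        if self.kind == "svm":
            return SVC(random_state=seed, **params)
        if self.kind == "lr":
            try:  # sklearn >= 1.9 spells the L1 penalty via l1_ratio
                return LogisticRegression(
                    l1_ratio=1.0, solver="liblinear", max_iter=5000,
                    random_state=seed, **params,
                )
            except TypeError:
                return LogisticRegression(
                    penalty="l1", solver="liblinear", max_iter=5000,
                    random_state=seed, **params,
                )
        if self.kind == "rf":
            return RandomForestClassifier(random_state=seed, **params)
        return GaussianNB(**params)


def default_model_specs(
    kinds: tuple[str, ...] = ("svm", "lr", "rf", "gnb"),
    rf_estimators: tuple[int, ...] = (100, 200, 500),
    inner_cv: int = 10,
) -> list[ModelSpec]:
    """The four classifier families with their default grids."""
    svm_grid: list[dict] = [
        {"kernel": "linear", "C": c} for c in (0.01, 0.1, 1.0, 10.0, 100.0)
    ]
    gammas = [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, "scale"]
    svm_grid += [
        {"kernel": "rbf", "C": c, "gamma": g}
        for c in (0.01, 0.1, 1.0, 10.0, 100.0)
        for g in gammas
    ]
    lr_grid = [{"C": float(c)} for c in np.geomspace(1e-3, 1e3, 10)]
    rf_grid = [{"n_estimators": n} for n in rf_estimators]
    specs = {
        "svm": ModelSpec("svm", tuple(svm_grid), inner_cv),
        "lr": ModelSpec("lr", tuple(lr_grid), inner_cv),
        "rf": ModelSpec("rf", tuple(rf_grid), inner_cv),
        "gnb": ModelSpec("gnb", ({"var_smoothing": 1e-9},), inner_cv),
    }
    return [specs[k] for k in kinds]


def _scores_of(model, X: np.ndarray) -> np.ndarray:
    # SVM scores by margin; the probabilistic models by P(class 1)
    if isinstance(model, SVC):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def tune_and_fit(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[object, dict]:
    """Exhaustive grid search by mean stratified K-fold CV accuracy.

    Ties keep the earlier (smaller-capacity) grid entry.  The winning
    configuration is refit on all training rows.
    """
    y = np.asarray(y).astype(int)
    if X.shape[1] == 0:
        raise ValueError("empty feature set")
    folds = min(spec.inner_cv, int(np.bincount(y).min()))
    if folds < 2:
        raise ValueError("need at least 2 subjects per class for inner CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_acc, best_params = -1.0, None
    for params in spec.grid:
        accs = []
        for tr, va in splits:
            m = spec.build(params, seed)
            m.fit(X[tr], y[tr])
            accs.append(float(np.mean(m.predict(X[va]) == y[va])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_acc, best_params = acc, params
    final = spec.build(best_params, seed)
    final.fit(X, y)
    return final, dict(best_params)


@dataclass
class LoopResult:
    """One outer loop: split, selection, per-model tuned test performance."""

    loop: int
    split_seed: int
    selected: list[str]
    weights: dict[str, float]
    models: dict[str, dict]  # kind -> {params, tp, tn, fp, fn, metrics...}


def _evaluate_models(
    specs: list[ModelSpec],
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    yte: np.ndarray,
    seed: int,
) -> dict[str, dict]:
    out: dict[str, dict] = {}
    for spec in specs:
        model, params = tune_and_fit(spec, Xtr, ytr, seed=seed)
        pred = model.predict(Xte)
        acc, sen, spe, bal = confusion_metrics(yte, pred)
        auc = roc_auc(_scores_of(model, Xte), yte)
        out[spec.kind] = {
            "params": params,
            "tp": int(np.sum((yte == 1) & (pred == 1))),
            "tn": int(np.sum((yte == 0) & (pred == 0))),
            "fp": int(np.sum((yte == 0) & (pred == 1))),
            "fn": int(np.sum((yte == 1) & (pred == 0))),
            "accuracy": acc, "sensitivity": sen, "specificity": spe,
            "balanced_accuracy": bal, "auc": auc,
        }
    return out


def run_loops(
    table: pd.DataFrame,
    labels: np.ndarray,
    specs: list[ModelSpec] | None = None,
    n_loops: int = 100,
    master_seed: int = 0,
    test_frac: float = 0.30,
    selection_kwargs: dict | None = None,
) -> tuple[list[LoopResult], pd.DataFrame]:
    """The nested resampling evaluation.

    Loop k draws a stratified split seeded ``master_seed + k``, runs the
    selection cascade on the training rows only, tunes every model by inner
    CV, and scores the held-out rows.  Loops whose cascade selects nothing
    are skipped (logged); the summary averages completed loops.
    Returns the loop records and a per-model mean/SD summary table.
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    specs = specs if specs is not None else default_model_specs()
    selection_kwargs = selection_kwargs or {}
    y = np.asarray(labels).astype(int)
    X = table.to_numpy(dtype=float)
    results: list[LoopResult] = []
    for k in range(n_loops):
        split_seed = master_seed + k
        plan = stratified_split(y, test_frac=test_frac, seed=split_seed)
        trace = select_features(
            table.iloc[plan.train], y[plan.train], seed=split_seed,
            **selection_kwargs,
        )
        if not trace.selected:
            logger.info("loop %d: empty feature selection, skipped", k)
            continue
        cols = trace.selected_idx
        Xtr = trace.scaler.apply(X[np.ix_(plan.train, trace.pruned_survivors)])
        Xte = trace.scaler.apply(X[np.ix_(plan.test, trace.pruned_survivors)])
        keep = np.isin(trace.pruned_survivors, cols)
        models = _evaluate_models(
            specs, Xtr[:, keep], y[plan.train], Xte[:, keep], y[plan.test],
            seed=split_seed,
        )
        results.append(
            LoopResult(loop=k, split_seed=split_seed, selected=trace.selected,
                       weights=trace.weights, models=models)
        )
    if not results:
        raise ValueError("every loop produced an empty selection")
    return results, summarize_loops(results)


def summarize_loops(results: list[LoopResult]) -> pd.DataFrame:
    """Mean +/- SD of each performance metric per model over completed loops."""
    rows = []
    kinds = list(results[0].models)
    for kind in kinds:
        row: dict[str, float | str] = {"model": kind, "n_loops": len(results)}
        for metric in METRIC_NAMES:
            vals = np.array([r.models[kind][metric] for r in results])
            row[f"mean_{metric}"] = float(vals.mean())
            row[f"sd_{metric}"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


@dataclass
class PermutationResult:
    """Label-shuffle null distribution for accuracy and AUC."""

    n_permutations: int
    actual_accuracy: float
    actual_auc: float
    permuted_accuracy: np.ndarray
    permuted_auc: np.ndarray
    p_accuracy: float
    p_auc: float


def _single_split_performance(
    table: pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    seed: int,
    test_frac: float,
    selection_kwargs: dict,
) -> tuple[float, float]:
    """One stratified split -> cascade -> tune -> test (accuracy, AUC).

    An empty selection yields chance-level statistics (majority-class
    accuracy, AUC 0.5); the same rule applies to actual and permuted runs so
    permutation p-values remain valid.
    """
    X = table.to_numpy(dtype=float)
    plan = stratified_split(y, test_frac=test_frac, seed=seed)
    trace = select_features(
        table.iloc[plan.train], y[plan.train], seed=seed, **selection_kwargs
    )
    yte = y[plan.test]
    if not trace.selected:
        majority = int(np.bincount(y[plan.train]).argmax())
        return float(np.mean(yte == majority)), 0.5
    keep = np.isin(trace.pruned_survivors, trace.selected_idx)
    Xtr = trace.scaler.apply(X[np.ix_(plan.train, trace.pruned_survivors)])[:, keep]
    Xte = trace.scaler.apply(X[np.ix_(plan.test, trace.pruned_survivors)])[:, keep]
    model, _ = tune_and_fit(spec, Xtr, y[plan.train], seed=seed)
    acc, *_ = confusion_metrics(yte, model.predict(Xte))
    return acc, roc_auc(_scores_of(model, Xte), yte)


def permutation_test(
    table: pd.DataFrame,
    labels: np.ndarray,
    spec: ModelSpec | None = None,
    n_perm: int = 1000,
    master_seed: int = 0,
    test_frac: float = 0.30,
    selection_kwargs: dict | None = None,
) -> PermutationResult:
    """Shuffle labels, rerun the complete pipeline, compare to the actual run.

    p = (#{permuted >= actual} + 1) / (n_perm + 1) so p is never zero.  Each
    permutation uses one stratified split of the shuffled labels.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    spec = spec if spec is not None else default_model_specs(("lr",))[0]
    selection_kwargs = selection_kwargs or {}
    y = np.asarray(labels).astype(int)
    actual_acc, actual_auc = _single_split_performance(
        table, y, spec, master_seed, test_frac, selection_kwargs
    )
    rng = np.random.default_rng(master_seed)
    perm_acc = np.empty(n_perm)
    perm_auc = np.empty(n_perm)
    for i in range(n_perm):
        y_shuf = rng.permutation(y)
        perm_acc[i], perm_auc[i] = _single_split_performance(
            table, y_shuf, spec, master_seed + i + 1, test_frac, selection_kwargs
        )
    p_acc = (np.sum(perm_acc >= actual_acc) + 1) / (n_perm + 1)
    p_auc = (np.sum(perm_auc >= actual_auc) + 1) / (n_perm + 1)
    return PermutationResult(
        n_permutations=n_perm, actual_accuracy=actual_acc, actual_auc=actual_auc,
        permuted_accuracy=perm_acc, permuted_auc=perm_auc,
        p_accuracy=float(p_acc), p_auc=float(p_auc),
    )
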