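"""Feature assembly and the selection cascade.

A subject's feature vector concatenates every global and nodal topological
metric at every sparsity threshold plus, per metric, the area under its
curve across thresholds (trapezoidal integral over S, a threshold-free
summary).  For an n-node atlas and a grid of T thresholds the count is
5*n*(T+1) + 7*(T+1); with n = 160 and T = 10 that is 8,877 features.

Selection on the training split only: a two-sided Mann-Whitney U screen at
p < 0.01, greedy Spearman collinearity pruning at |rho| > 0.7 (the later
column in canonical order is removed), z-standardization, then
squared-error LASSO on the 0/1 group labels with the penalty chosen by
stratified fivefold cross-validation.  Features with nonzero coefficients
at the chosen penalty survive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

from .graphmetrics import GLOBAL_METRICS, NODAL_METRICS, compute_subject_metrics
from .network import ThresholdGrid, binarize_stack, connectivity_from_timeseries, default_grid


def auc_over_thresholds(values: np.ndarray, grid: ThresholdGrid) -> float:
    """Trapezoidal integral of a metric over the sparsity grid."""
    v = np.asarray(values, dtype=float)
    if v.shape != (len(grid),):
        raise ValueError(f"need one value per grid point ({len(grid)}), got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("metric values must be finite")
    return float(np.trapezoid(v, np.asarray(grid.values)))


def feature_names(n_nodes: int, grid: ThresholdGrid | None = None) -> list[str]:
    """Canonical column order: global block then nodal, per-threshold before AUC.

    Naming scheme: ``Eglobal_thr0.20``, ``aEglobal``, ``DC_thr0.35_node042``,
    ``aDC_node042`` (1-based zero-padded node ids).
    """
    grid = grid if grid is not None else default_grid()
    names: list[str] = []
    for m in GLOBAL_METRICS:
        names.extend(f"{m}_thr{grid.label(s)}" for s in grid.values)
        names.append(f"a{m}")
    for node in range(1, n_nodes + 1):
        for m in NODAL_METRICS:
            names.extend(f"{m}_thr{grid.label(s)}_node{node:03d}" for s in grid.values)
            names.append(f"a{m}_node{node:03d}")
    return names


def expected_feature_count(n_nodes: int, n_thresholds: int = 10) -> int:
    """Closed form: 5*n*(T+1) + 7*(T+1)."""
    return 5 * n_nodes * (n_thresholds + 1) + 7 * (n_thresholds + 1)


def assemble_features(
    panels: list[tuple[np.ndarray, np.ndarray]],
    grid: ThresholdGrid,
    subjects: list[str] | None = None,
) -> pd.DataFrame:
    """Stack per-subject metric panels into the subjects x features table.

    ``panels`` holds, per subject, the ``(global_vals, nodal_vals)`` arrays
    from :func:`connectoml.graphmetrics.compute_subject_metrics`.
    """
    if not panels:
        raise ValueError("no subjects to assemble")
    n_thr = len(grid)
    n_nodes = panels[0][1].shape[2]
    rows = []
    for si, (gvals, nvals) in enumerate(panels):
        if gvals.shape != (len(GLOBAL_METRICS), n_thr) or nvals.shape != (
            len(NODAL_METRICS), n_thr, n_nodes,
        ):
            raise ValueError(f"subject {si}: incomplete metric panel {gvals.shape}, {nvals.shape}")
        if not (np.all(np.isfinite(gvals)) and np.all(np.isfinite(nvals))):
            raise ValueError(f"subject {si}: non-finite metric values")
        row = np.empty(expected_feature_count(n_nodes, n_thr))
        pos = 0
        for mi in range(len(GLOBAL_METRICS)):
            row[pos : pos + n_thr] = gvals[mi]
            row[pos + n_thr] = auc_over_thresholds(gvals[mi], grid)
            pos += n_thr + 1
        for node in range(n_nodes):
            for mi in range(len(NODAL_METRICS)):
                vals = nvals[mi, :, node]
                row[pos : pos + n_thr] = vals
                row[pos + n_thr] = auc_over_thresholds(vals, grid)
                pos += n_thr + 1
        rows.append(row)
    index = subjects if subjects is not None else [f"sub-{i + 1:03d}" for i in range(len(rows))]
    return pd.DataFrame(np.array(rows), index=index, columns=feature_names(n_nodes, grid))


def compute_feature_table(
    cohort,
    grid: ThresholdGrid | None = None,
    n_random: int = 100,
    swaps_per_edge: float = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """End-to-end: time series -> connectivity -> binary stacks -> features.

    The null ensemble for subject i, threshold t is seeded deterministically
    from ``seed`` so the table is reproducible subject by subject.
    """
    grid = grid if grid is not None else default_grid()
    panels = []
    subjects = list(cohort.covariates["subject"])
    for i in range(cohort.timeseries.shape[0]):
        conn = connectivity_from_timeseries(cohort.timeseries[i].T, subject=subjects[i])
        stack = binarize_stack(conn, grid)
        panels.append(
            compute_subject_metrics(
                stack, n_random=n_random, swaps_per_edge=swaps_per_edge,
                seed=seed + 1000 * i,
            )
        )
    return assemble_features(panels, grid, subjects=subjects)


# ---------------------------------------------------------------------------
# selection cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Stratified train/test partition of subject row indices."""

    train: np.ndarray
    test: np.ndarray
    seed: int
    test_frac: float


def stratified_split(labels: np.ndarray, test_frac: float = 0.30, seed: int = 0) -> SplitPlan:
    """Per-group sampling without replacement; test counts round half up."""
    y = np.asarray(labels)
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for g in np.unique(y):
        members = np.flatnonzero(y == g)
        if members.size < 2:
            raise ValueError(f"group {g} has fewer than 2 subjects")
        k = int(math.floor(members.size * test_frac + 0.5))
        if k == 0 or k == members.size:
            raise ValueError(f"test fraction {test_frac} degenerate for group {g}")
        test_idx.append(rng.choice(members, size=k, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return SplitPlan(train=train, test=test, seed=seed, test_frac=test_frac)


def mannwhitney_screen(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney U per feature; survivors have p < alpha.

    Exact enumeration when both groups have <= 8 members, otherwise the
    tie-corrected normal approximation.  Constant features get p = 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    a, b = X[y == 1], X[y == 0]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 training subjects")
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    constant = np.array([np.ptp(col) == 0 for col in X.T])
    pvals = np.ones(X.shape[1])
    live = ~constant
    if live.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(
                a[:, live], b[:, live], axis=0, alternative="two-sided", method=method
            )
        pvals[live] = np.nan_to_num(res.pvalue, nan=1.0)
    return pvals, pvals < alpha


def spearman_prune(
    X: np.ndarray,
    survivor_idx: np.ndarray,
    names: list[str],
    cutoff: float = 0.7,
) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Greedy collinearity pruning in canonical column order.

    Walking the surviving columns left to right, a column is dropped when
    its training-set Spearman |rho| with an already-retained column exceeds
    the cutoff; the removal log records (removed, retained partner, rho).
    """
    idx = np.sort(np.asarray(survivor_idx))
    if idx.size == 0:
        return idx, []
    ranked = np.apply_along_axis(stats.rankdata, 0, np.asarray(X, float)[:, idx])
    sd = ranked.std(axis=0)
    sd[sd == 0] = 1.0
    centered = (ranked - ranked.mean(axis=0)) / sd
    rho = centered.T @ centered / centered.shape[0]
    kept: list[int] = []
    removed_log: list[tuple[str, str, float]] = []
    for j in range(idx.size):
        partner = next((k for k in kept if abs(rho[k, j]) > cutoff), None)
        if partner is None:
            kept.append(j)
        else:
            removed_log.append(
                (names[idx[j]], names[idx[partner]], float(rho[partner, j]))
            )
    return idx[kept], removed_log


@dataclass(frozen=True)
class Scaler:
    """Per-feature training mean/SD; applied unchanged to any other table."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) / self.std


def fit_scaler(X: np.ndarray, names: list[str] | None = None) -> Scaler:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    dead = np.flatnonzero(std == 0)
    if dead.size:
        which = [names[d] for d in dead] if names else dead.tolist()
        raise ValueError(f"zero-variance feature(s) cannot be standardized: {which}")
    return Scaler(mean=mean, std=std)


@dataclass
class SelectionTrace:
    """Record of one pass through the selection cascade."""

    utest_p: np.ndarray
    utest_survivors: np.ndarray          # column indices into the full table
    pruned_survivors: np.ndarray         # after Spearman pruning
    spearman_removed: list[tuple[str, str, float]]
    scaler: Scaler | None
    lambda_grid: np.ndarray
    lambda_opt: float
    beta: np.ndarray                     # aligned with pruned_survivors
    selected: list[str]                  # names of nonzero-weight features
    selected_idx: np.ndarray
    weights: dict[str, float]


def lasso_lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 50) -> np.ndarray:
    """Log-spaced grid from lambda_max (all-zero solution) down 3 decades.

    In the loss sum((y - Xb)^2) + lambda * sum|b| with an intercept, the
    all-zero solution holds iff lambda >= 2 * max|X^T (y - ybar)|.
    """
    resid = y - y.mean()
    lam_max = 2.0 * np.max(np.abs(X.T @ resid))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 1e-3, n_points)


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str],
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Squared-error LASSO on 0/1 labels with stratified K-fold CV over lambda.

    Returns ``(lambda_opt, beta)`` where beta is the coefficient vector of
    the model refit on all training rows at the CV-optimal penalty.  Ties in
    CV error resolve toward the larger penalty (sparser model).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambda_grid is None:
        lambda_grid = lasso_lambda_grid(X, y)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    folds = min(cv_folds, int(np.bincount(y.astype(int)).min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    order = np.argsort(lambda_grid)[::-1]  # descending for the path solver
    lam_desc = lambda_grid[order]
    cv_err = np.zeros(lam_desc.size)
    for tr, va in skf.split(X, y):
        # whole regularization path per fold; intercept handled by centering
        Xtr, ytr = X[tr], y[tr]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        alphas = lam_desc / (2.0 * len(tr))
        _, coefs, _ = lasso_path(Xtr - xm, ytr - ym, alphas=alphas,
                                 max_iter=50_000, tol=1e-6)
        pred = (X[va] - xm) @ coefs + ym  # n_val x n_alphas
        cv_err += np.sum((y[va][:, None] - pred) ** 2, axis=0)
    # first minimiser in descending order = largest lambda among ties
    lam_opt = float(lam_desc[int(np.argmin(cv_err))])
    beta = _fit_lasso(X, y, lam_opt).coef_
    if names and np.all(beta == 0):
        warnings.warn("LASSO selected no features at the CV-optimal penalty")
    return lam_opt, beta


def _fit_lasso(X: np.ndarray, y: np.ndarray, lam: float) -> Lasso:
    # loss sum(r^2) + lam*sum|b|  <=>  sklearn's (1/2n)sum(r^2) + alpha*sum|b|
    alpha = lam / (2.0 * len(y))
    model = Lasso(alpha=alpha, fit_intercept=True, max_iter=50_000, tol=1e-6)
    model.fit(X, y)
    return model


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.01,
    spearman_cutoff: float = 0.7,
    cv_folds: int = 5,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> SelectionTrace:
    """Run the full cascade on a training table (training rows only!)."""
    X = table.to_numpy(dtype=float)
    names = list(table.columns)
    y = np.asarray(labels)
    pvals, mask = mannwhitney_screen(X, y, alpha=alpha)
    survivors = np.flatnonzero(mask)
    pruned, removed = spearman_prune(X, survivors, names, cutoff=spearman_cutoff)
    if pruned.size == 0:
        return SelectionTrace(
            utest_p=pvals, utest_survivors=survivors, pruned_survivors=pruned,
            spearman_removed=removed, scaler=None,
            lambda_grid=np.array([]), lambda_opt=float("nan"),
            beta=np.array([]), selected=[], selected_idx=np.array([], dtype=int),
            weights={},
        )
    scaler = fit_scaler(X[:, pruned], [names[i] for i in pruned])
    Xs = scaler.apply(X[:, pruned])
    lam_opt, beta = lasso_select(
        Xs, y.astype(float), [names[i] for i in pruned],
        lambda_grid=lambda_grid, cv_folds=cv_folds, seed=seed,
    )
    nz = np.flatnonzero(beta != 0)
    selected_idx = pruned[nz]
    selected = [names[i] for i in selected_idx]
    return SelectionTrace(
        utest_p=pvals, utest_survivors=survivors, pruned_survivors=pruned,
        spearman_removed=removed, scaler=scaler,
        lambda_grid=lambda_grid if lambda_grid is not None else np.array([]),
        lambda_opt=lam_opt, beta=beta, selected=selected,
        selected_idx=selected_idx,
        weights={names[pruned[j]]: float(beta[j]) for j in nz},
    )
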