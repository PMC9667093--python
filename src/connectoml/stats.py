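"""Stable-feature identification, clinical correlation, and group comparison.

A feature is a stable discriminator when the selection cascade picks it in
strictly more than a threshold number of the outer resampling loops
(default: more than 80 of 100).  Stable features are then related to
clinical severity scores within the patient group by partial Pearson
correlation — the correlation of the residuals of feature and score after
regressing both on nuisance covariates — with Bonferroni correction over
the tests actually performed.  A demographics table compares groups
variable by variable: Kolmogorov-Smirnov normality gate, then
unequal-variance (Welch) t-test or Mann-Whitney rank test for continuous
variables and a chi-squared test (no continuity correction) for binary
ones.  Welch's form is used because it reproduces published summary-based
statistics that the pooled form misses by a rounding step.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    """Selection frequency and direction of every ever-selected feature."""

    counts: dict[str, int]
    n_loops: int
    threshold: int
    stable: list[str]
    mean_weight: dict[str, float]
    direction: dict[str, int]  # sign of group-1 mean minus group-0 mean


def feature_stability(
    loop_results,
    threshold: int = 80,
    table: pd.DataFrame | None = None,
    labels: np.ndarray | None = None,
) -> StabilityReport:
    """Count selections across completed loops; stable means count > threshold.

    The inequality is strict: a feature selected exactly ``threshold`` times
    is not stable.  If the full feature table and labels are given, each
    feature's direction (sign of the group-1 minus group-0 mean on the full
    cohort) is recorded.
    """
    if not loop_results:
        raise ValueError("need at least one completed loop")
    counts: dict[str, int] = {}
    weights: dict[str, list[float]] = {}
    for r in loop_results:
        for name in r.selected:
            counts[name] = counts.get(name, 0) + 1
            weights.setdefault(name, []).append(r.weights[name])
    stable = sorted(
        (n for n, c in counts.items() if c > threshold),
        key=lambda n: -counts[n],
    )
    direction: dict[str, int] = {}
    if table is not None and labels is not None:
        y = np.asarray(labels)
        for name in counts:
            col = table[name].to_numpy(dtype=float)
            direction[name] = int(np.sign(col[y == 1].mean() - col[y == 0].mean()))
    return StabilityReport(
        counts=counts, n_loops=len(loop_results), threshold=threshold,
        stable=stable,
        mean_weight={n: float(np.mean(w)) for n, w in weights.items()},
        direction=direction,
    )


_NODE_RE = re.compile(r"node(\d+)$")


def feature_node(name: str) -> int | None:
    """0-based node index a feature name refers to, or None for global ones."""
    m = _NODE_RE.search(name)
    return int(m.group(1)) - 1 if m else None


def family_stability(
    loop_results, families: dict[str, set[int]]
) -> dict[str, float]:
    """Fraction of completed loops selecting >= 1 feature from each node family.

    A family is a set of 0-based node indices (e.g. the planted
    affected-down nodes); a loop hits the family when its selected set
    contains any feature of any node in it.  Because the collinearity prune
    deliberately collapses correlated features to shifting representatives
    across resamples, family-level frequency is the stable notion of
    "this region is consistently discriminative"; per-name frequencies are
    in :func:`feature_stability`.
    """
    if not loop_results:
        raise ValueError("need at least one completed loop")
    out = {}
    for fam, nodes in families.items():
        hits = sum(
            any(feature_node(name) in nodes for name in r.selected)
            for r in loop_results
        )
        out[fam] = hits / len(loop_results)
    return out


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates plus an intercept by
    least squares; r is the Pearson correlation of the residuals and p comes
    from the t distribution with n - k - 2 degrees of freedom (k covariates).
    With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        # constant covariates duplicate the intercept; drop them silently
        live = np.ptp(C, axis=0) > 0
        C = C[:, live]
        k = C.shape[1]
        Z = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            names = covariate_names or [f"cov{i}" for i in range(C.shape[1])]
            raise ValueError(f"rank-deficient covariate matrix among {names}")
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    beta_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    rx, ry = x - Z @ beta_x, y - Z @ beta_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("zero-variance residuals; partial correlation undefined")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return r, p


@dataclass
class PartialCorrelationResult:
    feature: str
    score: str
    r: float
    p: float
    significant: bool  # under the Bonferroni-corrected threshold


DEFAULT_COVARIATES = ("age", "sex", "education", "fd_power", "hdrs17", "hars14", "mmse")
DEFAULT_SCORES = ("trs_ab", "trs_c", "tetras", "duration", "frequency")


def correlate_clinical(
    table: pd.DataFrame,
    covariate_table: pd.DataFrame,
    stable_features: list[str],
    scores: tuple[str, ...] = DEFAULT_SCORES,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> list[PartialCorrelationResult]:
    """Partial correlations of stable features with clinical scores (group 1).

    Restricted to group-1 rows (the patient group carries the scores).  The
    Bonferroni divisor defaults to the number of tests actually performed;
    ``bonferroni_m`` overrides it for alternative correction conventions.
    """
    g1 = covariate_table["group"].to_numpy() == 1
    cov = covariate_table.loc[g1, list(covariates)].to_numpy(dtype=float)
    sub = table.loc[covariate_table.loc[g1, "subject"]] if "subject" in covariate_table else table.loc[g1]
    pairs = []
    for score in scores:
        if score not in covariate_table.columns:
            logger.info("score column %s missing; skipped", score)
            continue
        yvals = covariate_table.loc[g1, score].to_numpy(dtype=float)
        if np.isnan(yvals).all():
            logger.info("score column %s empty in group 1; skipped", score)
            continue
        for feat in stable_features:
            pairs.append((feat, score, yvals))
    computed = []
    for feat, score, yvals in pairs:
        try:
            r, p = partial_pearson(
                sub[feat].to_numpy(dtype=float), yvals, cov,
                covariate_names=list(covariates),
            )
        except ValueError as err:  # e.g. feature constant within the group
            logger.info("skipping %s ~ %s: %s", feat, score, err)
            continue
        computed.append((feat, score, r, p))
    m = bonferroni_m if bonferroni_m is not None else max(1, len(computed))
    cutoff = alpha / m
    return [
        PartialCorrelationResult(feat, score, r, p, p < cutoff)
        for feat, score, r, p in computed
    ]


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's unequal-variance t from per-group summaries.

    Returns (t, degrees of freedom, two-sided p).  Computing from summaries
    lets published group tables be checked without raw data.
    """
    se2 = sd1**2 / n1 + sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2**2 / ((sd1**2 / n1) ** 2 / (n1 - 1) + (sd2**2 / n2) ** 2 / (n2 - 1))
    p = float(2 * stats.t.sf(abs(t), df))
    return float(t), float(df), p


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col[~np.isnan(col)])
    return len(vals) <= 2


def demographic_table(
    covariate_table: pd.DataFrame,
    variables: list[str] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group comparison in the published-table style.

    Continuous variables pass a Kolmogorov-Smirnov normality gate (each
    group against a normal with its sample mean/SD); if both groups look
    normal a Welch t-test is used, otherwise the Mann-Whitney rank test.
    Binary variables use chi-squared without continuity correction, reported
    as a signed Z = sign(p1 - p2) * sqrt(chi2).  Statistics are rounded to 2
    decimals, matching reporting convention.
    """
    y = covariate_table["group"].to_numpy().astype(int)
    if variables is None:
        variables = [
            c for c in covariate_table.columns
            if c not in ("subject", "group")
        ]
    rows = []
    for var in variables:
        col = covariate_table[var].to_numpy(dtype=float)
        a, b = col[y == 1], col[y == 0]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            logger.info("variable %s missing in one group; skipped", var)
            continue
        if _is_binary(col):
            tab = pd.crosstab(y, col)
            if tab.shape != (2, 2):
                logger.info("variable %s degenerate contingency; skipped", var)
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            z = np.sign(a.mean() - b.mean()) * np.sqrt(chi2)
            rows.append({
                "variable": var, "test": "chi2",
                "group1": f"{int(a.sum())}/{int(len(a) - a.sum())}",
                "group0": f"{int(b.sum())}/{int(len(b) - b.sum())}",
                "statistic": round(float(z), 2), "p": float(p),
            })
            continue
        normal = all(
            stats.kstest((g - g.mean()) / g.std(ddof=1), "norm").pvalue
            >= normality_alpha
            for g in (a, b)
            if g.std(ddof=1) > 0
        ) and a.std(ddof=1) > 0 and b.std(ddof=1) > 0
        if normal:
            res = stats.ttest_ind(a, b, equal_var=False)
            stat, p, kind = float(res.statistic), float(res.pvalue), "welch_t"
        else:
            zres = stats.ranksums(a, b)
            stat, p, kind = float(zres.statistic), float(zres.pvalue), "ranksum_z"
        rows.append({
            "variable": var, "test": kind,
            "group1": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
            "group0": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
            "statistic": round(stat, 2), "p": p,
        })
    return pd.DataFrame(rows).set_index("variable")
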