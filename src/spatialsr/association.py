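"""Response-association statistics and predictive-power comparisons.

Group differences are tested per metric with a two-sided Welch t-test on
the metric's analysis scale (logarithmic for densities, exclusion ratios
and the Weibull scale; linear for the shape), with Benjamini–Hochberg
FDR control within declared metric families. Median 1-NN distances per
sample (scale · (ln 2)^(1/shape)) are compared with an exact two-sided
Mann–Whitney test. Predictive power is assessed by unpenalized logistic
regression: the ROC is built from in-sample fitted probabilities (an
optimistic estimate, by construction), its AUC by the rank statistic,
confidence intervals by stratified bootstrap (n = 500), and competing
feature sets are compared by a paired bootstrap of AUCs (one-sided
t-test) and by leave-one-out deviance curves (two-sided t-test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import CohortLabels
from .nlme import WeibullFit
from .weibull import median_1nn

logger = logging.getLogger(__name__)

#: Metrics whose group comparison runs on the log scale.
LOG_SCALE_PREFIXES = ("density.", "exclusion.", "scale.", "g_auc_", "median_1nn.")


@dataclass
class DifferentialResult:
    metric: str
    family: str
    scale: str  # linear | log
    mean_responder: float
    mean_non_responder: float
    fold_change: float  # difference of group means on the analysis scale
    p_value: float
    fdr: float | None = None
    n_responder: int = 0
    n_non_responder: int = 0


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_vs_chance: float
    replicate_aucs: np.ndarray = field(repr=False, default=None)
    coefficients: np.ndarray | None = None
    separable: bool = False
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    features: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (q-values) for one family."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


def default_scale(metric: str) -> str:
    return "log" if metric.startswith(LOG_SCALE_PREFIXES) else "linear"


def default_family(metric: str) -> str:
    """Family = the metric class (volcano panel): shape, scale, density, ..."""
    return metric.split(".", 1)[0]


def differential_test(
    metrics: pd.DataFrame,
    labels: CohortLabels,
    scale_map: dict[str, str] | None = None,
    family_map: dict[str, str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Welch t-test per metric with BH correction within each family.

    Returns a dataframe with one row per testable metric (both groups
    must have ≥2 non-missing values; others are skipped with a logged
    reason). ``fold_change`` is the responder − non-responder difference
    of group means on the analysis scale (a log-ratio for log-scale
    metrics).
    """
    lab = labels.as_series()
    results: list[DifferentialResult] = []
    for metric in metrics.columns:
        vals = metrics[metric]
        scale = (scale_map or {}).get(metric, default_scale(metric))
        family = (family_map or {}).get(metric, default_family(metric))
        groups = {}
        ok = True
        for g in ("responder", "non_responder"):
            sel = [s for s in metrics.index if lab.get(s) == g]
            v = vals.loc[sel].dropna().to_numpy(dtype=float)
            if scale == "log":
                v = v[v > 0]
                v = np.log(v)
            if v.size < 2:
                logger.info("metric %s skipped: <2 values in group %s", metric, g)
                ok = False
                break
            groups[g] = v
        if not ok:
            continue
        a, b = groups["responder"], groups["non_responder"]
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        results.append(
            DifferentialResult(
                metric=metric,
                family=family,
                scale=scale,
                mean_responder=float(a.mean()),
                mean_non_responder=float(b.mean()),
                fold_change=float(a.mean() - b.mean()),
                p_value=float(p),
                n_responder=a.size,
                n_non_responder=b.size,
            )
        )
    if not results:
        return pd.DataFrame(
            columns=[
                "metric", "family", "scale", "mean_responder",
                "mean_non_responder", "fold_change", "p_value", "fdr",
                "n_responder", "n_non_responder",
            ]
        )
    df = pd.DataFrame([r.__dict__ for r in results])
    df["fdr"] = np.nan
    for fam, idx in df.groupby("family").groups.items():
        df.loc[idx, "fdr"] = benjamini_hochberg(df.loc[idx, "p_value"].to_numpy())
    return df


def median_distance_test(
    fit: WeibullFit, labels: CohortLabels
) -> dict:
    """Per-sample Weibull medians compared between response groups.

    Uses the exact two-sided Mann–Whitney test for group sizes up to 20
    (normal approximation above), matching standard practice.
    """
    lab = labels.as_series()
    med = {
        s: median_1nn(p)
        for s, p in fit.per_sample.items()
        if p is not None
    }
    g1 = np.array([m for s, m in med.items() if lab.get(s) == "responder"])
    g2 = np.array([m for s, m in med.items() if lab.get(s) == "non_responder"])
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both response groups need at least one sample")
    method = "exact" if max(g1.size, g2.size) <= 20 else "asymptotic"
    try:
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
    except ValueError:  # ties make the exact method unavailable
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided", method="asymptotic")
    return {
        "median_responder": float(np.median(g1)),
        "median_non_responder": float(np.median(g2)),
        "p_value": float(res.pvalue),
        "n_responder": int(g1.size),
        "n_non_responder": int(g2.size),
        "per_sample_medians": med,
    }


# ---------------------------------------------------------------------------
# logistic regression / ROC machinery


def _logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100):
    """Unpenalized logistic regression by IRLS.

    Returns (coefficients incl. intercept, fitted probabilities,
    separable flag). Under perfect separation the coefficients are
    capped at ``max_iter`` iterations and flagged.
    """
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    separable = False
    for _ in range(max_iter):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        if np.max(w) < 1e-10:
            separable = True
            break
        WX = Xd * w[:, None]
        H = Xd.T @ WX + 1e-10 * np.eye(p + 1)
        g = Xd.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            separable = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
        if np.max(np.abs(beta)) > 1e3:
            separable = True
            break
    eta = np.clip(Xd @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    return beta, mu, separable


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC via the Mann–Whitney rank statistic (ties counted half)."""
    s1 = scores[y == 1]
    s0 = scores[y == 0]
    if s1.size == 0 or s0.size == 0:
        return float("nan")
    greater = (s1[:, None] > s0[None, :]).sum()
    equal = (s1[:, None] == s0[None, :]).sum()
    return (greater + 0.5 * equal) / (s1.size * s0.size)


def trapezoid_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """ROC AUC by trapezoidal integration of the ROC curve."""
    order = np.argsort(-scores, kind="mergesort")
    ys = y[order]
    ss = scores[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # keep only threshold boundaries (last index of each tied score run)
    distinct = np.flatnonzero(np.append(np.diff(ss) != 0, True))
    tpr = np.concatenate([[0], tps[distinct] / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps[distinct] / max(fps[-1], 1)])
    return float(np.trapezoid(tpr, fpr))


def residual_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Binomial residual deviance −2 Σ [y ln μ + (1−y) ln(1−μ)]."""
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _encode_labels(labels: CohortLabels, sample_ids: list[str]) -> np.ndarray:
    lab = labels.as_series()
    return np.array([1 if lab.get(s) == "responder" else 0 for s in sample_ids])


def logistic_roc(
    features: pd.DataFrame,
    labels: CohortLabels,
    n_boot: int = 500,
    seed: int = 0,
) -> RocResult:
    """Logistic model + ROC with stratified bootstrap CI.

    The ROC is built from the in-sample fitted probabilities, as is
    conventional for small-cohort biomarker panels — an optimistic
    estimate, flagged as such in the documentation. ``p_vs_chance`` is
    the two-sided rank test comparing fitted scores between classes.
    """
    sample_ids = list(features.index)
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite; impute or drop missing values")
    y = _encode_labels(labels, sample_ids)
    if min((y == 1).sum(), (y == 0).sum()) < 3:
        raise ValueError("need at least 3 samples per class")
    beta, mu, separable = _logistic_fit(X, y)
    if separable:
        logger.warning("perfect separation detected; coefficients capped")
    auc = rank_auc(mu, y)
    if np.ptp(mu) == 0:
        p_chance = 1.0
    else:
        p_chance = float(
            stats.mannwhitneyu(mu[y == 1], mu[y == 0], alternative="two-sided").pvalue
        )

    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, idx1.size, replace=True), rng.choice(idx0, idx0.size, replace=True)]
        )
        Xb, yb = X[take], y[take]
        _, mub, _ = _logistic_fit(Xb, yb)
        reps[b] = rank_auc(mub, yb)
    lo, hi = np.percentile(reps[np.isfinite(reps)], [2.5, 97.5])
    return RocResult(
        auc=float(auc),
        ci_low=float(lo),
        ci_high=float(hi),
        p_vs_chance=p_chance,
        replicate_aucs=reps,
        coefficients=beta,
        separable=separable,
        feature_names=list(features.columns),
        sample_ids=sample_ids,
        features=X,
        y=y,
    )


def bootstrap_roc_compare(
    roc_a: RocResult, roc_b: RocResult, n_boot: int = 500, seed: int = 0
) -> float:
    """One-sided p-value that model A's AUC exceeds model B's.

    Paired bootstrap: the same stratified sample resample is applied to
    both feature sets, both models refit, and the per-replicate AUC
    differences tested with a one-sided t-test (H1: AUC_a > AUC_b).
    """
    if roc_a.sample_ids != roc_b.sample_ids:
        raise ValueError("both models must be fit on the same samples")
    y = roc_a.y
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx1, idx1.size, replace=True), rng.choice(idx0, idx0.size, replace=True)]
        )
        yb = y[take]
        _, mua, _ = _logistic_fit(roc_a.features[take], yb)
        _, mub, _ = _logistic_fit(roc_b.features[take], yb)
        diffs[b] = rank_auc(mua, yb) - rank_auc(mub, yb)
    diffs = diffs[np.isfinite(diffs)]
    if np.ptp(diffs) == 0:
        return 0.5 if abs(diffs.mean()) < 1e-12 else (0.0 if diffs.mean() > 0 else 1.0)
    res = stats.ttest_1samp(diffs, 0.0, alternative="greater")
    return float(res.pvalue)


def loo_deviance(features: pd.DataFrame, labels: CohortLabels) -> np.ndarray:
    """Leave-one-out residual-deviance vector of a logistic model.

    For each fold the model is refit on the retained samples and its
    residual deviance on those samples recorded; folds with separation
    use the capped fit (flagged via log).
    """
    sample_ids = list(features.index)
    X = features.to_numpy(dtype=float)
    y = _encode_labels(labels, sample_ids)
    n = len(sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples for leave-one-out")
    devs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        _, mu, sep = _logistic_fit(X[keep], y[keep])
        if sep:
            logger.info("fold %d: separation; deviance from capped fit", i)
        devs[i] = residual_deviance(y[keep], mu)
    return devs


def loo_deviance_compare(
    features_a: pd.DataFrame, features_b: pd.DataFrame, labels: CohortLabels
) -> dict:
    """Two-sided t-test between LOO deviance vectors of two feature sets."""
    da = loo_deviance(features_a, labels)
    db = loo_deviance(features_b, labels)
    if np.ptp(da - db) == 0:
        p = 1.0
    else:
        p = float(stats.ttest_ind(da, db).pvalue)
    return {
        "deviance_a": da,
        "deviance_b": db,
        "mean_a": float(da.mean()),
        "mean_b": float(db.mean()),
        "p_value": p,
    }
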