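"""Risk-group construction: k-means dichotomization, nearest shrunken
centroids (NSC), and forward selection of the optimal gene-list prefix.

For each prefix of the ranked candidate list, samples are split into two
groups by k-means on z-scored expression; the split is scored by (a) the
log-rank p-value between the groups' survival and (b) the cross-validated
error of an NSC classifier trained to predict the split. The smallest prefix
minimizing the sum of the two metrics' ranks is the optimal classifier. The
cluster with the smaller restricted mean survival time is labeled "high"
risk.

The NSC implementation follows the shrunken-centroid method: per-gene class
deviations d_ik = (xbar_ik - xbar_i) / (m_k (s_i + s0)) with
m_k = sqrt(1/n_k - 1/n) and s0 = median(s_i), soft-thresholded by Delta, and
classification by the standardized discriminant score with class priors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedKFold

from .cohorts import Cohort
from .survival import logrank_test, restricted_mean_survival

__all__ = [
    "NSCModel",
    "SelectionTrace",
    "RiskClassifier",
    "kmeans_dichotomize",
    "nsc_fit",
    "nsc_predict",
    "nsc_cv_error",
    "forward_select",
]

LOW, HIGH = "low", "high"


@dataclass(frozen=True)
class NSCModel:
    classes: tuple[str, ...]
    class_centroids: np.ndarray  # (n_genes, n_classes), shrunken
    overall_centroid: np.ndarray  # (n_genes,)
    pooled_sd: np.ndarray  # per-gene s_i
    s0: float
    delta: float
    class_priors: np.ndarray


@dataclass(frozen=True)
class SelectionTrace:
    rows: list = field(default_factory=list)
    # each row: dict(g=..., genes=[...], logrank_p=..., cv_error=..., combined_rank=...)


@dataclass(frozen=True)
class RiskClassifier:
    gene_list: list[str]
    labels: np.ndarray  # per-sample "low"/"high"
    kmeans_centers: np.ndarray
    nsc: NSCModel
    trace: SelectionTrace
    logrank_p: float
    cv_error: float


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def kmeans_dichotomize(
    cohort: Cohort, genes: list[str], seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """2-means split of samples on z-scored expression of ``genes``.

    Returns (labels, centers) where labels are "low"/"high" per sample and
    "high" marks the cluster with the smaller restricted mean survival time
    (area under its KM curve up to the cohort's last observed time). 20
    seeded restarts are used for stability.
    """
    missing = [g for g in genes if g not in cohort.expr.index]
    if missing:
        raise KeyError(f"gene(s) not in cohort: {missing[:3]}")
    if cohort.n_samples < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    X = cohort.expr.loc[list(genes)].to_numpy(dtype=float)
    Z = _zscore_rows(X).T  # samples x genes
    if np.allclose(Z, Z[0], atol=1e-12):
        raise ValueError("all samples identical on the selected genes; no split")
    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    idx = km.fit_predict(Z)
    if len(np.unique(idx)) < 2:
        raise ValueError("k-means produced a single cluster")

    times, events = cohort.times, cohort.events
    tau = float(times.max())
    rmst = [
        restricted_mean_survival(times[idx == k], events[idx == k], tau) for k in (0, 1)
    ]
    high_cluster = int(np.argmin(rmst))  # shorter survival = high risk
    labels = np.where(idx == high_cluster, HIGH, LOW)
    centers = km.cluster_centers_[[1 - high_cluster, high_cluster]]  # low first
    return labels, centers


def _nsc_stats(X: np.ndarray, y: np.ndarray, classes: tuple[str, ...]):
    """Per-class means, overall mean, pooled within-class sd, m_k."""
    n = y.size
    K = len(classes)
    overall = X.mean(axis=1)
    cent = np.empty((X.shape[0], K))
    nk = np.empty(K)
    ss = np.zeros(X.shape[0])
    for k, c in enumerate(classes):
        mask = y == c
        nk[k] = mask.sum()
        cent[:, k] = X[:, mask].mean(axis=1)
        ss += ((X[:, mask] - cent[:, k][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(ss / max(n - K, 1))
    mk = np.sqrt(np.maximum(1.0 / nk - 1.0 / n, 0.0))
    return overall, cent, s, nk, mk


def nsc_fit(
    X: np.ndarray, y: np.ndarray, delta: float, s0: float | None = None
) -> NSCModel:
    """Fit a shrunken-centroid model at shrinkage ``delta``.

    ``X`` is genes x samples; ``y`` holds class labels. ``s0`` defaults to the
    median pooled within-class sd.
    """
    classes = tuple(sorted(np.unique(y).tolist()))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    overall, cent, s, nk, mk = _nsc_stats(X, y, classes)
    if s0 is None:
        s0 = float(np.median(s))
    denom = np.where(s + s0 == 0, 1.0, s + s0)
    d = (cent - overall[:, None]) / (mk[None, :] * denom[:, None])
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    shrunk_cent = overall[:, None] + mk[None, :] * denom[:, None] * d_shrunk
    priors = nk / nk.sum()
    return NSCModel(
        classes=classes,
        class_centroids=shrunk_cent,
        overall_centroid=overall,
        pooled_sd=s,
        s0=float(s0),
        delta=float(delta),
        class_priors=priors,
    )


def nsc_predict(model: NSCModel, X: np.ndarray) -> np.ndarray:
    """Classify samples (columns of ``X``) by minimum discriminant score
    sum_g (x_g - centroid_gk)^2 / (s_g + s0)^2 - 2 log pi_k."""
    denom = np.where(model.pooled_sd + model.s0 == 0, 1.0, model.pooled_sd + model.s0)
    scores = np.empty((X.shape[1], len(model.classes)))
    for k in range(len(model.classes)):
        diff = (X - model.class_centroids[:, k][:, None]) / denom[:, None]
        scores[:, k] = (diff**2).sum(axis=0) - 2.0 * np.log(model.class_priors[k])
    return np.asarray(model.classes)[np.argmin(scores, axis=1)]


def _max_abs_deviation(X, y) -> float:
    classes = tuple(sorted(np.unique(y).tolist()))
    overall, cent, s, nk, mk = _nsc_stats(X, y, classes)
    s0 = float(np.median(s))
    denom = np.where(s + s0 == 0, 1.0, s + s0)
    d = (cent - overall[:, None]) / (mk[None, :] * denom[:, None])
    return float(np.max(np.abs(d)))


def nsc_cv_error(
    X: np.ndarray,
    y: np.ndarray,
    delta_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float, NSCModel]:
    """Stratified CV over a shrinkage grid.

    Returns (min_cv_error, best_delta, model refit on all data at best_delta)
    where best_delta is the smallest grid value achieving the minimum CV
    misclassification rate. The default grid is 30 evenly spaced values from
    0 to the maximum absolute standardized deviation on the full data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if delta_grid is None:
        delta_grid = np.linspace(0.0, _max_abs_deviation(X, y), 30)
    delta_grid = np.asarray(delta_grid, dtype=float)

    max_folds = int(counts.min())
    folds = min(n_folds, max_folds)
    if folds < n_folds:
        warnings.warn(
            f"reducing CV folds from {n_folds} to {folds} (smallest class has "
            f"{max_folds} samples)",
            stacklevel=2,
        )
    if folds < 2:
        raise ValueError("smallest class too small for cross-validation")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(delta_grid.size)
    n_total = 0
    for train, test in skf.split(X.T, y):
        for j, delta in enumerate(delta_grid):
            model = nsc_fit(X[:, train], y[train], delta)
            pred = nsc_predict(model, X[:, test])
            errors[j] += np.sum(pred != y[test])
        n_total += test.size
    cv_err = errors / n_total
    best_j = int(np.flatnonzero(cv_err == cv_err.min())[0])
    best_delta = float(delta_grid[best_j])
    return float(cv_err[best_j]), best_delta, nsc_fit(X, y, best_delta)


def forward_select(
    cohort: Cohort,
    ranked_candidates: list[str],
    G_max: int = 300,
    seed: int = 0,
    n_folds: int = 10,
    n_delta: int = 30,
) -> RiskClassifier:
    """Scan prefixes of the ranked candidate list and pick the optimal one.

    For each prefix size g, the samples are dichotomized by k-means, the
    split is scored by its log-rank p and by NSC cross-validated error, and
    combined_rank(g) = rank(logrank_p) + rank(cv_error). The smallest g
    minimizing combined_rank wins.
    """
    from scipy.stats import rankdata

    if not ranked_candidates:
        raise ValueError("ranked_candidates must be non-empty")
    G = min(G_max, len(ranked_candidates))
    rows = []
    evaluated = []
    for g in range(1, G + 1):
        genes = list(ranked_candidates[:g])
        try:
            labels, _ = kmeans_dichotomize(cohort, genes, seed=seed)
            lr = logrank_test(cohort.times, cohort.events, (labels == HIGH).astype(int))
            X = cohort.expr.loc[genes].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv_err, _, _ = nsc_cv_error(
                    X, labels,
                    delta_grid=np.linspace(0.0, _max_abs_deviation(X, labels), n_delta),
                    n_folds=n_folds, seed=seed,
                )
        except (ValueError, KeyError):
            rows.append(dict(g=g, genes=genes, logrank_p=np.nan, cv_error=np.nan,
                             combined_rank=np.nan))
            continue
        rows.append(dict(g=g, genes=genes, logrank_p=lr.p, cv_error=cv_err,
                         combined_rank=np.nan))
        evaluated.append(len(rows) - 1)

    if not evaluated:
        raise ValueError("every candidate prefix was degenerate")
    ps = np.array([rows[i]["logrank_p"] for i in evaluated])
    errs = np.array([rows[i]["cv_error"] for i in evaluated])
    combined = rankdata(ps, method="average") + rankdata(errs, method="average")
    for i, c in zip(evaluated, combined):
        rows[i]["combined_rank"] = float(c)
    best_pos = int(np.argmin(combined))  # argmin takes the first = smallest g
    best_idx = evaluated[best_pos]
    best_g = rows[best_idx]["g"]
    genes = list(ranked_candidates[:best_g])

    labels, centers = kmeans_dichotomize(cohort, genes, seed=seed)
    lr = logrank_test(cohort.times, cohort.events, (labels == HIGH).astype(int))
    X = cohort.expr.loc[genes].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cv_err, _, model = nsc_cv_error(
            X, labels,
            delta_grid=np.linspace(0.0, _max_abs_deviation(X, labels), n_delta),
            n_folds=n_folds, seed=seed,
        )
    return RiskClassifier(
        gene_list=genes,
        labels=labels,
        kmeans_centers=centers,
        nsc=model,
        trace=SelectionTrace(rows=rows),
        logrank_p=float(lr.p),
        cv_error=float(cv_err),
    )
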