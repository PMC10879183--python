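"""Core right-censored survival statistics.

Provides the product-limit (Kaplan-Meier) estimator, the two-group log-rank
test, univariate Cox proportional-hazards regression with Breslow handling of
tied event times, and a minimum-p-value cutpoint scan restricted to an inner
quantile band of the marker.

The Cox score statistic at beta=0 is exposed both for a single covariate and
vectorized across a gene-by-sample matrix; for a binary covariate it coincides
with the log-rank chi-square, and for a continuous covariate it is the natural
generalization of the log-rank test. A known caveat of the cutpoint scan is
that minimizing the log-rank p over candidate thresholds is anti-conservative;
the returned p-value is the minimum scanned p, not a corrected one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "CutpointResult",
    "km_estimate",
    "restricted_mean_survival",
    "logrank_test",
    "cox_score_test",
    "cox_score_test_matrix",
    "cox_univariate",
    "optimal_cutpoint",
]


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier survival curve over the distinct event times."""

    event_times: np.ndarray  # ascending distinct times with >=1 event
    surv_prob: np.ndarray  # S(t) just after each event time (right-continuous)
    at_risk: np.ndarray  # number at risk just before each event time

    def survival_at(self, t: float) -> float:
        """S(t) for an arbitrary time (right-continuous step function)."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.surv_prob[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float
    observed: tuple[float, float]  # events per group
    expected: tuple[float, float]


@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    score_stat: float
    p: float  # chi-square(1) upper tail of the score statistic
    converged: bool
    n_events: int
    degenerate: bool = False


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    p: float
    n_low: int
    n_high: int
    scanned: list = field(default_factory=list)  # [(threshold, p), ...]


def _as_surv_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-D and of equal length")
    if t.size == 0:
        raise ValueError("empty survival input")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    if not np.all((e == 0) | (e == 1)):
        raise ValueError("events must be 0/1")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Product-limit estimator S(t) = prod_{t_j<=t} (1 - d_j/n_j).

    Censored observations tied with an event time are counted as still at risk
    at that time (the usual convention).
    """
    t, e = _as_surv_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq, first = np.unique(t, return_index=True)
    n = t.size
    ev_times, surv, risk = [], [], []
    s = 1.0
    for u, i0 in zip(uniq, first):
        mask = t == u
        d = int(e[mask].sum())
        if d == 0:
            continue
        n_at = n - i0  # sorted: everyone with time >= u
        s *= 1.0 - d / n_at
        ev_times.append(u)
        surv.append(s)
        risk.append(n_at)
    return KMCurve(
        event_times=np.asarray(ev_times, dtype=float),
        surv_prob=np.asarray(surv, dtype=float),
        at_risk=np.asarray(risk, dtype=int),
    )


def restricted_mean_survival(times, events, tau: float | None = None) -> float:
    """Area under the KM curve up to ``tau`` (default: last observed time)."""
    t, e = _as_surv_arrays(times, events)
    if tau is None:
        tau = float(t.max())
    curve = km_estimate(t, e)
    knots = curve.event_times[curve.event_times < tau]
    heights = curve.surv_prob[: knots.size]
    grid = np.concatenate(([0.0], knots, [tau]))
    steps = np.concatenate(([1.0], heights))
    return float(np.sum(steps * np.diff(grid)))


def logrank_test(times, events, groups) -> LogRankResult:
    """Two-group log-rank test with hypergeometric variance at each event time."""
    t, e = _as_surv_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    in1 = g == labels[1]
    if in1.all() or (~in1).all():
        raise ValueError("both groups must be non-empty")

    if e.sum() == 0:
        warnings.warn("no events in either group; log-rank p set to 1", stacklevel=2)
        return LogRankResult(0.0, 1.0, (0.0, 0.0), (0.0, 0.0))

    order = np.argsort(t, kind="stable")
    t, e, in1 = t[order], e[order], in1[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    # suffix counts of group-1 members in the risk set
    g1_suffix = np.cumsum(in1[::-1])[::-1]

    o_minus_e = 0.0
    var = 0.0
    obs1 = 0.0
    exp1 = 0.0
    for u, i0 in zip(uniq, first):
        mask = t == u
        d = float(e[mask].sum())
        if d == 0:
            continue
        n_at = float(n - i0)
        n1_at = float(g1_suffix[i0])
        d1 = float(e[mask & in1].sum())
        e1 = d * n1_at / n_at
        o_minus_e += d1 - e1
        if n_at > 1:
            var += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
        obs1 += d1
        exp1 += e1
    total = float(e.sum())
    chi2 = 0.0 if var == 0 else o_minus_e**2 / var
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogRankResult(
        chi2=float(chi2),
        p=max(min(p, 1.0), np.finfo(float).tiny),
        observed=(total - obs1, obs1),
        expected=(total - exp1, exp1),
    )


def cox_score_test_matrix(times, events, X) -> tuple[np.ndarray, np.ndarray]:
    """Cox partial-likelihood score test at beta=0, vectorized over covariates.

    ``X`` is (n_covariates, n_samples). Returns (chi2, p) arrays of length
    n_covariates. Breslow convention for ties. Degenerate covariates (zero
    variance in the risk sets) get chi2=0, p=1.
    """
    t, e = _as_surv_arrays(times, events)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != t.size:
        raise ValueError("X must have one column per sample")
    G = X.shape[0]
    if e.sum() == 0:
        return np.zeros(G), np.ones(G)

    order = np.argsort(t, kind="stable")
    t_sorted, e_sorted = t[order], e[order]
    Xs = X[:, order]
    _, first_all = np.unique(t_sorted, return_index=True)
    d_all = np.add.reduceat(e_sorted, first_all)
    keep = d_all > 0
    first = first_all[keep]
    d = d_all[keep].astype(float)
    # suffix sums over the risk set {i : t_i >= u}
    S1 = np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1]
    S2 = np.cumsum((Xs**2)[:, ::-1], axis=1)[:, ::-1]
    n = t.size
    n_at = (n - first).astype(float)

    ev_x = Xs * e_sorted  # per-sample event-weighted covariate
    s_event = np.add.reduceat(ev_x, first_all, axis=1)[:, keep]

    m1 = S1[:, first] / n_at
    m2 = S2[:, first] / n_at
    U = np.sum(s_event - d * m1, axis=1)
    I = np.sum(d * (m2 - m1**2), axis=1)
    chi2 = np.zeros(G)
    ok = I > 0
    chi2[ok] = U[ok] ** 2 / I[ok]
    p = np.ones(G)
    p[ok] = stats.chi2.sf(chi2[ok], df=1)
    return chi2, np.clip(p, np.finfo(float).tiny, 1.0)


def cox_score_test(times, events, x) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`cox_score_test_matrix`."""
    chi2, p = cox_score_test_matrix(times, events, np.asarray(x, dtype=float)[None, :])
    return float(chi2[0]), float(p[0])


def _breslow_loglik_U_I(x, first, d, s_event, beta):
    """Breslow partial log-likelihood and its first two derivatives.

    ``x`` is sorted ascending by time; ``first``/``d``/``s_event`` index the
    distinct event times (first risk-set index, event count, event-covariate
    sum).
    """
    w = np.exp(beta * x)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w * x)[::-1])[::-1]
    S2 = np.cumsum((w * x * x)[::-1])[::-1]
    r0, r1, r2 = S0[first], S1[first], S2[first]
    ll = float(np.sum(beta * s_event - d * np.log(r0)))
    U = float(np.sum(s_event - d * r1 / r0))
    I = float(np.sum(d * (r2 / r0 - (r1 / r0) ** 2)))
    return ll, U, I


def cox_univariate(times, events, x, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Univariate Cox PH fit by Newton-Raphson on the Breslow partial likelihood.

    The reported p-value is from the score test evaluated at beta=0 (chi-square
    with 1 df), which remains well-defined even when the MLE diverges.
    """
    t, e = _as_surv_arrays(times, events)
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate must be finite")
    n_events = int(e.sum())
    if np.var(x) == 0 or n_events == 0:
        return CoxFit(
            beta=0.0, se=np.inf, score_stat=0.0, p=1.0,
            converged=False, n_events=n_events, degenerate=True,
        )

    order = np.argsort(t, kind="stable")
    ts, es, xs = t[order], e[order], x[order]
    _, first_all = np.unique(ts, return_index=True)
    d_all = np.add.reduceat(es, first_all)
    keep = d_all > 0
    first, d = first_all[keep], d_all[keep].astype(float)
    s_event = np.add.reduceat(xs * es, first_all)[keep]

    _, U0, I0 = _breslow_loglik_U_I(xs, first, d, s_event, 0.0)
    score_stat = U0**2 / I0 if I0 > 0 else 0.0
    p = float(stats.chi2.sf(score_stat, df=1)) if I0 > 0 else 1.0

    beta = 0.0
    ll, U, I = _breslow_loglik_U_I(xs, first, d, s_event, beta)
    converged = False
    for _ in range(max_iter):
        if I <= 0:
            break
        step = U / I
        new_beta = beta + step
        new_ll, new_U, new_I = _breslow_loglik_U_I(xs, first, d, s_event, new_beta)
        # step-halving if the likelihood decreased
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2
            new_beta = beta + step
            new_ll, new_U, new_I = _breslow_loglik_U_I(xs, first, d, s_event, new_beta)
            halvings += 1
        if abs(new_beta - beta) < tol:
            beta, ll, U, I = new_beta, new_ll, new_U, new_I
            converged = True
            break
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
    se = float(1.0 / np.sqrt(I)) if I > 0 else np.inf
    return CoxFit(
        beta=float(beta), se=se, score_stat=float(score_stat),
        p=max(min(p, 1.0), np.finfo(float).tiny),
        converged=converged, n_events=n_events,
    )


def optimal_cutpoint(
    times, events, marker, lower_q: float = 0.10, upper_q: float = 0.90
) -> CutpointResult:
    """Minimum-log-rank-p threshold scan over an inner quantile band.

    Candidate thresholds are the distinct marker values t with
    quantile(lower_q) <= t < quantile(upper_q); samples split as
    (marker > t) vs (marker <= t). The smallest scanned p wins; ties go to the
    smaller threshold. The minimum p is anti-conservative and should not be
    interpreted at face value.
    """
    t, e = _as_surv_arrays(times, events)
    m = np.asarray(marker, dtype=float)
    if m.shape != t.shape:
        raise ValueError("marker must align with times/events")
    if t.size < 10:
        raise ValueError("cutpoint scan requires at least 10 samples")
    lo, hi = np.quantile(m, [lower_q, upper_q])
    cands = np.unique(m)
    cands = cands[(cands >= lo) & (cands < hi)]
    # a threshold equal to max(marker) would leave the high group empty
    cands = cands[cands < m.max()]
    if cands.size == 0:
        raise ValueError("no candidate thresholds inside the quantile band")

    scanned = []
    best = None
    for c in cands:
        high = m > c
        res = logrank_test(t, e, high.astype(int))
        scanned.append((float(c), res.p))
        if best is None or res.p < best[1]:
            best = (float(c), res.p, int((~high).sum()), int(high.sum()))
    thr, p, n_low, n_high = best
    return CutpointResult(threshold=thr, p=p, n_low=n_low, n_high=n_high, scanned=scanned)
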