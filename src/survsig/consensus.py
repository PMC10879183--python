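"""Risk-group differential expression, Holm control, and cross-cohort
signed consensus with a gene-name-sampling empirical null.

Differential expression uses an empirical-Bayes moderated t: per gene, the
two-group pooled residual variance s_g^2 (d_g = n - 2 df) is shrunk toward a
prior s0^2 with prior df d0, giving the posterior variance
s~_g^2 = (d0 s0^2 + d_g s_g^2)/(d0 + d_g) and a t statistic with d0 + d_g
degrees of freedom. The hyperparameters (d0, s0^2) are estimated by moment
matching on log s_g^2 across genes using digamma/trigamma identities of the
scaled chi-square hierarchy. Family-wise error is controlled by step-down
Holm adjustment.

A consensus gene is one called significant in the same direction in at least
``min_support`` cohorts. Whether the observed consensus-set size exceeds
chance is assessed by gene-name sampling: each null iteration redraws every
cohort's significant list as a uniform random subset of the shared gene
universe of the same size, carrying the cohort's observed up/down direction
counts assigned at random, and recomputes the consensus size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats
from scipy.optimize import brentq

from .cohorts import Cohort

__all__ = [
    "DEResult",
    "ModeratedTParams",
    "ConsensusSet",
    "moderated_t_de",
    "holm_adjust",
    "consensus_genes",
    "consensus_null_p",
    "median_center_by_group",
]

UP, DOWN = "up", "down"


@dataclass(frozen=True)
class DEResult:
    gene: str
    log_fc: float  # high - low mean log2 expression
    t_mod: float
    df_total: float
    p: float
    p_holm: float
    direction: str  # "up" / "down"
    significant: bool


@dataclass(frozen=True)
class ModeratedTParams:
    d0: float  # prior df; may be inf
    s0_sq: float


@dataclass(frozen=True)
class ConsensusSet:
    genes: list  # [(gene, direction, [supporting cohort names]), ...]
    observed_size: int
    n_up: int
    n_down: int
    empirical_p: float | None = None
    n_iter: int = 0
    universe_size: int = 0
    member_set: dict = field(default_factory=dict)  # gene -> direction

    def directions(self) -> dict:
        return {g: d for g, d, _ in self.genes}


def holm_adjust(p_values) -> np.ndarray:
    """Step-down Holm adjusted p-values, in the input order.

    adj_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) over the ascending order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0."""
    if x <= 0:
        return np.inf
    lo, hi = 1e-8, 1e8
    f = lambda y: special.polygamma(1, y) - x
    # trigamma is decreasing; bracket then root-find
    if f(lo) < 0:
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)


def estimate_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedTParams:
    """Moment-match (d0, s0^2) on log s_g^2 under the scaled chi-square
    hierarchy: Var(log s^2) = trigamma(df/2) + trigamma(d0/2)."""
    s_sq = np.asarray(s_sq, dtype=float)
    pos = s_sq[s_sq > 0]
    if pos.size < 2:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.mean(s_sq)) or 1.0)
    z = np.log(pos)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        return ModeratedTParams(d0=np.inf, s0_sq=float(np.exp(np.mean(e))))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def moderated_t_de(
    cohort: Cohort,
    labels,
    alpha: float = 0.05,
    moderated: bool = True,
    prior: ModeratedTParams | None = None,
) -> tuple[list[DEResult], ModeratedTParams]:
    """Two-group (high vs low risk) moderated-t differential expression.

    ``labels`` holds "low"/"high" per sample, aligned with the cohort.
    ``moderated=False`` falls back to the ordinary pooled two-sample t
    (equivalent to d0 = 0) for sensitivity analysis. Returns the per-gene
    results and the hyperparameters used.
    """
    y = np.asarray(labels)
    if y.size != cohort.n_samples:
        raise ValueError("labels must align with cohort samples")
    hi = y == "high"
    lo = y == "low"
    if not (hi.any() and lo.any()):
        raise ValueError("both risk groups must be present")
    n1, n2 = int(lo.sum()), int(hi.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    X = cohort.expr.to_numpy(dtype=float)
    m_hi = X[:, hi].mean(axis=1)
    m_lo = X[:, lo].mean(axis=1)
    log_fc = m_hi - m_lo
    ss = ((X[:, lo] - m_lo[:, None]) ** 2).sum(axis=1) + (
        (X[:, hi] - m_hi[:, None]) ** 2
    ).sum(axis=1)
    d_g = n1 + n2 - 2
    s_sq = ss / d_g

    if moderated:
        params = prior if prior is not None else estimate_variance_prior(s_sq, d_g)
        if np.isinf(params.d0):
            s_tilde_sq = np.full_like(s_sq, params.s0_sq)
            df_total = np.inf
        else:
            s_tilde_sq = (params.d0 * params.s0_sq + d_g * s_sq) / (params.d0 + d_g)
            df_total = params.d0 + d_g
    else:
        params = ModeratedTParams(d0=0.0, s0_sq=0.0)
        s_tilde_sq = s_sq
        df_total = float(d_g)

    se = np.sqrt(s_tilde_sq * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, log_fc / np.where(zero_var, 1.0, se))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p = np.where(zero_var & (log_fc == 0), 1.0, np.clip(p, 0.0, 1.0))

    p_holm = holm_adjust(p)
    results = [
        DEResult(
            gene=g,
            log_fc=float(log_fc[i]),
            t_mod=float(t[i]),
            df_total=float(df_total),
            p=float(p[i]),
            p_holm=float(p_holm[i]),
            direction=UP if log_fc[i] > 0 else DOWN,
            significant=bool(p_holm[i] < alpha),
        )
        for i, g in enumerate(cohort.genes)
    ]
    return results, params


def consensus_genes(
    de_lists: dict[str, list[DEResult]], min_support: int = 2
) -> ConsensusSet:
    """Signed cross-cohort consensus over per-cohort significant DE calls.

    ``de_lists`` maps cohort name to its DEResult list (only entries with
    ``significant=True`` count). A gene joins the consensus iff at least
    ``min_support`` cohorts call it significant in the same direction; a gene
    significant in opposite directions across cohorts is excluded unless one
    direction alone reaches ``min_support`` (ties between directions are
    excluded).
    """
    if len(de_lists) < 2:
        raise ValueError("consensus requires at least 2 cohorts")
    support: dict[str, dict[str, list[str]]] = {}
    for cname, results in de_lists.items():
        for r in results:
            if not r.significant:
                continue
            support.setdefault(r.gene, {UP: [], DOWN: []})[r.direction].append(cname)
    members = []
    for gene in sorted(support):
        ups, downs = support[gene][UP], support[gene][DOWN]
        up_ok, down_ok = len(ups) >= min_support, len(downs) >= min_support
        if up_ok and down_ok:
            if len(ups) == len(downs):
                continue
            direction, cohorts = (UP, ups) if len(ups) > len(downs) else (DOWN, downs)
        elif up_ok:
            direction, cohorts = UP, ups
        elif down_ok:
            direction, cohorts = DOWN, downs
        else:
            continue
        members.append((gene, direction, sorted(cohorts)))
    n_up = sum(1 for _, d, _ in members if d == UP)
    return ConsensusSet(
        genes=members,
        observed_size=len(members),
        n_up=n_up,
        n_down=len(members) - n_up,
        member_set={g: d for g, d, _ in members},
    )


def _null_consensus_sizes(
    counts: list[tuple[int, int]], n_universe: int, min_support: int,
    n_iter: int, rng, chunk: int = 512,
) -> np.ndarray:
    """Consensus sizes under gene-name sampling; vectorized in chunks."""
    sizes = np.empty(n_iter, dtype=np.int32)
    done = 0
    while done < n_iter:
        b = min(chunk, n_iter - done)
        up_sup = np.zeros((b, n_universe), dtype=np.int8)
        down_sup = np.zeros((b, n_universe), dtype=np.int8)
        rows = np.arange(b)[:, None]
        for n_up, n_down in counts:
            m = n_up + n_down
            if m == 0:
                continue
            r = rng.random((b, n_universe))
            idx = np.argsort(r, axis=1)[:, :m]
            # the within-set order is exchangeable, so the first n_up are a
            # uniform random direction assignment
            up_sup[rows, idx[:, :n_up]] += 1
            down_sup[rows, idx[:, n_up:m]] += 1
        member = (up_sup >= min_support) | (down_sup >= min_support)
        both = (up_sup >= min_support) & (down_sup >= min_support) & (up_sup == down_sup)
        sizes[done : done + b] = (member & ~both).sum(axis=1)
        done += b
    return sizes


def consensus_null_p(
    cohort_direction_counts: list[tuple[int, int]],
    universe: list[str],
    observed_size: int,
    min_support: int = 2,
    n_iter: int = 100_000,
    seed: int = 0,
) -> float:
    """One-tailed empirical p for the observed consensus size under
    gene-name sampling.

    ``cohort_direction_counts`` gives each cohort's observed (n_up, n_down)
    significant-call counts. Each of ``n_iter`` iterations redraws every
    cohort's list as a uniform random subset of ``universe`` of the same
    size with directions assigned at random, and recomputes the consensus
    size. Returns (1 + #{null >= observed}) / (1 + n_iter).
    """
    if observed_size < 0:
        raise ValueError("observed_size must be non-negative")
    n_universe = len(universe) if not isinstance(universe, int) else universe
    for n_up, n_down in cohort_direction_counts:
        if n_up + n_down > n_universe:
            raise ValueError("a cohort's list exceeds the universe size")
    if observed_size == 0:
        return 1.0
    rng = np.random.default_rng([seed, 0x5EED])
    sizes = _null_consensus_sizes(
        list(cohort_direction_counts), n_universe, min_support, n_iter, rng
    )
    return float((1 + np.sum(sizes >= observed_size)) / (1 + n_iter))


def median_center_by_group(expr_values, group_labels) -> dict[str, np.ndarray]:
    """Subtract the global median from (log-scale) expression values and
    return them grouped by subtype label, e.g. for plotting summaries."""
    x = np.asarray(expr_values, dtype=float)
    labels = list(group_labels)
    if len(labels) != x.size:
        raise ValueError("labels must align with values")
    if any(l is None or (isinstance(l, float) and np.isnan(l)) for l in labels):
        raise ValueError("unknown (missing) subtype label")
    centered = x - np.median(x)
    out: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(labels):
        out[str(g)] = centered[np.array([l == g for l in labels])]
    return out
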