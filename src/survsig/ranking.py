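"""Bootstrap Cox gene scoring and ranking.

Every gene is scored by resampling patients with replacement B times, fitting
a univariate Cox score test of the gene's log2 expression against survival in
each resample, trimming the most extreme p-values from both tails, and
averaging the inverse of the remainder. Genes are ranked by descending score
and the top-k slice forms the candidate list fed to the risk classifier.

By default one shared sequence of bootstrap index sets is reused across genes
(common random numbers), which makes scores directly comparable between genes
and cuts the cost by a factor of the gene count; per-gene independent
resampling is available via ``shared_indices=False``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohorts import Cohort
from .survival import cox_score_test_matrix

__all__ = [
    "BootstrapConfig",
    "GeneScore",
    "trimmed_inverse_mean",
    "gene_bootstrap_score",
    "rank_genes",
]


@dataclass(frozen=True)
class BootstrapConfig:
    B: int = 5000
    trim_frac: float = 0.05  # trimmed from EACH tail
    top_k: int = 300
    seed: int = 0
    p_floor: float = 1e-16
    shared_indices: bool = True

    def __post_init__(self):
        if not 0 <= self.trim_frac < 0.5:
            raise ValueError("trim_frac must be in [0, 0.5)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.p_floor <= 0:
            raise ValueError("p_floor must be positive")

    @property
    def n_trim(self) -> int:
        return math.floor(self.B * self.trim_frac)


@dataclass(frozen=True)
class GeneScore:
    gene: str
    score: float
    rank: int  # 1 = best
    n_valid_boot: int  # resamples with a non-degenerate Cox fit


def trimmed_inverse_mean(p_values, trim_frac: float, p_floor: float = 1e-16) -> float:
    """Mean of 1/max(p, p_floor) after dropping floor(B*trim_frac) values
    from each tail of the sorted p-values."""
    p = np.sort(np.asarray(p_values, dtype=float))
    if p.size == 0:
        raise ValueError("no p-values to aggregate")
    k = math.floor(p.size * trim_frac)
    kept = p[k : p.size - k] if k > 0 else p
    return float(np.mean(1.0 / np.maximum(kept, p_floor)))


def _bootstrap_pvalues(times, events, X, cfg: BootstrapConfig, rng) -> np.ndarray:
    """(B, n_genes) matrix of score-test p-values over bootstrap resamples.

    Degenerate resamples (zero events or zero covariate variance) contribute
    p = 1 — counted, never dropped — so every gene sees exactly B values.
    """
    n = times.size
    B = cfg.B
    G = X.shape[0]
    P = np.ones((B, G))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        tb, eb = times[idx], events[idx]
        if eb.sum() == 0:
            continue  # p stays 1 for every gene
        _, pb = cox_score_test_matrix(tb, eb, X[:, idx])
        P[b] = pb
    return P


def gene_bootstrap_score(
    times, events, expr_g, cfg: BootstrapConfig, rng=None
) -> tuple[float, int]:
    """Bootstrap score for a single gene: trimmed mean of inverse Cox
    score-test p-values over B patient resamples.

    Returns (score, n_valid_boot). A gene with zero variance in the original
    data cannot be informative; it gets the minimal score 1.0 (all p = 1)
    with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(expr_g, dtype=float)
    if times.size < 10:
        raise ValueError("bootstrap scoring requires n >= 10")
    if events.sum() == 0:
        raise ValueError("bootstrap scoring requires at least one event")
    if np.var(x) == 0:
        warnings.warn("zero-variance expression; score set to minimum", stacklevel=2)
        return 1.0, 0
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    P = _bootstrap_pvalues(times, events, x[None, :], cfg, rng)[:, 0]
    n_valid = int(np.sum(P < 1.0))
    return trimmed_inverse_mean(P, cfg.trim_frac, cfg.p_floor), n_valid


def rank_genes(cohort: Cohort, cfg: BootstrapConfig) -> list[GeneScore]:
    """Score and rank every gene in the cohort; descending score, ties broken
    lexicographically by gene ID.

    Samples are put in a canonical order (sorted by sample ID) before drawing
    bootstrap index sets, so scores do not depend on the storage order of the
    cohort. The first ``cfg.top_k`` entries of the returned list are the
    candidate genes.
    """
    if cohort.events.sum() == 0:
        raise ValueError(f"cohort {cohort.name!r} has no events; cannot rank genes")
    canonical = cohort.reorder_samples(sorted(cohort.samples))
    times, events = canonical.times, canonical.events
    X = canonical.expr.to_numpy(dtype=float)
    genes = canonical.genes
    G = len(genes)

    zero_var = X.var(axis=1) == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance gene(s) scored at the minimum",
            stacklevel=2,
        )

    if cfg.shared_indices:
        rng = np.random.default_rng([cfg.seed, 0xB007])
        P = _bootstrap_pvalues(times, events, X, cfg, rng)
        n_valid = (P < 1.0).sum(axis=0).astype(int)
        scores = np.array(
            [trimmed_inverse_mean(P[:, g], cfg.trim_frac, cfg.p_floor) for g in range(G)]
        )
    else:
        scores = np.empty(G)
        n_valid = np.empty(G, dtype=int)
        ss = np.random.SeedSequence([cfg.seed, 0xB007])
        for g, child in enumerate(ss.spawn(G)):
            if zero_var[g]:
                scores[g], n_valid[g] = 1.0, 0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores[g], n_valid[g] = gene_bootstrap_score(
                    times, events, X[g], cfg, np.random.default_rng(child)
                )
    scores[zero_var] = 1.0
    n_valid[zero_var] = 0

    order = sorted(range(G), key=lambda g: (-scores[g], genes[g]))
    return [
        GeneScore(gene=genes[g], score=float(scores[g]), rank=r + 1,
                  n_valid_boot=int(n_valid[g]))
        for r, g in enumerate(order)
    ]
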