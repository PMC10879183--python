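"""Synthetic multi-cohort expression/survival generator with planted truth.

Emulates the statistical structure of multi-cohort prognostic-signature
studies: several cohorts share a gene universe; a latent two-group risk
structure shifts a planted gene set on the log2 scale; survival follows a
proportional-hazards model driven by the planted genes' standardized
expression; censoring is independent exponential with its rate calibrated to
hit a target censored fraction; each cohort gets its own gene-level batch
shift.

Model, per cohort c, gene g, sample i::

    x_{g,i} = mu_g + b_{g,c} + delta_g * 1[i high-risk] * 1[g planted] + eps
    eps ~ N(0, sigma^2),  b_{g,c} ~ N(0, batch_sd^2),  mu_g ~ N(7, 1)
    T_i ~ Exponential(h0 * exp(sum_planted beta_g * z_{g,i}))
    C_i ~ Exponential(lambda_c),  observed = (min(T,C), 1[T<=C])

where z is the within-cohort z-score of x and beta_g = effect_size * dir_g
with dir_g = +1 for genes shifted up in the high-risk group and -1 for genes
shifted down (half of the planted set each). The gene universe, planted set,
directions, and gene means are derived from ``config.seed`` alone, so every
cohort shares them; all cohort-specific randomness comes from a child seed of
(seed, cohort_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .cohorts import ClinicalRecord, Cohort
import pandas as pd

__all__ = ["SimulationConfig", "PlantedTruth", "simulate_cohort", "simulate_multicohort"]


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 200
    n_samples_per_cohort: tuple[int, ...] = (150, 150, 150)
    n_planted: int = 10
    effect_size: float = 1.0  # log-hazard per unit of standardized expression
    group_shift: float = 1.5  # log2 mean shift of planted genes in high-risk
    high_risk_fraction: float = 0.5
    baseline_hazard: float = 0.1
    censoring_rate: float = 0.3
    cohort_batch_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0 or self.n_planted < 0:
            raise ValueError("n_genes must be positive, n_planted non-negative")
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if not all(n > 0 for n in self.n_samples_per_cohort):
            raise ValueError("all cohort sizes must be positive")
        if not 0 < self.high_risk_fraction < 1:
            raise ValueError("high_risk_fraction must be in (0,1)")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0,1)")
        if self.noise_sd <= 0 or self.cohort_batch_sd < 0:
            raise ValueError("noise_sd must be > 0 and cohort_batch_sd >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")

    @property
    def n_cohorts(self) -> int:
        return len(self.n_samples_per_cohort)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted by the simulator for recovery tests."""

    planted_genes: dict[str, int]  # gene -> +1 (up in high-risk) / -1 (down)
    true_beta: dict[str, float]
    latent_risk: dict[str, np.ndarray] = field(default_factory=dict)  # cohort -> 0/1

    @property
    def planted_set(self) -> set[str]:
        return set(self.planted_genes)


def _shared_universe(config: SimulationConfig):
    """Gene IDs, baseline means, planted set and directions shared by all
    cohorts; deterministic in config.seed."""
    rng = np.random.default_rng([config.seed, 0xC0110])
    genes = [f"G{i:05d}" for i in range(config.n_genes)]
    mu = rng.normal(7.0, 1.0, size=config.n_genes)
    planted_idx = rng.choice(config.n_genes, size=config.n_planted, replace=False)
    # half shifted up in high-risk, half down, to exercise signed consensus
    directions = np.ones(config.n_planted, dtype=int)
    directions[config.n_planted // 2 :] = -1
    planted = {genes[j]: int(directions[k]) for k, j in enumerate(planted_idx)}
    beta = {g: config.effect_size * d for g, d in planted.items()}
    return genes, mu, planted_idx, directions, planted, beta


def _calibrate_censoring_rate(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate lambda_c such that the marginal expected
    censored fraction mean_i[lambda_c/(lambda_c+h_i)] equals ``target``.

    Solved by root-finding on the analytic censoring probability.
    """
    if target <= 0:
        return 0.0

    def frac(lam):
        return float(np.mean(lam / (lam + hazards))) - target

    lo, hi = 1e-12, float(hazards.max())
    while frac(hi) < 0:
        hi *= 10
        if hi > 1e12:
            break
    return brentq(frac, lo, hi, xtol=1e-12, rtol=1e-10)


def simulate_cohort(
    config: SimulationConfig, cohort_index: int
) -> tuple[Cohort, PlantedTruth]:
    """Simulate one cohort; the planted structure is shared across indices.

    Returns the cohort and a :class:`PlantedTruth` whose ``latent_risk`` holds
    this cohort's per-sample 0/1 latent labels.
    """
    if not 0 <= cohort_index < config.n_cohorts:
        raise ValueError(f"cohort_index {cohort_index} out of range")
    genes, mu, planted_idx, directions, planted, beta = _shared_universe(config)
    n = config.n_samples_per_cohort[cohort_index]
    rng = np.random.default_rng([config.seed, cohort_index + 1])
    name = f"cohort{cohort_index + 1}"

    latent = (rng.random(n) < config.high_risk_fraction).astype(int)
    batch = rng.normal(0.0, config.cohort_batch_sd, size=config.n_genes)
    X = mu[:, None] + batch[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n)
    )
    shift = directions * config.group_shift
    X[planted_idx, :] += shift[:, None] * latent[None, :]

    # proportional hazards on within-cohort standardized planted expression
    if config.n_planted > 0:
        Xp = X[planted_idx, :]
        sd = Xp.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        Z = (Xp - Xp.mean(axis=1, keepdims=True)) / sd[:, None]
        eta = (config.effect_size * directions) @ Z
    else:
        eta = np.zeros(n)
    hazards = config.baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0 / hazards)
    lam_c = _calibrate_censoring_rate(hazards, config.censoring_rate)
    if lam_c > 0:
        C = rng.exponential(1.0 / lam_c, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)

    samples = [f"{name}_S{i:04d}" for i in range(n)]
    expr = pd.DataFrame(X, index=genes, columns=samples)
    clinical = [
        ClinicalRecord(s, float(time[i]), int(event[i])) for i, s in enumerate(samples)
    ]
    truth = PlantedTruth(
        planted_genes=planted, true_beta=beta, latent_risk={name: latent}
    )
    return Cohort(name, expr, clinical), truth


def simulate_multicohort(config: SimulationConfig) -> tuple[list[Cohort], PlantedTruth]:
    """Simulate all cohorts sharing one planted truth.

    Cohorts are mutually independent given the shared gene universe; seeds
    are derived deterministically from ``config.seed`` and the cohort index.
    """
    cohorts = []
    latent: dict[str, np.ndarray] = {}
    planted, beta = {}, {}
    for ci in range(config.n_cohorts):
        cohort, truth = simulate_cohort(config, ci)
        cohorts.append(cohort)
        latent.update(truth.latent_risk)
        planted, beta = truth.planted_genes, truth.true_beta
    return cohorts, PlantedTruth(planted_genes=planted, true_beta=beta, latent_risk=latent)
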