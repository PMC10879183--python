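"""End-to-end orchestration: rank -> classify -> DE -> consensus (-> cutpoint).

Per cohort, genes are bootstrap-scored and ranked, the optimal risk
classifier is built by forward selection over the candidate prefix, and
high-vs-low differential expression is computed. Classifiers never cross
cohorts; only the per-cohort significant DE lists are combined into the
signed consensus, whose size is tested against the gene-name-sampling null
over the shared (intersection) gene universe. Optional marker genes get an
optimal-cutpoint Kaplan-Meier split per cohort.

Everything is driven by one :class:`PipelineConfig`; stage seeds are derived
deterministically from the global seed, so identical config => identical
results, byte for byte in the written files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import RiskClassifier, forward_select
from .cohorts import Cohort, read_cohort, write_results
from .consensus import (
    ConsensusSet,
    DEResult,
    consensus_genes,
    consensus_null_p,
    moderated_t_de,
)
from .ranking import BootstrapConfig, GeneScore, rank_genes
from .simulate import SimulationConfig, simulate_multicohort
from .survival import CutpointResult, optimal_cutpoint

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ResultBundle", "run_pipeline", "scores_frame", "de_frame"]


@dataclass(frozen=True)
class PipelineConfig:
    # either paths to (expr, clinical) TSV pairs ...
    cohort_paths: tuple[tuple[str, str], ...] = ()
    cohort_names: tuple[str, ...] = ()
    # ... or a simulation config
    simulation: SimulationConfig | None = None

    B: int = 5000
    trim_frac: float = 0.05
    top_k: int = 300
    G_max: int = 300
    n_folds: int = 10
    n_delta: int = 30
    de_alpha: float = 0.05
    min_support: int = 2
    consensus_iters: int = 100_000
    cutpoint_lower_q: float = 0.10
    cutpoint_upper_q: float = 0.90
    marker_genes: tuple[str, ...] = ()
    seed: int = 0
    out_dir: str | None = None

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "n_samples_per_cohort" in sim:
                sim["n_samples_per_cohort"] = tuple(sim["n_samples_per_cohort"])
            sim = SimulationConfig(**sim)
        paths = tuple(tuple(p) for p in raw.pop("cohort_paths", ()))
        names = tuple(raw.pop("cohort_names", ()))
        markers = tuple(raw.pop("marker_genes", ()))
        return PipelineConfig(
            cohort_paths=paths, cohort_names=names, simulation=sim,
            marker_genes=markers, **raw,
        )


@dataclass
class ResultBundle:
    cohorts: list[Cohort]
    scores: dict[str, list[GeneScore]]
    classifiers: dict[str, RiskClassifier]
    de_tables: dict[str, list[DEResult]]
    consensus: ConsensusSet
    cutpoints: dict[str, dict[str, CutpointResult]] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def scores_frame(scores: list[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(s) for s in scores],
        columns=["gene", "score", "rank", "n_valid_boot"],
    )


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(r) for r in results],
        columns=["gene", "log_fc", "t_mod", "df_total", "p", "p_holm",
                 "direction", "significant"],
    )


def _load_cohorts(config: PipelineConfig):
    if config.simulation is not None:
        cohorts, truth = simulate_multicohort(config.simulation)
        return cohorts, truth
    if not config.cohort_paths:
        raise ValueError("config must provide cohort_paths or a simulation block")
    for expr_path, clin_path in config.cohort_paths:
        for p in (expr_path, clin_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"cohort file not found: {p}")
    names = config.cohort_names or tuple(
        f"cohort{i+1}" for i in range(len(config.cohort_paths))
    )
    cohorts = [
        read_cohort(e, c, n) for (e, c), n in zip(config.cohort_paths, names)
    ]
    return cohorts, None


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run the full multi-cohort pipeline under one config and seed."""
    cohorts, truth = _load_cohorts(config)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(cohorts) + 1)]

    scores: dict[str, list[GeneScore]] = {}
    classifiers: dict[str, RiskClassifier] = {}
    de_tables: dict[str, list[DEResult]] = {}
    for cohort, cseed in zip(cohorts, stage_seeds[:-1]):
        logger.info("ranking genes in %s", cohort.name)
        bcfg = BootstrapConfig(
            B=config.B, trim_frac=config.trim_frac, top_k=config.top_k, seed=cseed
        )
        gs = rank_genes(cohort, bcfg)
        scores[cohort.name] = gs
        candidates = [s.gene for s in gs[: config.top_k]]
        logger.info("forward-selecting classifier in %s", cohort.name)
        clf = forward_select(
            cohort, candidates, G_max=config.G_max, seed=cseed,
            n_folds=config.n_folds, n_delta=config.n_delta,
        )
        classifiers[cohort.name] = clf
        logger.info(
            "%s: %d-gene classifier, logrank p=%.3g, cv error=%.3f",
            cohort.name, len(clf.gene_list), clf.logrank_p, clf.cv_error,
        )
        de, _ = moderated_t_de(cohort, clf.labels, alpha=config.de_alpha)
        de_tables[cohort.name] = de

    universe = sorted(set.intersection(*(set(c.genes) for c in cohorts)))
    cons = consensus_genes(de_tables, min_support=config.min_support)
    counts = []
    for name in de_tables:
        sig = [r for r in de_tables[name] if r.significant]
        counts.append(
            (sum(1 for r in sig if r.direction == "up"),
             sum(1 for r in sig if r.direction == "down"))
        )
    emp_p = consensus_null_p(
        counts, universe, cons.observed_size,
        min_support=config.min_support, n_iter=config.consensus_iters,
        seed=stage_seeds[-1],
    )
    cons = dataclasses.replace(cons, empirical_p=emp_p, n_iter=config.consensus_iters,
                               universe_size=len(universe))

    cutpoints: dict[str, dict[str, CutpointResult]] = {}
    for gene in config.marker_genes:
        cutpoints[gene] = {}
        for cohort in cohorts:
            if gene not in cohort.expr.index:
                logger.warning("marker %s absent from %s; skipped", gene, cohort.name)
                continue
            cutpoints[gene][cohort.name] = optimal_cutpoint(
                cohort.times, cohort.events, cohort.expression_of(gene),
                lower_q=config.cutpoint_lower_q, upper_q=config.cutpoint_upper_q,
            )

    manifest = {
        "survsig_version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("cohort_paths", "cohort_names")
        },
        "cohorts": {c.name: {"n_genes": c.n_genes, "n_samples": c.n_samples}
                    for c in cohorts},
        "universe_size": len(universe),
    }
    if truth is not None:
        manifest["parameters"]["simulation"] = dataclasses.asdict(config.simulation)

    bundle = ResultBundle(
        cohorts=cohorts, scores=scores, classifiers=classifiers,
        de_tables=de_tables, consensus=cons, cutpoints=cutpoints,
        manifest=manifest,
    )
    if config.out_dir:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _classifier_payload(clf: RiskClassifier) -> dict:
    return {
        "gene_list": clf.gene_list,
        "logrank_p": clf.logrank_p,
        "cv_error": clf.cv_error,
        "kmeans_centers": clf.kmeans_centers.tolist(),
        "nsc": {
            "classes": list(clf.nsc.classes),
            "class_centroids": clf.nsc.class_centroids.tolist(),
            "overall_centroid": clf.nsc.overall_centroid.tolist(),
            "pooled_sd": clf.nsc.pooled_sd.tolist(),
            "s0": clf.nsc.s0,
            "delta": clf.nsc.delta,
            "class_priors": clf.nsc.class_priors.tolist(),
        },
        "trace": [
            {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
             for k, v in row.items() if k != "genes"}
            for row in clf.trace.rows
        ],
    }


def _write_bundle(bundle: ResultBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, gs in bundle.scores.items():
        write_results(scores_frame(gs), out_dir / f"scores_{name}.tsv")
    for name, clf in bundle.classifiers.items():
        write_results(_classifier_payload(clf), out_dir / f"classifier_{name}.json")
        labels = pd.DataFrame({
            "sample_id": bundle.cohorts[[c.name for c in bundle.cohorts].index(name)].samples,
            "risk": clf.labels,
        })
        write_results(labels, out_dir / f"labels_{name}.tsv")
    for name, de in bundle.de_tables.items():
        write_results(de_frame(de), out_dir / f"de_{name}.tsv")
    cons = bundle.consensus
    write_results(
        {
            "genes": [
                {"gene": g, "direction": d, "cohorts": c} for g, d, c in cons.genes
            ],
            "observed_size": cons.observed_size,
            "n_up": cons.n_up,
            "n_down": cons.n_down,
            "empirical_p": cons.empirical_p,
            "n_iter": cons.n_iter,
            "universe_size": cons.universe_size,
        },
        out_dir / "consensus.json",
    )
    if bundle.cutpoints:
        payload = {
            gene: {
                name: {"threshold": r.threshold, "p": r.p,
                       "n_low": r.n_low, "n_high": r.n_high}
                for name, r in per.items()
            }
            for gene, per in bundle.cutpoints.items()
        }
        write_results(payload, out_dir / "cutpoints.json")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
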