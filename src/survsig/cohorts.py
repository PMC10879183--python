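"""Cohort containers and TSV/JSON input-output.

A cohort pairs a genes-by-samples log2 expression matrix with a clinical
table (survival time, 0/1 event indicator, optional receptor-status subtype),
with sample order kept aligned between the two. Expression and clinical files
are plain TSV; structured results (classifiers, consensus sets) round-trip
through JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalRecord",
    "Cohort",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "write_results",
    "read_results",
]


class CohortFormatError(ValueError):
    """Raised when an expression/clinical file violates the cohort contract."""


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    time: float
    event: int
    subtype: str | None = None

    def __post_init__(self):
        if not (self.time >= 0 and np.isfinite(self.time)):
            raise CohortFormatError(
                f"sample {self.sample_id!r}: time must be finite and >= 0, got {self.time}"
            )
        if self.event not in (0, 1):
            raise CohortFormatError(
                f"sample {self.sample_id!r}: event must be 0 or 1, got {self.event}"
            )


class Cohort:
    """Aligned expression matrix + clinical table for one dataset.

    Parameters
    ----------
    name : cohort label used in logs and result files.
    expr : DataFrame, genes as index, samples as columns, log2 values.
    clinical : list of ClinicalRecord in the same order as ``expr.columns``.
    """

    def __init__(self, name: str, expr: pd.DataFrame, clinical: list[ClinicalRecord]):
        genes = list(expr.index.astype(str))
        samples = list(expr.columns.astype(str))
        if len(set(genes)) != len(genes):
            dup = pd.Index(genes)[pd.Index(genes).duplicated()][0]
            raise CohortFormatError(f"duplicate gene ID {dup!r}")
        if len(set(samples)) != len(samples):
            dup = pd.Index(samples)[pd.Index(samples).duplicated()][0]
            raise CohortFormatError(f"duplicate sample ID {dup!r}")
        if len(clinical) != len(samples):
            raise CohortFormatError(
                f"{len(clinical)} clinical records for {len(samples)} samples"
            )
        for rec, sid in zip(clinical, samples):
            if rec.sample_id != sid:
                raise CohortFormatError(
                    f"clinical record {rec.sample_id!r} misaligned with sample {sid!r}"
                )
        values = expr.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            g, s = np.argwhere(~np.isfinite(values))[0]
            raise CohortFormatError(
                f"non-finite expression value at gene {genes[g]!r}, sample {samples[s]!r}"
            )
        self.name = name
        self.expr = expr.copy()
        self.expr.index = self.expr.index.astype(str)
        self.expr.columns = self.expr.columns.astype(str)
        self.clinical = list(clinical)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.index)

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.clinical], dtype=float)

    @property
    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.clinical], dtype=int)

    @property
    def subtypes(self) -> list[str | None]:
        return [r.subtype for r in self.clinical]

    def expression_of(self, gene: str) -> np.ndarray:
        if gene not in self.expr.index:
            raise KeyError(f"gene {gene!r} not in cohort {self.name!r}")
        return self.expr.loc[gene].to_numpy(dtype=float)

    def reorder_samples(self, sample_ids: list[str]) -> "Cohort":
        idx = {r.sample_id: r for r in self.clinical}
        return Cohort(self.name, self.expr[sample_ids], [idx[s] for s in sample_ids])

    def __repr__(self) -> str:
        return f"Cohort({self.name!r}, {self.n_genes} genes x {self.n_samples} samples)"


def _read_clinical(clinical_path) -> pd.DataFrame:
    clin = pd.read_csv(clinical_path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "time", "event"}
    missing = required - set(clin.columns)
    if missing:
        raise CohortFormatError(f"clinical file missing column(s): {sorted(missing)}")
    if clin["sample_id"].duplicated().any():
        dup = clin.loc[clin["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise CohortFormatError(f"duplicate sample ID {dup!r} in clinical file")
    return clin


def read_cohort(expr_path, clinical_path, name: str) -> Cohort:
    """Read a cohort from an expression TSV and a clinical TSV.

    Samples present in only one of the two files are dropped with a log
    message; the expression file's sample order is preserved.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise CohortFormatError(f"duplicate gene ID {dup!r} in {expr_path}")
    if expr.columns.duplicated().any():
        dup = expr.columns[expr.columns.duplicated()][0]
        raise CohortFormatError(f"duplicate sample ID {dup!r} in {expr_path}")
    for col in expr.columns:
        bad = pd.to_numeric(expr[col], errors="coerce")
        nonnum = bad.isna() & expr[col].notna()
        if nonnum.any():
            gene = expr.index[nonnum][0]
            raise CohortFormatError(
                f"non-numeric expression cell at gene {gene!r}, sample {col!r} in {expr_path}"
            )
    expr = expr.astype(float)

    clin = _read_clinical(clinical_path)
    clin_ids = set(clin["sample_id"])
    expr_ids = list(expr.columns)
    shared = [s for s in expr_ids if s in clin_ids]
    dropped_expr = len(expr_ids) - len(shared)
    dropped_clin = len(clin_ids) - len(shared)
    if dropped_expr or dropped_clin:
        logger.warning(
            "cohort %s: dropped %d expression-only and %d clinical-only sample(s)",
            name, dropped_expr, dropped_clin,
        )
    if not shared:
        raise CohortFormatError("no samples shared between expression and clinical files")

    clin = clin.set_index("sample_id")
    records = []
    for sid in shared:
        row = clin.loc[sid]
        subtype = None
        if "subtype" in clin.columns and pd.notna(row.get("subtype")):
            subtype = str(row["subtype"])
        try:
            ev = int(row["event"])
        except (TypeError, ValueError) as err:
            raise CohortFormatError(f"sample {sid!r}: non-integer event") from err
        if ev != row["event"]:
            raise CohortFormatError(f"sample {sid!r}: event must be 0 or 1, got {row['event']}")
        records.append(ClinicalRecord(sid, float(row["time"]), ev, subtype))
    return Cohort(name, expr[shared], records)


def write_cohort(cohort: Cohort, expr_path, clinical_path) -> None:
    """Write a cohort back to the expression/clinical TSV pair."""
    Path(expr_path).parent.mkdir(parents=True, exist_ok=True)
    expr = cohort.expr.copy()
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep="\t", float_format="%.10g")
    clin = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in cohort.clinical],
            "time": [r.time for r in cohort.clinical],
            "event": [r.event for r in cohort.clinical],
            "subtype": [r.subtype if r.subtype is not None else "" for r in cohort.clinical],
        }
    )
    clin.to_csv(clinical_path, sep="\t", index=False, float_format="%.10g")


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_results(obj, path) -> None:
    """Write a pipeline result to disk.

    DataFrames (score tables, DE tables, selection traces) go to TSV with a
    header; dataclass results and dicts (classifier, consensus set, manifest)
    go to JSON. Round-tripping preserves text exactly and floats to better
    than 1e-12 relative.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", index=False, float_format="%.17g")
        return
    payload = _jsonify(obj)
    if not isinstance(payload, (dict, list)):
        raise TypeError(f"unsupported result type {type(obj).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_results(path):
    """Read back a result written by :func:`write_results` (TSV -> DataFrame,
    JSON -> dict/list)."""
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        return pd.read_csv(path, sep="\t")
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
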