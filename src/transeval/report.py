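"""Comparison-report orchestration and shared summary arithmetic.

``evaluate`` runs the full per-assembly pipeline — length statistics,
redundancy removal, reference-based completeness/contiguity per threshold
and per reference database, and the chimera scan — over a multi-assembly
configuration and assembles one comparison table, the shape used to choose
among competing de novo assemblies of the same read set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .assembly import filter_min_length, length_stats
from .chimera import ChimeraParams, detect_chimeras, chimera_rate
from .io import read_fasta, read_hits_table, read_lengths_tsv, group_hits_by_query
from .refeval import coverage_summary, completeness, contiguity

logger = logging.getLogger("transeval")

__all__ = ["EvaluationReport", "evaluate", "pass_percentage", "round_half_up"]


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero for positives)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pass_percentage(passed: int, total: int, decimals: int = 1) -> float:
    """Percent of items passing a filter, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= passed <= total:
        raise ValueError("need 0 <= passed <= total")
    return round_half_up(100.0 * passed / total, decimals)


@dataclass
class AssemblyRow:
    label: str
    total_contigs: int
    mean_length: int
    nonredundant_contigs: int
    n50: int
    chimera_count: int
    chimera_pct: float
    metrics: dict[str, dict[float, dict[str, float]]] = field(default_factory=dict)
    # metrics[db_label][threshold] = {"completeness": ..., "contiguity": ...}


@dataclass
class EvaluationReport:
    rows: list[AssemblyRow]
    thresholds: list[float]
    db_labels: list[str]
    expressed: dict[str, list[str]]  # per db: the expressed reference ids
    params: dict[str, Any] = field(default_factory=dict)

    def to_frame(self, as_fraction: bool = False) -> pd.DataFrame:
        records = []
        for row in self.rows:
            rec: dict[str, Any] = {
                "assembly": row.label,
                "total_contigs": row.total_contigs,
                "mean_length": row.mean_length,
                "nonredundant_contigs": row.nonredundant_contigs,
                "n50": row.n50,
                "chimera_count": row.chimera_count,
                "chimera_pct": row.chimera_pct,
            }
            for db in self.db_labels:
                for t in self.thresholds:
                    vals = row.metrics[db][t]
                    for metric in ("contiguity", "completeness"):
                        v = vals[metric]
                        if as_fraction:
                            rec[f"{metric}_{int(t * 100)}_{db}"] = round(v / 100.0, 3)
                        else:
                            rec[f"{metric}_{int(t * 100)}_{db}"] = round_half_up(v, 1)
            records.append(rec)
        return pd.DataFrame(records)

    def to_tsv(self, path: str | Path, as_fraction: bool = False) -> None:
        self.to_frame(as_fraction).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "db_labels": self.db_labels,
            "params": self.params,
            "rows": [asdict(r) for r in self.rows],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def evaluate(config: Mapping[str, Any]) -> EvaluationReport:
    """Run the whole evaluation over a multi-assembly configuration.

    Config keys::

        assemblies: [{label, fasta, hits: {db_label: hit_table_path}}, ...]
        references: {db_label: fasta_path | lengths_tsv_path}
        thresholds: [0.8] (ascending)
        min_len: 200
        expressed: {db_label: [ref ids]}  (optional; default = union of
            references hit by any assembly, per database)
        chimera: {min_identity, min_seg_len, max_q_overlap, min_self_overlap}

    All input files are checked before any computation starts.  The
    expressed set is computed once and shared across assemblies so the
    completeness/contiguity denominators stay comparable.
    """
    assemblies = config.get("assemblies", [])
    if not assemblies:
        raise ValueError("config lists no assemblies")
    references = config.get("references", {})
    if not references:
        raise ValueError("config lists no reference databases")
    thresholds = sorted(config.get("thresholds", [0.8]))
    min_len = int(config.get("min_len", 200))
    chim_params = ChimeraParams(**config.get("chimera", {}))

    # fail fast on missing files
    paths = [a["fasta"] for a in assemblies]
    paths += [p for a in assemblies for p in a.get("hits", {}).values()]
    paths += list(references.values())
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    ref_lengths: dict[str, dict[str, int]] = {}
    for db, path in references.items():
        p = str(path)
        if p.endswith((".tsv", ".txt")):
            ref_lengths[db] = read_lengths_tsv(p)
        else:
            ref_lengths[db] = read_fasta(p).lengths()

    # load everything once
    loaded = []
    for a in assemblies:
        contigs = filter_min_length(read_fasta(a["fasta"]), min_len)
        hits = {db: read_hits_table(p) for db, p in a.get("hits", {}).items()}
        loaded.append((a["label"], contigs, hits))
        logger.info(
            "assembly %s: %d contigs after min-length %d filter",
            a["label"], len(contigs), min_len,
        )

    # expressed set per database: caller-supplied, else union of refs hit
    # by ANY assembly under comparison
    expressed_cfg = config.get("expressed", {})
    expressed: dict[str, list[str]] = {}
    for db in references:
        if db in expressed_cfg:
            expressed[db] = sorted(expressed_cfg[db])
        else:
            seen: set[str] = set()
            for _, _, hits in loaded:
                for h in hits.get(db, []):
                    seen.add(h.subject_id)
            expressed[db] = sorted(seen)

    rows = []
    for label, contigs, hits in loaded:
        stats = length_stats(contigs)
        all_hits = [h for db_hits in hits.values() for h in db_hits]
        calls = detect_chimeras(group_hits_by_query(all_hits), chim_params)
        pct = chimera_rate(len(calls), stats.nonredundant_contigs)
        metrics: dict[str, dict[float, dict[str, float]]] = {}
        for db in references:
            cov = coverage_summary(hits.get(db, []), ref_lengths[db])
            metrics[db] = {}
            for t in thresholds:
                if expressed[db]:
                    metrics[db][t] = {
                        "completeness": completeness(cov, expressed[db], t),
                        "contiguity": contiguity(cov, expressed[db], t),
                    }
                else:
                    metrics[db][t] = {"completeness": 0.0, "contiguity": 0.0}
        rows.append(
            AssemblyRow(
                label=label,
                total_contigs=stats.total_contigs,
                mean_length=stats.mean_length,
                nonredundant_contigs=stats.nonredundant_contigs,
                n50=stats.n50,
                chimera_count=len(calls),
                chimera_pct=pct,
                metrics=metrics,
            )
        )
        logger.info(
            "assembly %s: n50=%d nonredundant=%d chimeras=%d (%.2f%%)",
            label, stats.n50, stats.nonredundant_contigs, len(calls), pct,
        )

    return EvaluationReport(
        rows=rows,
        thresholds=thresholds,
        db_labels=list(references),
        expressed=expressed,
        params={"min_len": min_len, "chimera": asdict(chim_params)},
    )
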