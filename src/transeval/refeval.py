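"""Reference-based assembly quality metrics.

Given tabular alignment hits of assembled contigs against a reference
transcript (or protein) catalog, this module computes:

* per-reference coverage — the fraction of each reference covered by the
  union of all hit intervals, and by the single best-covering contig;
* completeness at a threshold t — the percentage of expressed reference
  transcripts whose all-contig union coverage is >= t;
* contiguity at a threshold t — the percentage covered >= t by one single
  contig (a full-length-ness measure: fragmented assemblies score low);
* the Ortholog Hit Ratio (OHR) — per contig, the fraction of its best
  reference subject covered by that contig's merged hit intervals, where a
  value near 1.0 means the transcript was assembled to full length.

Overlapping HSPs are always union-merged, never summed, so no fraction can
exceed 1.  Coverage is measured on the subject (reference) axis in subject
units.  The "expressed" denominator is caller-supplied; the conventional
choice is the union of references hit by any assembly under comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import HitRecord, NormalizedHit

__all__ = [
    "RefCoverage",
    "CoverageSummary",
    "OhrRecord",
    "coverage_summary",
    "completeness",
    "contiguity",
    "metric_curve",
    "ortholog_hit_ratio",
]


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total length of the union of 0-based half-open intervals."""
    ivs = sorted(intervals)
    total = 0
    cur_lo, cur_hi = None, None
    for lo, hi in ivs:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        elif hi > cur_hi:
            cur_hi = hi
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


@dataclass(frozen=True)
class RefCoverage:
    ref_length: int
    covered_all: float
    covered_best_single: float
    best_contig_id: str | None


@dataclass
class CoverageSummary:
    """Per-reference coverage fractions, all-contig union and best single contig."""

    per_ref: dict[str, RefCoverage]

    def __getitem__(self, ref_id: str) -> RefCoverage:
        return self.per_ref[ref_id]

    def refs(self) -> list[str]:
        return list(self.per_ref)


@dataclass(frozen=True)
class OhrRecord:
    contig_id: str
    subject_id: str
    ohr: float


def _normalize(hits: Sequence[HitRecord | NormalizedHit]) -> list[NormalizedHit]:
    return [h.normalized() if isinstance(h, HitRecord) else h for h in hits]


def coverage_summary(
    hits: Sequence[HitRecord | NormalizedHit],
    ref_lengths: Mapping[str, int],
) -> CoverageSummary:
    """Compute per-reference union coverage and best-single-contig coverage.

    Every reference in ``ref_lengths`` gets an entry; references without
    hits get zero coverage and no best contig.  A hit extending beyond its
    subject's declared length is a hard error.
    """
    norm = _normalize(hits)
    by_ref: dict[str, list[NormalizedHit]] = {}
    for h in norm:
        if h.subject_id not in ref_lengths:
            raise ValueError(f"hit subject {h.subject_id!r} not in ref_lengths")
        if h.s_interval[1] > ref_lengths[h.subject_id]:
            raise ValueError(
                f"hit {h.query_id!r} -> {h.subject_id!r} extends to "
                f"{h.s_interval[1]} beyond reference length "
                f"{ref_lengths[h.subject_id]}"
            )
        by_ref.setdefault(h.subject_id, []).append(h)

    per_ref: dict[str, RefCoverage] = {}
    for ref_id, length in ref_lengths.items():
        ref_hits = by_ref.get(ref_id, [])
        if not ref_hits:
            per_ref[ref_id] = RefCoverage(length, 0.0, 0.0, None)
            continue
        covered_all = union_length(h.s_interval for h in ref_hits) / length
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for h in ref_hits:
            by_contig.setdefault(h.query_id, []).append(h.s_interval)
        # deterministic tie-break: largest union, then smallest contig id
        best_id, best_cov = None, 0
        for contig_id in sorted(by_contig):
            cov = union_length(by_contig[contig_id])
            if cov > best_cov:
                best_id, best_cov = contig_id, cov
        per_ref[ref_id] = RefCoverage(
            ref_length=length,
            covered_all=covered_all,
            covered_best_single=best_cov / length,
            best_contig_id=best_id,
        )
    return CoverageSummary(per_ref)


def _pass_pct(cov: CoverageSummary, expressed: Iterable[str], threshold: float, attr: str) -> float:
    ids = list(expressed)
    if not ids:
        raise ValueError("expressed reference set is empty")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    missing = [r for r in ids if r not in cov.per_ref]
    if missing:
        raise ValueError(f"expressed references without coverage entries: {missing[:5]}")
    passed = sum(1 for r in ids if getattr(cov.per_ref[r], attr) >= threshold)
    return 100.0 * passed / len(ids)


def completeness(cov: CoverageSummary, expressed: Iterable[str], threshold: float) -> float:
    """Percent of expressed references with union coverage >= threshold (inclusive)."""
    return _pass_pct(cov, expressed, threshold, "covered_all")


def contiguity(cov: CoverageSummary, expressed: Iterable[str], threshold: float) -> float:
    """Percent of expressed references covered >= threshold by a single contig."""
    return _pass_pct(cov, expressed, threshold, "covered_best_single")


def metric_curve(
    cov: CoverageSummary,
    expressed: Iterable[str],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Completeness and contiguity across a sweep of coverage thresholds.

    Both columns are non-increasing in the threshold.
    """
    ids = list(expressed)
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = [
        {
            "threshold": t,
            "completeness": completeness(cov, ids, t),
            "contiguity": contiguity(cov, ids, t),
        }
        for t in thresholds
    ]
    return pd.DataFrame(rows, columns=["threshold", "completeness", "contiguity"])


def ortholog_hit_ratio(
    hits: Sequence[HitRecord | NormalizedHit],
    ref_lengths: Mapping[str, int],
) -> list[OhrRecord]:
    """Ortholog Hit Ratio per contig against its best-matching reference.

    The best subject for a contig maximizes the summed bitscore over that
    contig–subject pair (ties: lowest summed evalue, then lexicographically
    smallest subject id).  OHR is the union of the pair's subject intervals
    over the reference length, capped at 1.0.  Contigs without hits are
    simply absent from the result.
    """
    norm = _normalize(hits)
    pair: dict[tuple[str, str], list[NormalizedHit]] = {}
    for h in norm:
        if h.subject_id not in ref_lengths:
            raise ValueError(f"hit subject {h.subject_id!r} not in ref_lengths")
        pair.setdefault((h.query_id, h.subject_id), []).append(h)

    per_contig: dict[str, list[tuple[float, float, str]]] = {}
    for (qid, sid), ph in pair.items():
        score = sum(h.bitscore for h in ph)
        ev = sum(h.evalue for h in ph)
        per_contig.setdefault(qid, []).append((score, ev, sid))

    out: list[OhrRecord] = []
    for qid in sorted(per_contig):
        candidates = per_contig[qid]
        # max bitscore; ties -> min evalue; ties -> lexicographic subject
        best = max(candidates, key=lambda c: (c[0], -c[1], _NegStr(c[2])))
        sid = best[2]
        cov = union_length(h.s_interval for h in pair[(qid, sid)])
        out.append(OhrRecord(qid, sid, min(1.0, cov / ref_lengths[sid])))
    return out


class _NegStr:
    """Reverses string ordering so max() picks the lexicographically smallest."""

    __slots__ = ("s",)

    def __init__(self, s: str) -> None:
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s
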