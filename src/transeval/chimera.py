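"""Detection and cutting of chimeric contigs from alignment hit tables.

A trans-chimera joins fragments of two different transcripts into one
contig; a self-chimera duplicates (or inverts) a fragment of a single
transcript.  Both are misassembly artifacts, common in polyploid
transcriptomes, and both leave a characteristic footprint in a translated
or nucleotide search against a reference catalog: two (or more)
query-disjoint alignment segments that cannot belong to one collinear
transcript — either they match different subjects, or they match the same
subject twice over (overlapping subject intervals, or opposite
orientations).

The scan works per contig: filter hits by identity and length, merge
same-subject collinear HSPs into segments, then look for offending
query-disjoint segment pairs.  Called contigs are cut at the midpoint of
the inter-segment query gap, which minimizes the worst-case breakpoint
error absent per-base evidence between segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import HitRecord, NormalizedHit, SequenceSet, SeqEntry

__all__ = [
    "ChimeraParams",
    "Segment",
    "SegmentationResult",
    "ChimeraCall",
    "segment_hits",
    "detect_chimeras",
    "cut_chimeras",
    "chimera_rate",
]


@dataclass(frozen=True)
class ChimeraParams:
    """Thresholds for the chimera scan.

    min_identity: percent identity below which hits are ignored.
    min_seg_len: minimum alignment length (query units) for a hit to count.
    max_q_overlap: two segments whose query intervals overlap by no more
        than this many units are treated as query-disjoint; larger overlaps
        are conflicting evidence, not chimera evidence.
    min_self_overlap: minimum mutual subject-interval overlap (fraction of
        the shorter segment) for two same-subject segments to indicate a
        self-chimera.
    diag_tolerance: allowed drift of the alignment diagonal when merging
        same-subject collinear HSPs into one segment.
    """

    min_identity: float = 30.0
    min_seg_len: int = 100
    max_q_overlap: int = 60
    min_self_overlap: float = 0.2
    diag_tolerance: int = 60


@dataclass(frozen=True)
class Segment:
    query_id: str
    subject_id: str
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    orientation: int


@dataclass
class SegmentationResult:
    segments: list[Segment]
    conflicts: list[tuple[int, int]] = field(default_factory=list)  # index pairs


@dataclass(frozen=True)
class ChimeraCall:
    contig_id: str
    kind: str  # "trans" | "self"
    segments: tuple[Segment, ...]
    breakpoints: tuple[int, ...]  # 0-based; cut BEFORE the position


def _q_overlap(a: Segment, b: Segment) -> int:
    lo = max(a.q_interval[0], b.q_interval[0])
    hi = min(a.q_interval[1], b.q_interval[1])
    return max(0, hi - lo)


def _s_overlap_frac(a: Segment, b: Segment) -> float:
    lo = max(a.s_interval[0], b.s_interval[0])
    hi = min(a.s_interval[1], b.s_interval[1])
    if hi <= lo:
        return 0.0
    shorter = min(
        a.s_interval[1] - a.s_interval[0], b.s_interval[1] - b.s_interval[0]
    )
    return (hi - lo) / shorter


def segment_hits(
    contig_hits: Sequence[HitRecord | NormalizedHit],
    params: ChimeraParams = ChimeraParams(),
) -> SegmentationResult:
    """Filter and merge one contig's hits into alignment segments.

    Hits below ``min_identity`` or shorter than ``min_seg_len`` are dropped.
    Hits to the same subject with the same orientation and a consistent
    diagonal (subject offset tracking query offset within
    ``diag_tolerance``) are merged — a fragmented but collinear alignment is
    one segment, not chimera evidence.  Segment pairs overlapping more than
    ``max_q_overlap`` on the query are reported as conflicts.
    """
    norm = [h.normalized() if isinstance(h, HitRecord) else h for h in contig_hits]
    qids = {h.query_id for h in norm}
    if len(qids) > 1:
        raise ValueError(f"hits from multiple queries: {sorted(qids)}")
    usable = [
        h
        for h in norm
        if h.pct_identity >= params.min_identity and h.aln_length >= params.min_seg_len
    ]
    # group by (subject, orientation), sort by query start, chain-merge
    groups: dict[tuple[str, int], list[NormalizedHit]] = {}
    for h in usable:
        groups.setdefault((h.subject_id, h.orientation), []).append(h)

    segments: list[Segment] = []
    for (sid, orient), hs in groups.items():
        hs.sort(key=lambda h: h.q_interval)
        chain: list[NormalizedHit] = []
        for h in hs:
            if chain and _diag_compatible(chain[-1], h, orient, params.diag_tolerance):
                chain.append(h)
            else:
                if chain:
                    segments.append(_chain_to_segment(chain, sid, orient))
                chain = [h]
        if chain:
            segments.append(_chain_to_segment(chain, sid, orient))

    segments.sort(key=lambda s: s.q_interval)
    conflicts = [
        (i, j)
        for i in range(len(segments))
        for j in range(i + 1, len(segments))
        if _q_overlap(segments[i], segments[j]) > params.max_q_overlap
    ]
    return SegmentationResult(segments=segments, conflicts=conflicts)


def _diag_compatible(
    prev: NormalizedHit, nxt: NormalizedHit, orient: int, tol: int
) -> bool:
    # diagonal = subject position minus query position (forward), or
    # subject position plus query position (reverse-orientation matches).
    if orient == 1:
        d_prev = prev.s_interval[0] - prev.q_interval[0]
        d_next = nxt.s_interval[0] - nxt.q_interval[0]
    else:
        d_prev = prev.s_interval[1] + prev.q_interval[0]
        d_next = nxt.s_interval[1] + nxt.q_interval[0]
    return abs(d_next - d_prev) <= tol


def _chain_to_segment(chain: list[NormalizedHit], sid: str, orient: int) -> Segment:
    q_lo = min(h.q_interval[0] for h in chain)
    q_hi = max(h.q_interval[1] for h in chain)
    s_lo = min(h.s_interval[0] for h in chain)
    s_hi = max(h.s_interval[1] for h in chain)
    return Segment(chain[0].query_id, sid, (q_lo, q_hi), (s_lo, s_hi), orient)


def detect_chimeras(
    hits_by_contig: Mapping[str, Sequence[HitRecord | NormalizedHit]],
    params: ChimeraParams = ChimeraParams(),
) -> list[ChimeraCall]:
    """Scan every contig's hits and call trans- and self-chimeras.

    A contig is trans-chimeric when it carries >= 2 query-disjoint segments
    matching different subjects; self-chimeric when >= 2 query-disjoint
    segments match the same subject with mutually overlapping subject
    intervals (>= ``min_self_overlap`` of the shorter) or with opposite
    orientations.  A single segment, or a collinear multi-HSP structure
    (merged into one segment), is never called.  Breakpoints fall at the
    midpoint of the query gap between adjacent offending segments; an
    abutting pair is cut exactly at the junction.
    """
    calls: list[ChimeraCall] = []
    for contig_id in sorted(hits_by_contig):
        seg_result = segment_hits(hits_by_contig[contig_id], params)
        segs = seg_result.segments
        if len(segs) < 2:
            continue
        conflict_pairs = set(seg_result.conflicts)

        trans_pairs: list[tuple[int, int]] = []
        self_pairs: list[tuple[int, int]] = []
        for i in range(len(segs)):
            for j in range(i + 1, len(segs)):
                if (i, j) in conflict_pairs:
                    continue  # heavy query overlap: conflicting, not chimeric
                a, b = segs[i], segs[j]
                if a.subject_id != b.subject_id:
                    trans_pairs.append((i, j))
                elif (
                    a.orientation != b.orientation
                    or _s_overlap_frac(a, b) >= params.min_self_overlap
                ):
                    self_pairs.append((i, j))

        if not trans_pairs and not self_pairs:
            continue
        kind = "trans" if trans_pairs else "self"
        offending = trans_pairs if trans_pairs else self_pairs
        involved = sorted({i for pair in offending for i in pair})
        # breakpoints between adjacent involved segments along the query
        breakpoints = []
        offend_set = {frozenset(p) for p in offending}
        for a_idx, b_idx in zip(involved, involved[1:]):
            if frozenset((a_idx, b_idx)) not in offend_set:
                # adjacent involved segments that are not themselves an
                # offending pair (e.g. collinear pieces of one side)
                continue
            a, b = segs[a_idx], segs[b_idx]
            bp = (a.q_interval[1] + b.q_interval[0]) // 2
            breakpoints.append(bp)
        if not breakpoints:  # offending pair not adjacent: cut between extremes
            i, j = offending[0]
            a, b = segs[i], segs[j]
            breakpoints.append((a.q_interval[1] + b.q_interval[0]) // 2)
        calls.append(
            ChimeraCall(
                contig_id=contig_id,
                kind=kind,
                segments=tuple(segs),
                breakpoints=tuple(sorted(set(breakpoints))),
            )
        )
    return calls


def cut_chimeras(sset: SequenceSet, calls: Iterable[ChimeraCall]) -> SequenceSet:
    """Replace each called contig by its pieces, ids suffixed ``_part1..k``.

    Cuts happen BEFORE each breakpoint position (0-based).  Total bases are
    conserved and uncalled contigs pass through untouched.
    """
    by_id = {c.contig_id: c for c in calls}
    out: list[SeqEntry] = []
    for rec in sset:
        call = by_id.get(rec.id)
        if call is None:
            out.append(rec)
            continue
        seq = rec.sequence
        for bp in call.breakpoints:
            if not 0 < bp < len(seq):
                raise ValueError(
                    f"breakpoint {bp} outside contig {rec.id!r} (len {len(seq)})"
                )
        bounds = [0, *sorted(call.breakpoints), len(seq)]
        for k, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
            out.append(SeqEntry(f"{rec.id}_part{k}", seq[lo:hi], rec.description))
    return SequenceSet(records=out, alphabet=sset.alphabet)


def chimera_rate(n_chimeric: int, n_nonredundant: int) -> float:
    """Chimera percentage: 100 * chimeric / nonredundant contigs, 2 decimals."""
    if n_nonredundant <= 0:
        raise ValueError("nonredundant contig count must be positive")
    if not 0 <= n_chimeric <= n_nonredundant:
        raise ValueError("need 0 <= n_chimeric <= n_nonredundant")
    from .report import round_half_up

    return round_half_up(100.0 * n_chimeric / n_nonredundant, 2)
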