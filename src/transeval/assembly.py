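"""Contig-level assembly statistics and redundancy removal.

Implements the per-assembly bookkeeping used to compare de novo
transcriptome assemblies: minimum-length filtering, contig counts, mean
length, N50, and removal of redundant contigs, where redundancy means 100%
nucleotide identity — a contig identical to, or an exact substring of,
another contig on either strand.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from .io import SequenceSet, SeqEntry, reverse_complement

__all__ = [
    "AssemblyStats",
    "filter_min_length",
    "n50",
    "deduplicate",
    "length_stats",
    "merge_assemblies",
]


@dataclass(frozen=True)
class AssemblyStats:
    """Summary statistics for one assembly (one comparison-table row)."""

    total_contigs: int
    nonredundant_contigs: int
    total_bases: int
    mean_length: int  # rounded to nearest base, as comparison tables print it
    n50: int


def filter_min_length(sset: SequenceSet, min_len: int) -> SequenceSet:
    """Keep contigs of length >= ``min_len`` (boundary inclusive), preserving order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    kept = [r for r in sset if len(r.sequence) >= min_len]
    return SequenceSet(records=kept, alphabet=sset.alphabet)


def n50(lengths: list[int]) -> int:
    """Standard N50: the smallest length L such that contigs >= L hold half the bases.

    Computed by sorting descending and accumulating until the running sum
    reaches half of the total.
    """
    if not lengths:
        raise ValueError("n50 of an empty length list is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("lengths must be positive")
    ordered = sorted(lengths, reverse=True)
    half = sum(ordered) / 2
    acc = 0
    for length in ordered:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def deduplicate(
    sset: SequenceSet,
) -> tuple[SequenceSet, list[tuple[str, str, str]]]:
    """Remove 100%-identical and exactly contained contigs (both strands).

    A contig is redundant when its sequence equals, or occurs as an exact
    substring of, another contig — on the forward strand or as a reverse
    complement.  Within a redundancy cluster the longest sequence is kept;
    equal-length ties keep the lexicographically smallest id.  Returns the
    reduced set plus ``(removed_id, kept_id, reason)`` tuples with reason in
    ``{"identical", "contained", "contained_rc"}``.

    The search concatenates retained candidates (longest first) so each
    containment test is two C-level substring scans bounded to strictly
    longer sequences; removal is resolved transitively to the final kept
    representative.
    """
    if sset.alphabet != "nucleotide":
        raise ValueError("deduplicate operates on nucleotide sets")

    # Longest first; ties by id so the lexicographically smallest id is the
    # cluster representative among equal-length duplicates.
    order = sorted(sset.records, key=lambda r: (-len(r.sequence), r.id))

    removed: list[tuple[str, str, str]] = []
    removal_map: dict[str, tuple[str, str]] = {}  # removed id -> (kept id, reason)

    # Pass 1: exact duplicates (same strand) and reverse-complement equals.
    by_seq: dict[str, str] = {}
    survivors: list[SeqEntry] = []
    for rec in order:
        fwd = by_seq.get(rec.sequence)
        if fwd is not None:
            removal_map[rec.id] = (fwd, "identical")
            continue
        rc = by_seq.get(reverse_complement(rec.sequence))
        if rc is not None:
            removal_map[rec.id] = (rc, "contained_rc")
            continue
        by_seq[rec.sequence] = rec.id
        survivors.append(rec)

    # Pass 2: containment in a strictly longer sequence.  Containment is
    # transitive (up to strand flips), so testing against *all* strictly
    # longer sequences — removed or not — is equivalent to testing against
    # retained ones, and lets us search one prefix of a single big string.
    sep = "#"
    big = sep.join(r.sequence for r in survivors) + sep
    offsets = []  # start offset of each survivor in `big`
    pos = 0
    for r in survivors:
        offsets.append(pos)
        pos += len(r.sequence) + 1
    # end offset in `big` of the block of sequences strictly longer than x
    kept: list[SeqEntry] = []
    for idx, rec in enumerate(survivors):
        # first survivor index with length <= len(rec): survivors are sorted
        # by descending length, so scan back from idx.
        j = idx
        while j > 0 and len(survivors[j - 1].sequence) == len(rec.sequence):
            j -= 1
        end = offsets[j]  # big[:end] holds all strictly longer survivors
        host = -1
        reason = ""
        if end > 0:
            p = big.find(rec.sequence, 0, end)
            if p >= 0:
                host, reason = p, "contained"
            else:
                p = big.find(reverse_complement(rec.sequence), 0, end)
                if p >= 0:
                    host, reason = p, "contained_rc"
        if host >= 0:
            host_idx = bisect.bisect_right(offsets, host) - 1
            removal_map[rec.id] = (survivors[host_idx].id, reason)
        else:
            kept.append(rec)

    # Resolve chains: the kept representative must itself be retained.
    def resolve(rid: str) -> tuple[str, str]:
        kept_id, reason = removal_map[rid]
        while kept_id in removal_map:
            nxt_id, nxt_reason = removal_map[kept_id]
            # strand flips compose: rc of rc is forward
            if reason == "contained_rc" and nxt_reason == "contained_rc":
                reason = "contained"
            elif "contained_rc" in (reason, nxt_reason):
                reason = "contained_rc"
            elif reason == "identical" and nxt_reason == "identical":
                reason = "identical"
            else:
                reason = "contained"
            kept_id = nxt_id
        return kept_id, reason

    kept_ids = {r.id for r in kept}
    for rid in removal_map:
        kid, reason = resolve(rid)
        assert kid in kept_ids
        removed.append((rid, kid, reason))

    # Preserve the input order of retained records.
    kept_set = {r.id for r in kept}
    retained = [r for r in sset.records if r.id in kept_set]
    return SequenceSet(records=retained, alphabet=sset.alphabet), removed


def length_stats(sset: SequenceSet) -> AssemblyStats:
    """Full length statistics for one assembly; nonredundant count via dedup."""
    if len(sset) == 0:
        raise ValueError("length_stats of an empty assembly is undefined")
    lengths = [len(r.sequence) for r in sset]
    total_bases = sum(lengths)
    nonredundant, _ = deduplicate(sset)
    return AssemblyStats(
        total_contigs=len(sset),
        nonredundant_contigs=len(nonredundant),
        total_bases=total_bases,
        mean_length=round(total_bases / len(lengths)),
        n50=n50(lengths),
    )


def merge_assemblies(
    sets: list[SequenceSet], labels: list[str]
) -> SequenceSet:
    """Label-prefix and union multiple assemblies, then dedup at 100% identity.

    Mirrors merging per-k-mer assemblies from one assembler into a single
    set.  Retained ids look like ``label:original_id`` so provenance stays
    recoverable.
    """
    if len(sets) != len(labels):
        raise ValueError("need one label per assembly")
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    combined = [
        SeqEntry(f"{label}:{rec.id}", rec.sequence, rec.description)
        for label, sset in zip(labels, sets)
        for rec in sset
    ]
    merged = SequenceSet(records=combined, alphabet="nucleotide")
    reduced, _ = deduplicate(merged)
    return reduced
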