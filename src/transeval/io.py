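"""Readers and writers for the formats every evaluation stage touches.

Four carriers cover the whole pipeline: FASTA sequence sets (contigs,
reference transcripts, coding sequences), 12-column tab-separated alignment
hit tables (the classic tabular search output: query, subject, %identity,
length, mismatches, gap opens, qstart, qend, sstart, send, evalue,
bitscore), per-transcript fragment-count tables, and qPCR crossing-point
(Cp) tables with an embedded dilution-series design.

Coordinate convention: hit tables carry 1-based inclusive coordinates and
encode a reverse-orientation subject match as ``s_start > s_end``.  All
downstream interval arithmetic uses 0-based half-open intervals on the
forward strand; :meth:`HitRecord.normalized` is the single place where that
conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceSet",
    "HitRecord",
    "CpTable",
    "read_fasta",
    "write_fasta",
    "read_hits_table",
    "write_hits_table",
    "read_cp_table",
]

# IUPAC nucleotide codes incl. ambiguity letters; gaps are not sequence.
_NUC_LETTERS = frozenset("ACGTUNRYSWKMBDHV")
# Amino acids incl. ambiguity (B, Z, J, X) and stop '*'.
_PROT_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHV", "TGCAANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqEntry:
    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceSet:
    """An ordered collection of uniquely named sequences.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``.  Sequences are stored
    uppercase; validation is strict (unknown letters are a hard error) so
    that downstream arithmetic never meets surprises.
    """

    records: list[SeqEntry] = field(default_factory=list)
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet: {self.alphabet!r}")
        seen: set[str] = set()
        letters = _NUC_LETTERS if self.alphabet == "nucleotide" else _PROT_LETTERS
        clean: list[SeqEntry] = []
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id: {rec.id!r}")
            seen.add(rec.id)
            if not rec.sequence:
                raise ValueError(f"empty sequence for id {rec.id!r}")
            seq = rec.sequence.upper()
            for pos, ch in enumerate(seq):
                if ch not in letters:
                    raise ValueError(
                        f"invalid {self.alphabet} character {ch!r} at position "
                        f"{pos + 1} of record {rec.id!r}"
                    )
            clean.append(SeqEntry(rec.id, seq, rec.description))
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SeqEntry]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SeqEntry:
        if isinstance(key, str):
            for rec in self.records:
                if rec.id == key:
                    return rec
            raise KeyError(key)
        return self.records[key]

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def lengths(self) -> dict[str, int]:
        return {r.id: len(r.sequence) for r in self.records}


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit (HSP) between a query contig and a reference subject."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int  # 1-based inclusive
    q_end: int
    s_start: int  # 1-based inclusive; s_start > s_end encodes reverse match
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be >= 1: {self.aln_length}")
        if self.evalue < 0 or self.bitscore < 0:
            raise ValueError("evalue and bitscore must be non-negative")
        if min(self.q_start, self.q_end, self.s_start, self.s_end) < 1:
            raise ValueError("coordinates are 1-based and must be >= 1")

    @property
    def is_reversed(self) -> bool:
        return self.s_start > self.s_end

    def normalized(self) -> "NormalizedHit":
        """Convert to 0-based half-open forward-strand intervals.

        This is the single coordinate-normalization point for the package.
        """
        q_lo, q_hi = sorted((self.q_start, self.q_end))
        s_lo, s_hi = sorted((self.s_start, self.s_end))
        return NormalizedHit(
            query_id=self.query_id,
            subject_id=self.subject_id,
            pct_identity=self.pct_identity,
            aln_length=self.aln_length,
            q_interval=(q_lo - 1, q_hi),
            s_interval=(s_lo - 1, s_hi),
            orientation=-1 if self.is_reversed else 1,
            evalue=self.evalue,
            bitscore=self.bitscore,
        )


@dataclass(frozen=True)
class NormalizedHit:
    """A hit with 0-based half-open intervals and explicit orientation."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    orientation: int  # +1 forward, -1 reverse
    evalue: float
    bitscore: float


_CP_ROLES = ("target", "reference", "calibrator")
_CP_COLUMNS = [
    "sample_id",
    "gene_id",
    "run_id",
    "rt_replicate",
    "tech_replicate",
    "cp",
    "role",
    "dilution",
]


@dataclass
class CpTable:
    """qPCR crossing-point measurements plus dilution-series rows.

    Backed by a pandas DataFrame with columns
    ``sample_id, gene_id, run_id, rt_replicate, tech_replicate, cp, role,
    dilution``.  ``role`` distinguishes target-gene rows, reference-gene
    (normalizer) rows and calibrator-sample rows; ``dilution`` is set only
    on calibration-series rows.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in _CP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"Cp table missing columns: {missing}")
        df = df[_CP_COLUMNS]
        df["cp"] = df["cp"].astype(float)
        if not (df["cp"] > 0).all() or not df["cp"].apply(pd.notna).all():
            raise ValueError("all cp values must be finite and positive")
        bad_roles = set(df["role"]) - set(_CP_ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles: {sorted(bad_roles)}")
        if df["dilution"].notna().any() and not (df.loc[df["dilution"].notna(), "dilution"] > 0).all():
            raise ValueError("dilution factors must be positive")
        key = ["sample_id", "gene_id", "run_id", "rt_replicate", "tech_replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate replicate key: "
                + ", ".join(f"{k}={first[k]!r}" for k in key)
            )
        self.frame = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def measurements(self) -> pd.DataFrame:
        """Rows that are expression measurements (no dilution factor)."""
        return self.frame[self.frame["dilution"].isna()]

    def dilution_series(self, gene_id: str) -> pd.DataFrame:
        """Calibration-series rows for one gene, sorted by dilution desc."""
        df = self.frame
        rows = df[(df["gene_id"] == gene_id) & df["dilution"].notna()]
        return rows.sort_values("dilution", ascending=False)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> SequenceSet:
    """Read a FASTA file into a validated :class:`SequenceSet`.

    Multi-line sequences are concatenated, record order is preserved, and
    the description is everything after the first whitespace of the header.
    Duplicate ids, empty records and off-alphabet characters are hard errors.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqEntry(rec.id, str(rec.seq), desc))
    return SequenceSet(records=records, alphabet=alphabet)


def write_fasta(sset: SequenceSet, path: str | Path, line_width: int = 60) -> None:
    """Write a SequenceSet as wrapped FASTA. Round-trips with :func:`read_fasta`."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for rec in sset:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), line_width):
                fh.write(rec.sequence[i : i + line_width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables


def read_hits_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table ('#' comment lines allowed)."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hits_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.2g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


def group_hits_by_query(hits: Iterable[HitRecord]) -> dict[str, list[NormalizedHit]]:
    """Normalize hits and bucket them per query contig, preserving order."""
    grouped: dict[str, list[NormalizedHit]] = {}
    for hit in hits:
        grouped.setdefault(hit.query_id, []).append(hit.normalized())
    return grouped


# ---------------------------------------------------------------------------
# Cp tables


def read_cp_table(path: str | Path) -> CpTable:
    """Read a comma-separated Cp table (header row naming the CpTable fields)."""
    df = pd.read_csv(path)
    if "dilution" not in df.columns:
        df["dilution"] = float("nan")
    return CpTable(df)


def read_lengths_tsv(path: str | Path) -> dict[str, int]:
    """Two-column (id, length) TSV into a mapping; used for reference lengths."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "length"], comment="#")
    lengths = dict(zip(df["id"].astype(str), df["length"].astype(int)))
    for k, v in lengths.items():
        if v < 1:
            raise ValueError(f"non-positive length for {k!r}")
    return lengths
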