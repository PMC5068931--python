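"""Synthetic data with attached ground truth for every evaluation stage.

The generators emulate the statistical structure the real pipeline
consumes — a reference transcript catalog, contig sets derived from it by
fragmentation with planted exact-duplicate redundancy and planted trans-
and self-chimeras (plus hit tables that are exact images of the source
intervals), serial-dilution qPCR Cp tables with known efficiencies and
expression ratios, and codon-sequence pairs with planted synonymous and
nonsynonymous changes.  Everything is a pure function of its parameters and
an explicit seed, so reruns are byte-identical and each downstream metric
can be checked against recorded truth instead of downloaded data.

What the generators deliberately idealize: emitted hits have 100% identity
and exact coordinates (a ``noise`` option adds identity jitter, interval
trimming and short decoy hits); there is no sequencing-error model and no
read-level simulation.  Tests passing on these fixtures demonstrate the
*arithmetic* of the metrics, not robustness to real aligner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import HitRecord, SequenceSet, SeqEntry, CpTable
from .kaks import CODON_TABLE, STOP_CODONS, count_sites, count_differences

import pandas as pd

__all__ = [
    "AssemblyTruth",
    "ContigTruth",
    "QpcrTruth",
    "simulate_reference",
    "simulate_assembly",
    "simulate_qpcr",
    "simulate_divergent_pair",
    "validate_hits_against_sequences",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_ALPHABET, size=length).tobytes().decode()


def simulate_reference(
    n_refs: int,
    length_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
) -> SequenceSet:
    """Uniform-random reference transcripts, deterministic given the seed."""
    if n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range: {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    width = len(str(n_refs))
    for i in range(n_refs):
        length = int(rng.integers(lo, hi + 1))
        records.append(SeqEntry(f"ref{i:0{width}d}", _random_seq(rng, length)))
    return SequenceSet(records=records, alphabet="nucleotide")


@dataclass(frozen=True)
class ContigTruth:
    contig_id: str
    source_refs: tuple[str, ...]
    source_intervals: tuple[tuple[int, int], ...]  # 0-based half-open on the ref
    is_duplicate: bool = False
    duplicate_of: str | None = None
    is_chimera: bool = False
    chimera_kind: str | None = None  # "trans" | "self"
    breakpoint: int | None = None  # 0-based position on the contig


@dataclass
class AssemblyTruth:
    """Ground truth for one simulated assembly."""

    contigs: dict[str, ContigTruth]
    covered_all: dict[str, float]  # realized per-reference union coverage
    covered_best_single: dict[str, float]
    duplicate_ids: set[str] = field(default_factory=set)
    chimera_ids: set[str] = field(default_factory=set)


def _emit_hit(
    contig_id: str,
    q_lo: int,
    q_hi: int,
    ref_id: str,
    s_lo: int,
    s_hi: int,
    identity: float = 100.0,
) -> HitRecord:
    length = q_hi - q_lo
    mism = int(round(length * (100.0 - identity) / 100.0))
    return HitRecord(
        query_id=contig_id,
        subject_id=ref_id,
        pct_identity=identity,
        aln_length=length,
        mismatches=mism,
        gap_opens=0,
        q_start=q_lo + 1,
        q_end=q_hi,
        s_start=s_lo + 1,
        s_end=s_hi,
        evalue=0.0,
        bitscore=2.0 * length,
    )


def simulate_assembly(
    reference: SequenceSet,
    frag_mean: int = 400,
    frag_sd: int = 100,
    dup_rate: float = 0.0,
    chimera_rate: float = 0.0,
    coverage_design: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    noise: bool = False,
) -> tuple[SequenceSet, list[HitRecord], AssemblyTruth]:
    """Build a contig set from a reference with controlled structure.

    Per reference the coverage design fixes a target union coverage ``a``
    and best-single-contig coverage ``b <= a``: one "best" contig spans the
    reference prefix of fraction b, and the stretch from b to a is tiled by
    strictly shorter chunks (length ~ N(frag_mean, frag_sd), clipped).
    Truth records the *realized* fractions after integer rounding, so
    coverage metrics can be compared exactly.  When no design is given,
    b ~ U(0.4, 1.0) and a ~ U(b, 1.0) per reference.

    ``dup_rate``/``chimera_rate`` are fractions of the base contig count
    emitted additionally as planted exact duplicates (or exactly contained
    copies) and as trans/self chimeras.  Chimera segments and duplicate
    slices are drawn inside already-covered reference intervals and kept
    shorter than the best contig, so they perturb neither covered_all nor
    covered_best_single.  Emitted hits are exact images of the source
    intervals; ``noise=True`` jitters identities, trims intervals and adds
    short low-complexity decoy hits (all below the default scan
    thresholds).
    """
    if not 0 <= dup_rate <= 1 or not 0 <= chimera_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")
    if chimera_rate > 0 and len(reference) < 2:
        raise ValueError("trans-chimeras need at least 2 references")
    rng = np.random.default_rng(seed)
    ref_seqs = {r.id: r.sequence for r in reference}
    ref_ids = list(ref_seqs)

    contigs: list[SeqEntry] = []
    seq_by_id: dict[str, str] = {}
    hits: list[HitRecord] = []
    truth_contigs: dict[str, ContigTruth] = {}
    covered_all: dict[str, float] = {}
    covered_best: dict[str, float] = {}
    best_contig_piece: dict[str, tuple[int, int]] = {}  # ref -> best interval

    counter = 0

    def new_id(tag: str = "c") -> str:
        nonlocal counter
        counter += 1
        return f"{tag}{counter:06d}"

    def add_simple(ref_id: str, lo: int, hi: int, tag: str = "c") -> str:
        cid = new_id(tag)
        seq = ref_seqs[ref_id][lo:hi]
        contigs.append(SeqEntry(cid, seq))
        seq_by_id[cid] = seq
        hits.append(_emit_hit(cid, 0, hi - lo, ref_id, lo, hi))
        truth_contigs[cid] = ContigTruth(cid, (ref_id,), ((lo, hi),))
        return cid

    for ref_id in ref_ids:
        L = len(ref_seqs[ref_id])
        if coverage_design and ref_id in coverage_design:
            a_frac, b_frac = coverage_design[ref_id]
            if not 0 < b_frac <= a_frac <= 1:
                raise ValueError(
                    f"design for {ref_id!r} needs 0 < best <= all <= 1"
                )
        else:
            b_frac = float(rng.uniform(0.4, 1.0))
            a_frac = float(rng.uniform(b_frac, 1.0))
        b_len = max(1, int(round(b_frac * L)))
        a_len = max(b_len, int(round(a_frac * L)))

        add_simple(ref_id, 0, b_len)
        best_contig_piece[ref_id] = (0, b_len)

        # tile (b_len, a_len] with chunks strictly shorter than the best
        # contig but never shorter than 50 nt — sub-50-nt random substrings
        # can occur elsewhere by chance and would plant accidental
        # redundancy; truth records the *realized* union coverage
        pos = b_len
        while a_len - pos >= 50 and b_len > 50:
            chunk = max(50, int(rng.normal(frag_mean, frag_sd)))
            chunk = min(chunk, b_len - 1, a_len - pos)
            if a_len - pos - chunk < 50:  # avoid a tiny leftover tail
                chunk = min(a_len - pos, b_len - 1)
            if chunk < 50:
                break
            add_simple(ref_id, pos, pos + chunk)
            pos += chunk

        covered_all[ref_id] = pos / L
        covered_best[ref_id] = b_len / L

    base_ids = list(truth_contigs)
    n_base = len(base_ids)

    # planted duplicates: exact copies or contained slices of base contigs
    n_dup = int(round(dup_rate * n_base))
    dup_ids: set[str] = set()
    for _ in range(n_dup):
        src_id = base_ids[int(rng.integers(n_base))]
        src = truth_contigs[src_id]
        src_seq = seq_by_id[src_id]
        cid = f"{src_id}_dup{len(dup_ids)}"  # sorts after src_id: dedup keeps src
        if rng.random() < 0.5 or len(src_seq) < 120:
            seq = src_seq
            lo_off, hi_off = 0, len(src_seq)
        else:  # exactly contained slice
            cut = int(rng.integers(1, len(src_seq) // 2))
            lo_off, hi_off = cut, len(src_seq)
            seq = src_seq[lo_off:hi_off]
        ref_id = src.source_refs[0]
        s_lo = src.source_intervals[0][0] + lo_off
        s_hi = src.source_intervals[0][0] + hi_off
        contigs.append(SeqEntry(cid, seq))
        hits.append(_emit_hit(cid, 0, len(seq), ref_id, s_lo, s_hi))
        truth_contigs[cid] = ContigTruth(
            cid, (ref_id,), ((s_lo, s_hi),), is_duplicate=True, duplicate_of=src_id
        )
        dup_ids.add(cid)

    # planted chimeras: segments drawn inside the best (already covered)
    # prefix of each reference and kept well short of it
    n_chim = int(round(chimera_rate * n_base))
    chim_ids: set[str] = set()

    def chimera_segment(ref_id: str) -> tuple[int, int]:
        # a sub-interval of the best-contig prefix: at least 150 units (so
        # noise trimming keeps it above the default minimum segment length)
        # but never longer than the best contig itself
        b_lo, b_hi = best_contig_piece[ref_id]
        b_len = b_hi - b_lo
        seg_len = min(max(150, b_len // 2), b_len)
        start_max = b_hi - seg_len
        start = int(rng.integers(b_lo, start_max + 1)) if start_max > b_lo else b_lo
        return start, start + seg_len

    for k in range(n_chim):
        kind = "trans" if (rng.random() < 0.5 or len(ref_ids) < 2) else "self"
        if kind == "trans":
            i, j = rng.choice(len(ref_ids), size=2, replace=False)
            ref_a, ref_b = ref_ids[int(i)], ref_ids[int(j)]
            (a_lo, a_hi) = chimera_segment(ref_a)
            (b_lo, b_hi) = chimera_segment(ref_b)
            cid = new_id("chimT")
            seq = ref_seqs[ref_a][a_lo:a_hi] + ref_seqs[ref_b][b_lo:b_hi]
            junction = a_hi - a_lo
            contigs.append(SeqEntry(cid, seq))
            hits.append(_emit_hit(cid, 0, junction, ref_a, a_lo, a_hi))
            hits.append(_emit_hit(cid, junction, len(seq), ref_b, b_lo, b_hi))
            truth_contigs[cid] = ContigTruth(
                cid,
                (ref_a, ref_b),
                ((a_lo, a_hi), (b_lo, b_hi)),
                is_chimera=True,
                chimera_kind="trans",
                breakpoint=junction,
            )
        else:
            ref_a = ref_ids[int(rng.integers(len(ref_ids)))]
            (a_lo, a_hi) = chimera_segment(ref_a)
            cid = new_id("chimS")
            piece = ref_seqs[ref_a][a_lo:a_hi]
            seq = piece + piece  # tandem self-join
            junction = a_hi - a_lo
            contigs.append(SeqEntry(cid, seq))
            hits.append(_emit_hit(cid, 0, junction, ref_a, a_lo, a_hi))
            hits.append(_emit_hit(cid, junction, len(seq), ref_a, a_lo, a_hi))
            truth_contigs[cid] = ContigTruth(
                cid,
                (ref_a, ref_a),
                ((a_lo, a_hi), (a_lo, a_hi)),
                is_chimera=True,
                chimera_kind="self",
                breakpoint=junction,
            )
        chim_ids.add(cid)

    if noise:
        hits = _add_hit_noise(hits, rng, ref_seqs)

    sset = SequenceSet(records=contigs, alphabet="nucleotide")
    truth = AssemblyTruth(
        contigs=truth_contigs,
        covered_all=covered_all,
        covered_best_single=covered_best,
        duplicate_ids=dup_ids,
        chimera_ids=chim_ids,
    )
    return sset, hits, truth


def _add_hit_noise(
    hits: list[HitRecord], rng: np.random.Generator, ref_seqs: dict[str, str]
) -> list[HitRecord]:
    """Identity jitter, mild interval trimming, and short decoy hits.

    Trimming is capped at 25 units per end so planted chimera segments
    (>= 150 units) stay above the default minimum segment length; decoys are
    30-80 units long, below the default, so a correct scan filters them.
    """
    ref_ids = list(ref_seqs)
    noisy: list[HitRecord] = []
    for h in hits:
        identity = float(rng.uniform(90.0, 100.0))
        trim_l = int(rng.integers(0, 26))
        trim_r = int(rng.integers(0, 26))
        span = h.q_end - h.q_start + 1
        if span - trim_l - trim_r < 50:
            trim_l = trim_r = 0
        noisy.append(
            HitRecord(
                query_id=h.query_id,
                subject_id=h.subject_id,
                pct_identity=identity,
                aln_length=span - trim_l - trim_r,
                mismatches=int(round((span - trim_l - trim_r) * (100 - identity) / 100)),
                gap_opens=0,
                q_start=h.q_start + trim_l,
                q_end=h.q_end - trim_r,
                s_start=h.s_start + trim_l,
                s_end=h.s_end - trim_r,
                evalue=float(10.0 ** rng.uniform(-60, -20)),
                bitscore=h.bitscore * (span - trim_l - trim_r) / span,
            )
        )
        if rng.random() < 0.15:  # spurious short decoy hit
            decoy_len = int(rng.integers(30, 81))
            ref_id = ref_ids[int(rng.integers(len(ref_ids)))]
            s_lo = int(rng.integers(0, max(1, len(ref_seqs[ref_id]) - decoy_len)))
            q_lo = int(rng.integers(0, max(1, span - decoy_len))) + h.q_start - 1
            noisy.append(
                HitRecord(
                    query_id=h.query_id,
                    subject_id=ref_id,
                    pct_identity=float(rng.uniform(70, 95)),
                    aln_length=decoy_len,
                    mismatches=int(decoy_len * 0.2),
                    gap_opens=0,
                    q_start=q_lo + 1,
                    q_end=q_lo + decoy_len,
                    s_start=s_lo + 1,
                    s_end=s_lo + decoy_len,
                    evalue=float(10.0 ** rng.uniform(-8, -2)),
                    bitscore=decoy_len * 1.0,
                )
            )
    return noisy


def validate_hits_against_sequences(
    hits: list[HitRecord], contigs: SequenceSet, reference: SequenceSet
) -> None:
    """Check that every forward 100%-identity hit is an exact substring image."""
    cseqs = {r.id: r.sequence for r in contigs}
    rseqs = {r.id: r.sequence for r in reference}
    for h in hits:
        n = h.normalized()
        if h.pct_identity < 100.0 or n.orientation != 1:
            continue
        q = cseqs[n.query_id][n.q_interval[0] : n.q_interval[1]]
        s = rseqs[n.subject_id][n.s_interval[0] : n.s_interval[1]]
        if q != s:
            raise AssertionError(
                f"hit {n.query_id!r}->{n.subject_id!r} is not an exact image"
            )


# ---------------------------------------------------------------------------
# qPCR


@dataclass
class QpcrTruth:
    """Design of a simulated qPCR experiment.

    efficiencies: per-gene true amplification efficiency, in (1, 2.2].
    ratios: per (sample, gene) true expression ratio relative to the
        reference gene (reference-gene amount is 1 in every sample).
    reference_gene: the normalizer (e.g. actin).
    noise_sd: Gaussian sd on every Cp, in cycles.
    run_offsets: additive Cp offset per run; the first run must be 0 (it is
        the calibrator's reference run).
    """

    efficiencies: dict[str, float]
    ratios: dict[tuple[str, str], float]
    reference_gene: str = "actin"
    noise_sd: float = 0.0
    run_offsets: tuple[float, ...] = (0.0,)
    calibrator_amounts: dict[str, float] = field(default_factory=dict)
    base_log_amount: float = 24.0 * 0.6931471805599453  # Cp 24 at E=2, amount 1

    def __post_init__(self) -> None:
        for g, e in self.efficiencies.items():
            if not 1.0 < e <= 2.2:
                raise ValueError(f"efficiency for {g!r} outside (1, 2.2]: {e}")
        if any(r <= 0 for r in self.ratios.values()):
            raise ValueError("true ratios must be positive")
        if self.run_offsets and self.run_offsets[0] != 0.0:
            raise ValueError("the first (reference) run must have offset 0")
        if self.reference_gene not in self.efficiencies:
            raise ValueError("reference gene needs an efficiency")


def simulate_qpcr(
    design: QpcrTruth,
    n_rt: int = 2,
    n_tech: int = 2,
    dilution_series: tuple[float, ...] = (1.0, 0.1, 0.01, 0.001, 0.0001),
    dilution_replicates: int = 3,
    seed: int = 0,
) -> CpTable:
    """Emit a Cp table realizing the design.

    The Cp model is cp = (C - ln(amount)) / ln(E_gene) + run_offset + noise
    with a shared threshold constant C, which makes the efficiency-corrected
    ratio recover the designed amount ratio exactly when noise_sd = 0.
    Samples are spread round-robin over the runs; a calibrator sample (with
    fixed amounts) appears in every run, and a standard curve is generated
    per gene from the same efficiencies as a 5-point 10-fold dilution series
    measured in triplicate — the conventional layout; anything sparser lets
    efficiency-fit error exponentiate through E**Cp into a visible ratio
    bias.
    """
    if n_rt < 1 or n_tech < 1:
        raise ValueError("replicate counts must be >= 1")
    rng = np.random.default_rng(seed)
    C = design.base_log_amount
    ref = design.reference_gene
    genes = sorted(g for g in design.efficiencies if g != ref)
    samples = sorted({s for s, _ in design.ratios})
    n_runs = len(design.run_offsets)
    runs = [f"run{k + 1}" for k in range(n_runs)]

    def cp_of(gene: str, amount: float, run_idx: int) -> float:
        e = design.efficiencies[gene]
        cp = (C - np.log(amount)) / np.log(e) + design.run_offsets[run_idx]
        if design.noise_sd > 0:
            cp += float(rng.normal(0.0, design.noise_sd))
        return float(cp)

    rows = []

    def emit(sample: str, gene: str, amount: float, run_idx: int, role: str) -> None:
        for rt in range(1, n_rt + 1):
            for tech in range(1, n_tech + 1):
                rows.append(
                    {
                        "sample_id": sample,
                        "gene_id": gene,
                        "run_id": runs[run_idx],
                        "rt_replicate": rt,
                        "tech_replicate": tech,
                        "cp": cp_of(gene, amount, run_idx),
                        "role": role,
                        "dilution": float("nan"),
                    }
                )

    for s_idx, sample in enumerate(samples):
        run_idx = s_idx % n_runs
        emit(sample, ref, 1.0, run_idx, "reference")
        for gene in genes:
            if (sample, gene) in design.ratios:
                emit(sample, gene, design.ratios[(sample, gene)], run_idx, "target")

    # calibrator in every run
    for run_idx in range(n_runs):
        emit("calibrator", ref, 1.0, run_idx, "reference")
        for gene in genes:
            amount = design.calibrator_amounts.get(gene, 1.0)
            emit("calibrator", gene, amount, run_idx, "calibrator")

    # standard curve (run 1, single RT rep; tech index enumerates wells)
    for gene in [ref, *genes]:
        well = 0
        for d in dilution_series:
            for _ in range(dilution_replicates):
                well += 1
                rows.append(
                    {
                        "sample_id": "dilution_series",
                        "gene_id": gene,
                        "run_id": runs[0],
                        "rt_replicate": 1,
                        "tech_replicate": well,
                        "cp": cp_of(gene, d, 0),
                        "role": "target" if gene != ref else "reference",
                        "dilution": float(d),
                    }
                )

    return CpTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Divergent coding-sequence pairs


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    codons = [c for c in CODON_TABLE if c not in STOP_CODONS]
    return [codons[int(rng.integers(len(codons)))] for _ in range(n_codons)]


def simulate_divergent_pair(
    n_codons: int,
    target_pN: float,
    target_pS: float,
    seed: int = 0,
) -> tuple[str, str, dict[str, float]]:
    """A coding-sequence pair with planted synonymous/nonsynonymous changes.

    Starting from a random stop-free CDS, single-base changes are planted in
    distinct codons (at most one change per codon, so pathway averaging is
    exact) and classified at planting time with the same difference logic
    the estimator uses.  The numbers of planted changes are
    round(target_pS * S) and round(target_pN * N) where S and N are the
    site counts of the starting sequence.  Truth records planted Sd, Nd and
    the realized proportions.
    """
    if not 0 <= target_pN < 0.75 or not 0 <= target_pS < 0.75:
        raise ValueError("target proportions must lie in [0, 0.75)")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons_a = _random_cds(rng, n_codons)
    sites = [count_sites(c) for c in codons_a]
    S = sum(s for s, _ in sites)
    N = sum(n for _, n in sites)
    n_syn = int(round(target_pS * S))
    n_non = int(round(target_pN * N))
    if n_syn + n_non > n_codons:
        raise ValueError(
            f"targets need {n_syn + n_non} mutated codons but only "
            f"{n_codons} codons exist (one change per codon)"
        )

    codons_b = list(codons_a)
    order = rng.permutation(n_codons)
    planted_sd = 0
    planted_nd = 0
    used: set[int] = set()

    def plant(idx: int, want_synonymous: bool) -> bool:
        codon = codons_b[idx]
        options = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant in STOP_CODONS:
                    continue
                sd, nd = count_differences(codon, mutant)
                if want_synonymous and sd == 1.0:
                    options.append(mutant)
                elif not want_synonymous and nd == 1.0:
                    options.append(mutant)
        if not options:
            return False
        codons_b[idx] = options[int(rng.integers(len(options)))]
        return True

    queue = list(order)
    for want_syn, needed in ((True, n_syn), (False, n_non)):
        placed = 0
        remaining = []
        for idx in queue:
            if placed >= needed:
                remaining.append(idx)
                continue
            if idx in used:
                continue
            if plant(int(idx), want_syn):
                used.add(int(idx))
                placed += 1
            else:
                remaining.append(idx)
        if placed < needed:
            raise ValueError(
                "could not place all requested changes; lower the targets"
            )
        queue = remaining
        if want_syn:
            planted_sd = placed
        else:
            planted_nd = placed

    seq_a = "".join(codons_a)
    seq_b = "".join(codons_b)
    truth = {
        "planted_Sd": float(planted_sd),
        "planted_Nd": float(planted_nd),
        "S_seq_a": S,
        "N_seq_a": N,
        "realized_pS": planted_sd / S if S else 0.0,
        "realized_pN": planted_nd / N if N else 0.0,
    }
    return seq_a, seq_b, truth
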