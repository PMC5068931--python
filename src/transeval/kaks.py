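"""Pairwise synonymous/nonsynonymous divergence (Nei-Gojobori, 1986 style).

For two aligned coding sequences the method counts, per codon, the numbers
of synonymous (S) and nonsynonymous (N) *sites* — each of the three codon
positions contributes f/3 synonymous sites, where f is the fraction of the
three possible single-nucleotide changes at that position that preserve the
amino acid — and classifies observed *differences* between codon pairs by
averaging over all minimal mutational pathways with equal weights,
excluding pathways that pass through a stop codon.  The proportions
pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), and the ratio Ka/Ks
(equivalently dN/dS) summarizes selective constraint: << 1 purifying
selection, ~1 neutrality/relaxed constraint.

Convention: changes *to* stop codons count as nonsynonymous in site
counting (``stop_policy="nonsynonymous"``); pass
``stop_policy="excluded"`` to remove them from the per-position denominator
instead.  Codons containing gaps or ambiguity characters in either sequence
are dropped pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

__all__ = ["KaKsResult", "count_sites", "count_differences", "kaks", "CODON_TABLE"]

_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
# Standard genetic code, codon -> amino acid ('*' = stop).
CODON_TABLE: dict[str, str] = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


@dataclass(frozen=True)
class KaKsResult:
    n_codons_used: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None  # None when the JC correction is undefined (p >= 3/4)
    Ka: float | None
    ratio: float | None  # Ka/Ks; None when Ks == 0 or either distance undefined


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon not allowed: {codon!r}")


def count_sites(codon: str, stop_policy: str = "nonsynonymous") -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one codon.

    Each position contributes (synonymous changes)/(counted changes) sites;
    with the default policy every position counts all 3 possible changes and
    a change creating a stop codon is nonsynonymous, so s + n == 3.  With
    ``stop_policy="excluded"`` stop-creating changes leave the denominator.
    """
    codon = codon.upper()
    _check_codon(codon)
    if stop_policy not in ("nonsynonymous", "excluded"):
        raise ValueError(f"unknown stop_policy: {stop_policy!r}")
    aa = CODON_TABLE[codon]
    s_total = 0.0
    n_total = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                if stop_policy == "excluded":
                    continue
                counted += 1  # counts as a nonsynonymous opportunity
                continue
            counted += 1
            if CODON_TABLE[mutant] == aa:
                syn += 1
        if counted:
            s_total += syn / counted if stop_policy == "excluded" else syn / 3
            n_total += (counted - syn) / counted if stop_policy == "excluded" else (3 - syn) / 3
    return s_total, n_total


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    All minimal mutational pathways (orderings of the differing positions)
    are enumerated and averaged with equal weights; pathways passing through
    a stop codon are excluded.  If every pathway hits a stop, all pathways
    are used as a fallback so the count stays defined.  Always
    sd + nd == number of differing positions.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    _check_codon(codon_a)
    _check_codon(codon_b)
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return float(sd), float(nd)

    paths = [walk(order) for order in permutations(diff_positions)]
    valid = [p for p in paths if p is not None]
    if not valid:  # all pathways pass through stops: fall back to all
        valid = []
        for order in permutations(diff_positions):
            cur = codon_a
            sd = nd = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                same = (
                    nxt not in STOP_CODONS
                    and cur not in STOP_CODONS
                    and CODON_TABLE[nxt] == CODON_TABLE[cur]
                )
                if same:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            valid.append((float(sd), float(nd)))
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion cannot be negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


_SKIP_CHARS = set("-.NRYSWKMBDHV")


def _usable_codon(c: str) -> bool:
    return all(b in "ACGT" for b in c) and c not in STOP_CODONS


def kaks(seq_a: str, seq_b: str, stop_policy: str = "nonsynonymous") -> KaKsResult:
    """Pairwise Ka/Ks between two aligned coding sequences.

    Codon pairs where either codon contains a gap or ambiguity character, or
    is a stop codon, are dropped (complete-codon deletion).  Site counts are
    averaged over the two sequences; differences are summed over codon
    pairs.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    usable = 0
    s_a = n_a = s_b = n_b = 0.0
    sd_total = nd_total = 0.0
    n_full = len(seq_a) - len(seq_a) % 3
    for i in range(0, n_full, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        usable += 1
        sa, na = count_sites(ca, stop_policy)
        sb, nb = count_sites(cb, stop_policy)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        sd, nd = count_differences(ca, cb)
        sd_total += sd
        nd_total += nd
    if usable == 0:
        raise ValueError("no usable codon pairs in the alignment")
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd_total / S if S > 0 else 0.0
    pN = nd_total / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    return KaKsResult(
        n_codons_used=usable,
        S=S,
        N=N,
        Sd=sd_total,
        Nd=nd_total,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
    )
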