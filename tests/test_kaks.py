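"""Nei-Gojobori Ka/Ks: site counting, pathway averaging, JC correction."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transeval.kaks import (
    CODON_TABLE,
    STOP_CODONS,
    count_differences,
    count_sites,
    jukes_cantor,
    kaks,
)
from transeval.simulate import simulate_divergent_pair

SENSE_CODONS = sorted(c for c in CODON_TABLE if c not in STOP_CODONS)


# --- independent brute-force oracle -----------------------------------------


def oracle_sites(codon):
    """Enumerate all 9 single-base changes; stops count as nonsynonymous."""
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TABLE[mutant] == CODON_TABLE[codon]:
                s += 1 / 3
    return s, 3 - s


def oracle_differences(ca, cb):
    """Average sd/nd over stop-free minimal pathways, enumerated explicitly."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in permutations(diffs):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None  # conventions diverge; skip in comparisons
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def oracle_kaks(seq_a, seq_b):
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a) - len(seq_a) % 3, 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        if any(x not in "ACGT" for x in ca + cb):
            continue
        sa, na = oracle_sites(ca)
        sb, nb = oracle_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        d = oracle_differences(ca, cb)
        if d is None:
            d = count_differences(ca, cb)  # fallback convention, same as impl
        Sd += d[0]
        Nd += d[1]
    pS, pN = Sd / S, Nd / N
    ks = -0.75 * math.log(1 - 4 * pS / 3) if pS < 0.75 else None
    ka = -0.75 * math.log(1 - 4 * pN / 3) if pN < 0.75 else None
    return S, N, Sd, Nd, ks, ka


# --- tests -------------------------------------------------------------------


class TestCountSites:
    @pytest.mark.parametrize(
        "codon, s, n",
        [("TTT", 1 / 3, 8 / 3), ("GGG", 1.0, 2.0), ("ATG", 0.0, 3.0)],
    )
    def test_examples(self, codon, s, n):
        got_s, got_n = count_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(n)

    def test_all_sense_codons_match_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            os_, on_ = oracle_sites(codon)
            assert s == pytest.approx(os_, abs=1e-12), codon
            assert s + n == pytest.approx(3.0, abs=1e-12), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestCountDifferences:
    @pytest.mark.parametrize(
        "ca, cb, sd, nd",
        [
            ("GAA", "GAG", 1.0, 0.0),  # Glu -> Glu synonymous
            ("AAA", "AGA", 0.0, 1.0),  # Lys -> Arg nonsynonymous
            ("TTT", "GTA", 0.5, 1.5),  # two pathways averaged
        ],
    )
    def test_examples(self, ca, cb, sd, nd):
        assert count_differences(ca, cb) == pytest.approx((sd, nd))

    def test_two_pathway_enumeration(self):
        # explicit oracle: TTT->GTT->GTA and TTT->TTA->GTA
        sd, nd = count_differences("TTT", "GTA")
        assert (sd, nd) == pytest.approx(oracle_differences("TTT", "GTA"))

    def test_sd_plus_nd_equals_observed_diffs(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            ca, cb = rng.choice(SENSE_CODONS, size=2)
            sd, nd = count_differences(ca, cb)
            n_diff = sum(a != b for a, b in zip(ca, cb))
            assert sd + nd == pytest.approx(n_diff)


class TestKaks:
    def test_identical_sequences(self):
        seq = "ATGGCTAAA" * 10
        res = kaks(seq, seq)
        assert res.Sd == res.Nd == 0.0
        assert res.Ka == res.Ks == 0.0
        assert res.ratio is None  # Ks == 0

    def test_symmetry(self):
        a, b, _ = simulate_divergent_pair(100, 0.03, 0.10, seed=3)
        ra, rb = kaks(a, b), kaks(b, a)
        assert ra.Sd == pytest.approx(rb.Sd)
        assert ra.Ka == pytest.approx(rb.Ka)
        assert ra.Ks == pytest.approx(rb.Ks)

    def test_sites_sum_rule(self):
        a, b, _ = simulate_divergent_pair(200, 0.02, 0.08, seed=4)
        res = kaks(a, b)
        assert res.S + res.N == pytest.approx(3 * res.n_codons_used, abs=1e-9)

    def test_gapped_codons_dropped_pairwise(self):
        a = "ATGGCTAAAGCT"
        b = "ATG---AAAGCT"
        res = kaks(a, b)
        assert res.n_codons_used == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kaks("ATG", "ATGGCT")

    def test_only_synonymous_changes_gives_zero_ka(self):
        a, b, _ = simulate_divergent_pair(150, 0.0, 0.10, seed=5)
        res = kaks(a, b)
        assert res.Ka == 0.0
        assert res.Ks > 0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        a = "".join(rng.choice(SENSE_CODONS, size=n))
        # mutate freely (may create multi-diff codons, gaps excluded)
        b_codons = []
        for i in range(n):
            codon = a[3 * i : 3 * i + 3]
            if rng.random() < 0.3:
                pos = int(rng.integers(3))
                base = "ACGT"[int(rng.integers(4))]
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant not in STOP_CODONS:
                    codon = mutant
            b_codons.append(codon)
        b = "".join(b_codons)
        res = kaks(a, b)
        S, N, Sd, Nd, ks, ka = oracle_kaks(a, b)
        assert res.S == pytest.approx(S, abs=1e-9)
        assert res.N == pytest.approx(N, abs=1e-9)
        assert res.Sd == pytest.approx(Sd, abs=1e-9)
        assert res.Nd == pytest.approx(Nd, abs=1e-9)
        if ks is not None:
            assert res.Ks == pytest.approx(ks, abs=1e-9)

    def test_cross_check_against_biopython_ng86(self):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        a, b, _ = simulate_divergent_pair(200, 0.04, 0.12, seed=11)
        res = kaks(a, b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dN, dS = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert res.Ka == pytest.approx(dN, abs=1e-6)
        assert res.Ks == pytest.approx(dS, abs=1e-6)

    def test_planted_divergence_recovery(self):
        for seed in range(5):
            a, b, truth = simulate_divergent_pair(500, 0.05, 0.15, seed=seed)
            res = kaks(a, b)
            # one change per codon and non-adjacent: counts recover exactly
            assert res.Sd == truth["planted_Sd"]
            assert res.Nd == truth["planted_Nd"]


class TestJukesCantor:
    def test_small_p_limit(self):
        for p in (0.001, 0.01, 0.04):
            assert abs(jukes_cantor(p) - p) <= p**2

    def test_saturation_undefined(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None

    def test_monotone(self):
        ps = np.linspace(0.01, 0.7, 30)
        ds = [jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(ds, ds[1:]))
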