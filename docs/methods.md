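# Methods

This note documents the models and conventions behind each computation, the
choices made where the field leaves the design open, and what the synthetic
fixtures do and do not demonstrate.

## Coordinate conventions

Tabular alignment hit tables (the 12-column dialect: query, subject,
%identity, alignment length, mismatches, gap opens, qstart, qend, sstart,
send, e-value, bit score) carry 1-based inclusive coordinates; a subject
match on the reverse strand is encoded as sstart > send. All internal
interval arithmetic uses 0-based half-open intervals on the forward strand.
The conversion happens in exactly one place (`HitRecord.normalized()`);
nothing downstream ever touches raw hit coordinates. This single
normalization point is deliberate — coverage, OHR and chimera logic all do
interval arithmetic, and one shared conversion removes the usual class of
off-by-one drift.

## Assembly statistics and redundancy

N50 is computed by the standard descending-sort-and-accumulate definition:
the smallest contig length L such that contigs of length ≥ L contain at
least half of all bases. Mean length is reported rounded to the nearest
integer base, matching how assembly comparison tables print it.

Redundancy is defined as 100% nucleotide identity: a contig equal to, or an
exact substring of, another contig on either strand is redundant. Within a
redundancy cluster the longest sequence is retained; equal-length ties keep
the lexicographically smallest id, so the operation is deterministic.
Clustering at identity below 100% (the territory of greedy word-based
clusterers) is intentionally out of scope: the contract implemented here is
exactly what a "nonredundant contigs" column measures. The implementation
concatenates candidates longest-first and answers each containment query
with two C-level substring scans bounded to strictly longer sequences;
because containment is transitive (up to strand flips), testing against all
strictly longer sequences is equivalent to testing against retained ones.
Tests check it against a naive quadratic both-strand scan.

## Completeness, contiguity, OHR

All three metrics measure coverage on the subject (reference) axis, in
subject units. Overlapping alignment segments from the same contig are
union-merged, never summed — summed coverage can exceed the reference
length and double-counts repeated matches; the union is the defensible
reading of "proportion covered". Fractions are capped at 1.0.

* completeness(t) = percentage of expressed references whose union coverage
  over all contigs is ≥ t (boundary inclusive);
* contiguity(t) = the same with the single best-covering contig;
* OHR = union coverage of a contig's best subject, per contig.

The "expressed" denominator is caller-supplied. The default — the union of
references hit by any assembly under comparison — is the only definition
computable from the hit tables themselves, and sharing one denominator
across assemblies keeps their columns comparable. Best-subject selection
for OHR maximizes the summed bit score per contig–subject pair (ties:
lowest summed e-value, then lexicographically smallest subject id) — the
standard ranking where no explicit selection rule exists.

Two laws follow from the definitions and are enforced as tests: contiguity
≤ completeness at every threshold (a single contig's union is a subset of
the all-contig union), and both metrics are non-increasing in the
threshold.

## Chimera scan

Parameters (all overridable on the CLI):

| parameter        | default | units         | role |
|------------------|---------|---------------|------|
| min_identity     | 30      | percent       | drop weak hits (translated-search scale) |
| min_seg_len      | 100     | query units   | drop short/spurious hits |
| max_q_overlap    | 60      | query units   | larger query overlaps are conflicting, not chimeric, evidence |
| min_self_overlap | 0.2     | fraction      | subject-interval mutual overlap to call a self-chimera |
| diag_tolerance   | 60      | units         | diagonal drift allowed when merging collinear HSPs |

The cited chimera-screening approach does not fix numeric thresholds, so
these defaults are configuration, chosen at translated-search scale
(identity 30% spans distant protein homology; 100 query units ≈ 33 codons;
overlap/diagonal tolerances of 60 absorb end trimming). The synthetic
acceptance checks are threshold-robust by construction: planted chimera
segments are ≥ 150 units long at 90–100% identity, decoy hits are ≤ 80
units.

Per contig: hits are filtered, then same-subject same-orientation hits
whose alignment diagonal is consistent within `diag_tolerance` are merged —
a fragmented but collinear alignment is one segment and never chimera
evidence. A contig with ≥ 2 query-disjoint segments (overlap ≤
`max_q_overlap`) matching different subjects is trans-chimeric; matching
the same subject with mutually overlapping subject intervals or opposite
orientations, self-chimeric. The breakpoint is the midpoint of the query
gap between adjacent offending segments (abutting segments cut exactly at
the junction) — without per-base evidence inside the gap, the midpoint
minimizes the worst-case error, which is therefore bounded by half the
inter-segment gap. Contigs can in principle show both kinds of evidence;
trans takes precedence in the call's `kind`, and counts are summed for the
chimera percentage. The percentage denominator is the nonredundant contig
count — the only denominator consistent across published comparison rows
that report both figures.

Cutting replaces a called contig by its pieces (`_part1..k`, 5'→3'),
conserving total bases. Biological fusion transcripts cannot be
distinguished from misassemblies by this screen; everything flagged is
reported.

## qPCR quantification

The efficiency-corrected relative quantification model: amplification obeys
amount × E^Cp = threshold, so with a reference (normalizer) gene measured in
the same cDNA,

    ratio = E_ref^Cp_ref / E_target^Cp_target,

computed in log space. Efficiency comes from an ordinary least-squares fit
of Cp against log10(dilution): E = 10^(−1/slope); E = 2 is perfect
doubling. Slopes ≥ 0 mark a curve invalid rather than raising — flat
standards are a data problem the caller must see. Efficiencies are bounded
in (1, 4] for the math and flagged above 2.2 as chemically implausible.

Replicate aggregation: technical replicates are averaged on the Cp scale
within each RT replicate; one ratio is formed per RT replicate against the
reference-gene Cp from the *same* sample, run and RT replicate (pairing
within the physical cDNA cancels loading variation); the calibrator sample,
measured in every run, corrects multiplicative run-to-run variation
(reference run = lexicographically first run id); the report is mean ± sd
(ddof = 1) over RT replicates. The ordering — Cp average first, then
ratios, then mean of ratios — is a choice; it keeps the target/reference
pairing intact where averaging ratios of averaged ratios would not.

Where the reference gene is unusable in some material (e.g. a low-expressed
normalizer in seeds), cDNA-normalized ratios are bridged into
reference-normalized space by the geometric mean, over samples measured
both ways, of (reference-normalized / cDNA-normalized). The geometric mean
is the right average for a multiplicative rescaling factor.

FPKM = fragments / ((length/10³) × (mapped/10⁶)), with raw transcript
length by default; callers with effective lengths supply them via the
length column option.

## Ka/Ks

Nei–Gojobori (1986)-style counting with equal pathway weighting and
Jukes–Cantor correction — the standard method behind the classic pairwise
Ks/Ka statistics. Site counting: each codon position contributes
(synonymous single-base changes)/3 synonymous sites; changes creating a
stop codon count as nonsynonymous by default (S + N = 3 × codons), with an
option to exclude them from the denominator instead, since published
implementations differ on this convention. Difference counting: all
orderings of the differing positions are enumerated, pathways through stop
codons are excluded, and sd/nd are averaged with equal weights; if every
pathway passes through a stop (rare), all pathways are used as a fallback
so the count stays defined. Codons containing gaps or ambiguity characters
in either sequence are dropped pairwise. Site counts are averaged over the
two sequences; pS = Sd/S and pN = Nd/N are corrected by
d = −(3/4)·ln(1 − (4/3)p), undefined at p ≥ 3/4; the ratio is undefined at
Ks = 0. The implementation is checked against a brute-force enumeration
oracle (exact to 1e-9) and against an independent library implementation of
the same estimator.

## Synthetic data

The generators are pure functions of (parameters, seed) — byte-identical
reruns — and every emitted hit is an exact image of its source interval,
enforced by a validator.

**Assemblies.** Per reference, a coverage design fixes target union
coverage a and best-single-contig coverage b ≤ a: one contig spans the
reference prefix of fraction b, and the stretch up to a is tiled by chunks
drawn from N(frag_mean, frag_sd), each strictly shorter than the best
contig and at least 50 nt (shorter random substrings recur elsewhere by
chance and would plant accidental redundancy). Truth records the realized
integer-rounded fractions, so coverage recovery is asserted exactly, not
approximately. When no design is given, b ~ U(0.4, 1.0) and a ~ U(b, 1.0).
Planted duplicates are exact copies or contained slices of existing contigs
(ids sort after their source, so deduplication keeps the original);
planted chimeras join two reference segments (trans) or tandem-repeat one
(self), drawn inside already-covered intervals and kept shorter than the
best contig so they perturb neither coverage fraction. The `noise` option
jitters identities to 90–100%, trims hit ends by up to 25 units and adds
15% short (30–80 unit) decoy hits — a robustness probe, not an aligner
error model.

**qPCR.** Cp = (C − ln(amount))/ln(E_gene) + run_offset + N(0, sd), sharing
one threshold constant C across genes, which makes noiseless aggregation
invert exactly to the designed ratios for arbitrary per-gene efficiencies.
The first run carries offset 0 and is the calibrator's reference run. The
standard curve is a 5-point 10-fold dilution series measured in triplicate
per gene — the conventional calibration layout. This matters: efficiency
error propagates exponentially through E^Cp (at Cp ≈ 25–30, a ±0.04 error
on E is a ~30% lognormal spread on the ratio), so a 3-point single-well
curve under realistic Cp noise biases recovered ratios well beyond what any
practitioner would accept from their standards.

**Codon pairs.** Starting from a random stop-free coding sequence, single
base changes are planted in distinct codons (at most one per codon, so
pathway averaging is exact) and classified at planting time with the same
difference logic the estimator uses; round(pS·S) synonymous and round(pN·N)
nonsynonymous changes are placed. Truth records planted Sd/Nd exactly.

**What passing these fixtures shows — and does not.** The metrics'
arithmetic is exact, the detection logic is correct on clean and mildly
noisy footprints, and the quantification inverts its own generative model.
The fixtures contain no sequencing error, no alignment ambiguity, no
paralogy, no isoforms and no amplification inhibitors; performance on real
assemblies and real plates depends on those, and the thresholds above are
the knobs to retune there.

## Problem sizes and determinism

The shipped test suite and the acceptance script run at the scale the
checks need rather than study scale: 1,000 references / ~18,000 contigs × 5
seeds for the metric-law checks, 200 random sets for the oracle-equivalence
checks, ~2,200 contigs × 10 seeds for chimera recovery, 200 seeds for the
qPCR noise study, 100 random pairs plus 20 planted-divergence seeds for
Ka/Ks. Every random draw descends from an explicit seed; reruns are
reproducible to the byte.

## Known limitations

* Redundancy removal is exact-match only; near-duplicates (≠ 100%
  identity) pass through by design.
* The chimera screen needs informative hits: a chimera whose halves both
  miss the reference catalog is invisible, so the measured rate is a lower
  bound under sparse catalogs.
* Coverage metrics treat the reference catalog as truth; assembly of
  transcripts absent from the catalog is not rewarded.
* The qPCR model assumes constant per-gene efficiency across the dilution
  range and multiplicative run effects; saturating or inhibited reactions
  violate both.
* Ka/Ks here is the counting estimator; it ignores transition/transversion
  bias and codon-frequency effects, and saturates near p = 3/4 — for deep
  divergences a ML codon model is the better tool.
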