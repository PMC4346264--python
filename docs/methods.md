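# Methods

## Read model and preprocessing

Each sequencing read is modeled as

    [5′-adapter remnant (5 nt, CGAUC)] [barcode (4 nt)] [insert 5–45 nt] [3′ adapter …]

The sequencing primer covers the first 21 nt of the 30-nt 5′ adapter, so
the remnant and barcode occupy fixed positions; the six barcodes are the
4-nt variable suffixes of the six 5′ adapters (GAAA, AAAA, AGAA, ACAA,
CAAA, UAAA after T→U canonicalization). All analysis is done in RNA space
(A, C, G, U); reads with any other character are rejected and accounted.

Demultiplexing matches the barcode field at a configurable Hamming
tolerance (default 0 — several of the six barcodes are mutual distance 1,
so any tolerance ≥ 1 makes true barcodes ambiguous; the demultiplexer
returns UNASSIGNED with an "ambiguous" flag in that case). Trimming locates
the leftmost occurrence of the first 8 nt of the 3′ adapter
(AUCUCGUAUGCCGUCUUCUGCUUGU) allowing one mismatch, removes it and
everything 3′ of it, then strips the 9-nt 5′ prefix. An empty insert is an
adapter dimer. The artifact filter drops inserts carrying a local match to
any full 5′ adapter or its reverse complement — any 10-nt window aligning
with ≤ 1 mismatch — reproducing the removal of adapter-derived library
artifacts with a transparent, testable rule (a deliberate replacement for
an opaque external trimmer). Finally the 5–40-nt analysis window is
applied. Every read lands in exactly one accounting bin (kept, unassigned,
no-adapter, adapter-dimer, artifact, length, alphabet), and the bins sum to
the raw read count by construction.

Mismatch tolerances (1 in the adapter seed, 0 in barcodes, 10/1 in the
artifact rule) are package choices, exposed in `AdapterConfig`.

## Annotation

Inserts are matched as contiguous substrings of reference transcripts with
up to 2 mismatches (Hamming), via pigeonhole seed-and-verify (split the
query into max_mm+1 fragments; one must match exactly), which is proven
equivalent to the naive all-positions scan by property test. Transcript
space deliberately replaces genome-scale alignment: the stage contract —
insert → category multiset — is all that downstream consumes, and the
matcher is interchangeable. Inserts hitting the rDNA repeating-unit
surrogate within 2 mismatches are classified rRNA outright and skip
transcript matching. A read matching k ≥ 1 categories contributes 1/k to
each ("and/or" assignment); stacked category percentages therefore total
100 % over annotated reads, with the unannotated fraction reported
separately. A winner-takes-priority mode is available. Matching is
sense-strand by default (small-RNA libraries are stranded); reverse
complement matching sits behind a flag.

## Profiling and differential abundance

The species frequency of sequence s in a sample is
100·count(s)/Σ count(same length) — the per-length percentage; a
whole-window denominator (all 5–40-nt reads) is available for
single-species abundance plots. Length-histogram peaks are strict local
maxima with plateau merging (a run of equal counts flanked by strictly
lower counts reports all member lengths; window edges compare one-sided; a
fully flat profile has no peaks).

The comparing set is the deduplicated union over samples and lengths of
each sample's N most-abundant sequences per length (N = 5 plasma-style,
10 PBMC-style; ties at rank N broken lexicographically and logged).
Frequencies of a comparing sequence absent from a sample are imputed 0 —
a sequence in one person's top-N may simply be unobserved in another.
Each comparing sequence is tested with a pooled-variance two-sample
Student's t (df = n₁+n₂−2), two-tailed, significance at raw P < α = 0.05
with no multiple-testing correction by default (Benjamini–Hochberg
optional). Zero pooled variance is handled explicitly: equal means → (t=0,
p=1); unequal means → p=0, flagged degenerate.

## Segregation statistic

Six samples admit C(6,3)/2 = 10 unordered balanced bipartitions
(generalized to 2m). For each, the number of comparing sequences
significant for that 3-vs-3 split is counted; a sequence significant under
several bipartitions counts toward each (the published 79+54 arithmetic
treats counts as additive events). With S_case significant at the true
case/control split and n = S_case + S_other in total, the expected case
count under uniform allocation is E = n/10 and the reported probability is
the exact binomial point mass at S_case with p = 1/10. The point mass (not
a tail) is the reading that reproduces the published PBMC value
4.2×10⁻⁴³ at (k=109, n=250); upper-tail and two-tailed variants are
reported alongside as labelled alternatives. All probability arithmetic is
in log space via log-gamma — at the 10⁻⁴³ scale naive products underflow —
and agrees with exact rational arithmetic to 1e-10 relative for all
k ≤ n ≤ 300.

Recomputing the plasma value at (k=79, n=133) gives 2.4×10⁻⁴⁴, matching
the published mantissa but one order of magnitude below the published
exponent (10⁻⁴³); the PBMC value reproduces exactly under the same rule.
Both the recomputed value and the discrepancy are reported; neither is
silently "corrected".

## Guide-RNA structure rules

Structure is combinatorial pattern matching over Watson-Crick + G·U
pairing, not thermodynamic folding: every claim is an enumerable fact.
Guide classes by length and fold: heptamer 5–8 nt; 14-nt-linear 12–16 nt
with no internal stem-loop of ≥ 4 bp; hook 15–25 nt with a 3′ stem-loop
(≥ 4 bp) after a ≥ 7-nt unpaired 5′ segment; 5′-half-tRNA 26–40 nt folding
into an unpaired 5′ acceptor arm (≥ 7 nt) plus an internal stem-loop (stem
3–7 bp, loop 3–11 nt; best fold = longest stem, ties to the 5′-most). The
windows interpolate the published "usually 7–31 nt, but 5–6 nt and >31 nt
occur" taxonomy, which defines no sharp bounds.

A pre-tRNA-like complex requires (i) a contiguous duplex of ≥ 7 bp between
the guide's 5′ terminus and the target, **capped at the guide's unpaired
acceptor-arm length** — bases inside the guide's intramolecular D-stem
mimic are not available for intermolecular pairing; (ii) a T-arm-like
stem-loop on the target (stem ≥ 4 bp, loop 5–9 nt, bonus if the loop
carries the GGUUC consensus) within 30 nt upstream of the duplex; (iii) at
least one target nucleotide 3′ of the duplex — the discriminator. Cleavage
is predicted at the bond immediately 3′ of the discriminator; product
lengths always sum to the target length. The arm cap matters: the Y4
31-mer's best fold leaves exactly the 9-nt arm GGCUGGUCC unpaired, so its
duplex with RNA-Y is 9 bp (positions 29–37) even though a raw pairing run
would extend to 10 bp through a G·U wobble at target position 28; the
predicted cleavage between positions 38/39 yields 38-nt + 8-nt products.

## Synthetic data

The generator emulates one multiplexed run of up to six barcoded libraries:
insert lengths follow a weighted distribution over 5–45 nt (default peaks
at 14/15/16, 22/23, 26, 31, 37 nt over a uniform floor); inserts are
substrings of a fabricated 10-category reference that includes an
rDNA-repeating-unit surrogate (carrying the 14-nt 28S fragment
CGCGACCUCAGAUC) and a 94-nt Y4-like transcript whose 5′ 31-mer is the Y4
fragment. Within each transcript, start positions follow a Zipf-like
preference (exponent 1.2 under a seeded permutation), so each length
stratum is dominated by a few "processing products" with counts large
enough for the t approximation to hold — real strata are likewise
dominated by a few species. Planted truth: 4 differential species (fold
change 20; "more" species at 0.5 % of their stratum in controls, 10 % in
cases; "less" species mirrored), 2 uniformly-abundant null species (10 %
of their stratum), and 5 % adapter artifacts (alternating adapter dimers
and 5′-adapter fragments). Species that the preprocessor could not
round-trip exactly — those resembling the 3′-adapter seed anywhere in the
assembled read (including junction windows) or locally resembling a 5′
adapter — are excluded from the sampling pool, so on noise-free data
trim+filter recovers the planted insert multiset *exactly* and drops
exactly the artifact fraction. An optional uniform substitution rate
(default 0) mutates insert bases; the truth table always records what was
actually emitted. Per-library depth defaults to 10⁴ reads (no published
depths exist; this gives planted effects clear detectability at fold 20
while keeping replicate studies fast).

What the generator does **not** emulate: Illumina error/quality profiles,
PCR duplicates, genome coordinates, ligation biases. Passing tests
therefore demonstrate the correctness of the *procedure* under known
truth, not performance on real libraries.

## Replicate studies and their expected outcomes

`studies.planted_recovery_study` (100 seeds, read-level pipeline) and
`studies.null_calibration_study` (500 replicates, multiset-level, which the
round-trip identity shows is equivalent on noise-free data) quantify the
procedure. Under the standard conditions: every planted differential
species is recovered with the correct direction in 100/100 seeds; the
per-sequence type-I rate without planted effects is ≈ 0.04, within the
sampling band of α = 0.05; and the case bipartition's rank is uniform
under exchangeability (χ², randomized tie-breaking).

Two properties are *not* achievable simultaneously with a calibrated test,
and the corresponding checks are expected to fail: (a) "zero false
positives among the k planted-null species in ≥95 % of seeds" has
probability ≈ 0.95^k per seed by the very definition of α (measured:
92/100 with k = 2); (b) "case bipartition ranked strictly first in ≥95 %
of seeds" would require ≲ 1 false positive per bipartition, i.e. an
effective type-I rate ~0.5 % over a several-hundred-sequence comparing
set — an order of magnitude below α (measured: 32/100). A conservative
(sparse, heavily discrete) background would deliver (a) and (b) but push
the type-I rate far below its calibration band. The package keeps the
calibrated background and documents the trade-off rather than tuning one
check against the other.

## Numerical and degenerate-input choices

Deterministic everywhere: seeded numpy Generators with fixed stream tags;
ties broken lexicographically (top-N), 5′-most (folds), or uniformly at
random from a seeded stream (rank statistics). Empty length strata yield
missing (not zero) single-species frequencies but impute zero in the
comparison table; zero annotated reads yield an explicitly flagged empty
category profile; an odd sample count fails the segregation stage with a
clean error. Probability sums are validated to 1e-12; the binomial point
mass to 1e-10 relative against exact rationals.

## Known limitations

Transcript-space annotation cannot resolve multi-locus genomic origins;
the t-test inherits its fragility at n = 3 per group; the segregation
point probability is a descriptive statistic (its null model treats
significant events as independently allocated, which sequences shared
between bipartitions violate); structure rules ignore thermodynamics,
pseudoknots, and chemical modifications, and predict sites, not cleavage
efficiency.
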