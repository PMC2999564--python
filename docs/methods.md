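# Methods

This note documents the models, numerical choices and open design
decisions behind `estoligo`, in the order the pipeline runs.

## Alignment model and statistics

The internal aligner stands in for BLASTN in the assembly-quality tests
and the similarity filter. Scoring is match/mismatch with affine gaps
(default +1/−2, gap open −5, gap extend −2; a gap of length L costs
open + L·extend). Ambiguous bases (N) always score as mismatches and
never count as identities; other IUPAC ambiguity codes are collapsed to
N at parse time, since the pipeline's alphabet is {A,C,G,T,N}.

**Search.** Exact shared words nominate a (pair, strand) combination;
the nominated strand is then resolved by a full Gotoh Smith–Waterman
with traceback rather than a banded X-drop extension. The sequences in
scope (ESTs, probes) are short enough that O(mn) per seeded pair is
cheap, and the payoff is a strong contract: any reported hit is the
exact local optimum for its strand, which is what the dynamic-programming
audit in the test suite asserts. Ties among equal-scoring optima resolve
to the smallest (query start, subject start). The default word size is
11 for QC-style searches; the word size is a parameter, and callers
aligning sequences with denser mismatches than one per word length
should lower it (the seeding is only guaranteed lossless when the
alignments of interest contain an exact run of at least the word size).

**Statistics.** λ is the unique positive root of
Σᵢⱼ pᵢpⱼ e^{λsᵢⱼ} = 1 (bracketed Brent, tolerance 10⁻¹²). K uses the
standard lattice-case series: with the column-score distribution P, its
k-fold convolutions P_k, span gcd d and relative entropy H,

    σ = Σ_{k=1}^{50} (1/k)·[ Σ_{s<0} P_k(s)·e^{λs} + P(S_k ≥ 0) ],
    K = d·λ·e^{−2σ} / (H·(1 − e^{−λd})).

The series is truncated at 50 terms (terms decay geometrically; the
truncation error is far below 10⁻⁹ here, and the loop exits early once
terms drop below 10⁻¹²). For +1/−2 uniform composition this yields
λ = 1.3327, K = 0.621 — the published ungapped BLASTN values. E-values
use the raw m·n search space with no length adjustment: the sequences
are short, every consumer only thresholds at E ≤ 10⁻⁵, and omitting the
adjustment makes counts bit-reproducible.

## Similarity windows and the choice of word size 11

The cross-hybridization primitive asks whether two sequences share an
ungapped window of ≥ w columns at identity ≥ t on either strand (w = 50,
t = 0.95 for the probe filter; w = 25, strict t = 0.95 and t = 1.0 for
the completeness categories). Candidate diagonals come from exact shared
words; each candidate diagonal is scanned exhaustively (prefix sums over
all window start/end pairs), maximizing identity fraction, then length.

A pigeonhole argument fixes the word size. A qualifying window of L ≥ 50
columns admits at most ⌊0.05·L⌋ mismatches, so it contains an exact run
of at least ⌈(L−m)/(m+1)⌉ matches; minimizing over L gives 15 (at L=60,
m=3) — not 16, which only the L=50 case would justify. Word 11 is
therefore used: it is lossless for every window length in both the
(50, 0.95) and the (25, 0.95) regimes, with margin. Gapped overlaps are
assessed on their longest gap-free stretch, which the diagonal scan
yields directly.

## Assembly QC conventions

"Significant hits" tallies reported hits (a sequence aligning to many
partners contributes many hits), while the identity categories tally
sequences once each by their best qualifying overlap; only this reading
keeps the two kinds of counts on coherent scales. The 100% and >95%
categories are nested (a 100% overlap also counts as >95%); the >95%
bound is strict. In the correctness test, each assembly sequence keeps
one best reference hit per set (lowest E, then highest score, then
lexicographic subject id), and full-length identity divides identities
by the length of the shorter partner, requiring that length to be ≥100
bases.

## Probe design

Length-class boundaries are strict: a 150 nt target receives a single
60-mer and a 300 nt target two ("longer than" switches class). Targets
under 40 nt are undesignable and reported as rejected, not errored. A
per-source override exists because subtracted-library (SSH) targets
always receive two probes regardless of length.

The window score is an invented deterministic stand-in for the vendor's
proprietary criterion:

    score = −|GC − 0.5| − 0.05·(longest homopolymer − 4)₊
            − 0.02·(longest self-complementary stretch − 8)₊,

windows with >10% N ineligible. Its exact shape matters less than its
determinism and the placement contract (every probe is an exact
substring of its target or the target's reverse complement); the
homopolymer and hairpin penalties encode the standard reasons a window
makes a poor oligo. The self-complement length is found by binary search
(the property is monotone in length). "Best distribution" splits the
target into k equal segments and takes the best fully-contained window
per segment; segments shorter than a window borrow from neighbours but
chosen windows stay pairwise distinct. Probe ids are
`<target>|<orientation>|<start>` for traceability.

Array accounting is exact: 243,504 spots, 2,105 controls, 241,399
features; unique probes are placed once and leftover capacity is filled
by cycling through probes in input order with increasing replicate
index.

## Hybridization simulator

The generator emulates a one-color, spike-in-calibrated test-array
study: 4 arrays scanned at PMT gains 400 and 500 (gain factors 1.0 and
1.6), 10 spike-in species at geometric concentrations 1…512 with 60
replicate spots each, 100 negative controls, and a 16-bit scanner
ceiling of 65,535 — deliberately distinct from the 65,000 saturation
call so the two concepts stay separate.

Truth per target: expressed ~ Bernoulli(0.5 by default), orientation
uniform, abundance log-normal(μ=8.3, σ=0.6) in SI units at unit gain
(median ≈ 4,000, comfortably above the calibrated threshold of ≈ 250
and far below saturation, the regime a pooled-sample test hybridization
aims for). Per-probe affinity is log-normal(σ=0.3) drawn once and reused
across arrays; per-spot multiplicative noise is log-normal(σ=0.2),
shared between the two scans of the same physical spot (one
hybridization, two gains). Wrong-orientation and unexpressed probes draw
background N(50, 20) (scaled by gain; may be negative, as real
background-subtracted data can be). Probes similar to a signal-bearing
probe at the (50, 0.95) window criterion receive 10% of that probe's
signal — note this includes the antisense probe covering the same region
as an expressed sense probe, since similarity is checked on both
strands; the selection steps 4–6 exist precisely to resolve such pairs
toward the stronger (true-orientation) probe.

What the simulator does *not* model: spatial artifacts, dye chemistry,
probe-position (3'/5') bias, partial-overlap cross-hybridization below
the window criterion, and sequence-dependent affinity. Passing tests
therefore demonstrate the pipeline's logic — calibration, calling,
selection, conservation — not array chemistry.

## Signal calling

The "lowest three spike-ins" are selected by median replicate SI, not
nominal concentration, so calibration works when concentrations are
unknown. The threshold SD is the sample SD (n−1) over the *pooled*
replicates of those three species: replicates are the observable
variance source, and pooling also absorbs the between-species spread,
giving a conservative threshold. A spot exactly at the threshold is
absent (the boundary is resolved conservatively toward absent);
SI ≥ 65,000 is saturated. Every spot instance, duplicate-fill features
included, is one measurement, producing 4/8/16 denominators.

## Selection

Step order follows the numbered procedure literally, with the
higher-mean-SI rule (step 6) applied as the universal tie-break inside
steps 2–5 and ties broken by lexicographic probe id. Mean SI is the
across-measurement mean of non-flagged intensities at both PMT settings.
Step 3 keeps one best probe per distinct target sequence within each
orientation (covering both duplicate targets and multi-probe targets);
step 4 removes identical probes and then duplicate targets across
orientations, so the final set has pairwise-distinct probe sequences
*and* pairwise-distinct targets — one probe per unique target. The
similarity filter (step 5) is greedy in descending mean SI with exact
window verification against kept probes, so the final set is pairwise
dissimilar and each removal names its keeper. "Redundant target" means
exact sequence identity after case folding; targets that merely overlap
are a documented limitation, not silently merged.

## Problem sizes and determinism

The simulated studies used by the test suite and the acceptance script
run at 500 targets (70–250 nt, ~1,500 probes per orientation pair), 4
arrays × 2 PMT gains — large enough that every selection step fires,
small enough to run on a laptop in under a minute. The aligner audit
uses 1,000 random pairs (length ≤ 40, half with planted mutated copies
so high-scoring optima actually occur, word size 4 in the regime where
seeding is provably lossless for scores ≥ 8); the similarity-filter
audit uses 2,000 60-mers with 50 planted near-duplicate pairs. All
randomness flows from explicit integer seeds; identical seeds give
byte-identical simulator output.

## Known limitations

* The aligner reports the single best hit per strand, not all
  significant local alignments of a pair; completeness "hit" counts are
  therefore per (ordered pair, strand).
* K is computed for ungapped statistics and reused for gapped hits, as
  classical ungapped theory stands in for gapped parameters here; only
  thresholded comparisons at E ≤ 10⁻⁵ consume it.
* The probe-quality score is a documented stand-in; absolute scores are
  not comparable to any vendor tool, only rankings within a target.
* Near-duplicate (partially overlapping) targets can both survive
  selection if their probes are dissimilar; identifying overlapping
  targets is out of scope.
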