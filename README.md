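# estoligo

Design, test and select transcriptome-wide oligonucleotide microarray
probes for species that have rich EST collections but no reference
genome.

When all you have is a large set of assembled ESTs (contigs and
singletons), building a custom expression array means answering four
questions: *is the assembly any good*, *where should probes go*, *which
probes actually light up on a real hybridization*, and *which subset is
unique — one validated probe per unique target transcript*. `estoligo`
implements that whole workflow for one-color spike-in-calibrated arrays,
plus a hybridization simulator so every stage can be exercised and
audited without wet-lab data.

## What it computes

**Assembly QC.** Two BLASTN-style tests over an assembly's unique
sequences. The *completeness* test aligns every sequence against all
others and counts significant hits (E ≤ 10⁻⁵) and sequences with ≥25
overlapping bases at 100% or >95% identity — redundancy a thorough
assembler would have merged. The *correctness* test keeps each
sequence's single most significant hit against reference Sanger ESTs and
counts full-length identity: identities / min(|q|, |s|) ≥ θ with
min(|q|, |s|) ≥ 100 bases (θ = 0.90 same-species, 0.80 congeners).

Alignment statistics are ungapped Karlin–Altschul: λ solves
Σᵢⱼ pᵢpⱼ e^{λ sᵢⱼ} = 1, K comes from the standard lattice series, and
E = K·m·n·e^{−λS} with no length adjustment, so thresholded counts are
exactly reproducible. The search itself is seed-and-extend: an exact
shared word nominates a strand, and a full affine-gap Smith–Waterman
resolves it, so every reported hit is the true local optimum.

**Probe design.** Deterministic re-specification of the vendor design
step. Target length picks the rule — 40–59 nt → one 40-mer; 60–150 nt →
one 60-mer ("best probe"); 151–300 nt → two 60-mers; >300 nt → four
("best distribution" over equal segments) — and windows are ranked by a
documented score (GC balance, homopolymer and self-complementarity
penalties). Probes are designed for both sense and antisense
orientations, deduplicated within probe groups, and packed into a
244K-format layout: 243,504 spots = 2,105 controls + 241,399 features,
leftover capacity filled with duplicate features.

**Signal calling.** Per array × PMT scan, the detection threshold is the
mean + 2 × SD of the pooled replicates of the three lowest spike-in
species; spots at SI ≥ 65,000 are saturated (flagged), spots at or below
the threshold absent, the rest present. Calls aggregate into per-probe
matrices with 4/8/16-measurement denominators (4 arrays × 2 PMT gains,
duplicate features doubling up).

**Probe selection.** The six-step reduction to one validated probe per
unique target: (1) drop probes flagged in >25% of measurements (≥2/4,
3/8, 5/16); call positive at ≥75% present; (2–4) remove redundant
probes and targets within and across orientations; (5) remove probes
sharing ≥95% identity over ≥50 consecutive bases on either strand
(cross-hybridization risk); (6) every conflict keeps the probe with the
higher mean SI. Removals are logged with their step, so input probes are
conserved between the validated set and the provenance log.

## Worked example

Simulate a 60-target study, call signals and select probes:

```
$ estoligo simulate --n-targets 60 --seed 11 --out-prefix demo
60 targets, 170 probes, 7360 spots
$ estoligo call --spots demo.spots.tsv --out demo.calls.tsv
8 calibrations, 170 probes tabulated
$ estoligo select --calls demo.calls.tsv --manifest demo.manifest.tsv \
    --targets demo.targets.fasta --genome-size-mb 700 --out-prefix demo.sel
35 validated probes (sense 51.4%, antisense 48.6%); targeted bases 5333
```

170 probes (both orientations of 60 targets) yield 7,360 spots across 4
arrays × 2 PMT gains including spike-in and negative-control features;
8 calibrations means one spike-in threshold per array × PMT. Roughly
half the targets are expressed in the simulation's truth, and each
expressed target survives as exactly one probe in its true orientation —
hence 35 validated probes with a near-even orientation split.
`demo.sel.tsv` lists each validated probe with its target sequence and
mean/CV signal intensity; `demo.sel.provenance.tsv` records every
removed probe with the step that removed it.

The same pipeline is available as library functions (`completeness_test`,
`design_probes`, `calibrate_threshold`, `select_unique`, ...) — see the
module docstrings and `docs/methods.md`.

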