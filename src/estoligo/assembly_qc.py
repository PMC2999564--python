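"""Assembly-evaluation tests: within-assembly completeness and
reference-based correctness.

The completeness test aligns every unique sequence (contig or singleton)
against all others in the same assembly and tallies (a) significant hits
at an E-value cutoff and (b) sequences whose best ungapped overlap of at
least 25 columns is 100% or >95% identical — a thorough assembler leaves
few such redundancies.  The correctness test aligns each sequence against
reference Sanger EST sets and counts, per reference set, sequences with a
significant best hit and those whose best hit covers the full length of
the shorter partner (>=100 bases) at a per-set identity threshold
(0.90 for same-species references, 0.80 for congeners by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .aligner import (
    DEFAULT_WORD_SIZE,
    KarlinAltschulParams,
    ScoringParams,
    best_window,
    local_align,
    solve_lambda,
)
from .seqcore import SequenceRecord

logger = logging.getLogger(__name__)

#: identity categories are nested: a 100%-qualifying sequence also counts
#: in the >95% column (Table-style nesting).
IDENTITY_MIN_OVERLAP = 25


@dataclass
class CompletenessReport:
    n_sequences: int
    n_significant_hits: int  # tallies hits (ordered pairs x strands), not sequences
    n_identical_25: int
    n_near_identical_25: int
    by_source: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class CorrectnessReport:
    n_sequences: int
    n_significant_vs_ref: dict[str, int]
    n_full_length_identity: dict[str, int]
    identity_thresholds: dict[str, float]
    min_full_length: int


def _category_counts(
    records: Sequence[SequenceRecord], word_size: int
) -> tuple[dict[str, bool], dict[str, bool]]:
    """Per-sequence best-overlap categories via ungapped window scan."""
    ident: dict[str, bool] = {r.id: False for r in records}
    near: dict[str, bool] = {r.id: False for r in records}
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            w = best_window(a.seq, b.seq, IDENTITY_MIN_OVERLAP, word_size)
            if w is None:
                continue
            if w.identity == 1.0:
                ident[a.id] = ident[b.id] = True
                near[a.id] = near[b.id] = True
            elif w.identity > 0.95:
                near[a.id] = near[b.id] = True
    return ident, near


def completeness_test(
    assembly: Sequence[SequenceRecord],
    e_threshold: float = 1e-5,
    params: ScoringParams | None = None,
    word_size: int = DEFAULT_WORD_SIZE,
) -> CompletenessReport:
    """All-vs-all redundancy survey of one assembly.

    Significant hits are tallied per reported hit (a sequence may hit many
    partners, so the count can exceed the number of sequences); the
    identity categories tally sequences once each by their best
    qualifying ungapped overlap.  Gapped overlaps are assessed on their
    longest gap-free stretch, which the window scan yields directly.
    """
    params = params or ScoringParams()
    if len(assembly) < 2:
        warnings.warn("completeness test needs >= 2 sequences; reporting zeros")
        return CompletenessReport(len(assembly), 0, 0, 0)
    ka = solve_lambda(params)
    n_hits = 0
    for q in assembly:
        for s in assembly:
            if q.id == s.id:
                continue
            for h in local_align(q, s, params, min_score=1, word_size=word_size, ka=ka):
                if h.evalue <= e_threshold:
                    n_hits += 1
    ident, near = _category_counts(assembly, word_size)

    by_source: dict[str, dict[str, int]] = {}
    for r in assembly:
        d = by_source.setdefault(r.source, {"n": 0, "identical": 0, "near_identical": 0})
        d["n"] += 1
        d["identical"] += ident[r.id]
        d["near_identical"] += near[r.id]
    return CompletenessReport(
        n_sequences=len(assembly),
        n_significant_hits=n_hits,
        n_identical_25=sum(ident.values()),
        n_near_identical_25=sum(near.values()),
        by_source=by_source,
    )


def correctness_test(
    assembly: Sequence[SequenceRecord],
    refs: Mapping[str, Sequence[SequenceRecord]],
    identity_thresholds: Mapping[str, float] | float = 0.90,
    min_full_length: int = 100,
    e_threshold: float = 1e-5,
    params: ScoringParams | None = None,
    word_size: int = DEFAULT_WORD_SIZE,
) -> CorrectnessReport:
    """Agreement of an assembly with named reference EST collections.

    For each assembly sequence only the single most significant reference
    hit per set is considered (lowest E, then highest score, then
    lexicographic subject id).  It counts toward full-length identity iff
    the shorter of query and subject is >= ``min_full_length`` bases and
    ``identities / min(len(query), len(subject))`` reaches the set's
    threshold.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    params = params or ScoringParams()
    ka = solve_lambda(params)
    if isinstance(identity_thresholds, (int, float)):
        identity_thresholds = {name: float(identity_thresholds) for name in refs}
    n_sig = {name: 0 for name in refs}
    n_full = {name: 0 for name in refs}
    for q in assembly:
        for name, ref_set in refs.items():
            best = None
            for s in ref_set:
                for h in local_align(q, s, params, min_score=1, word_size=word_size, ka=ka):
                    key = (h.evalue, -h.score, h.subject_id)
                    if best is None or key < best[0]:
                        best = (key, h, s)
            if best is None or best[1].evalue > e_threshold:
                continue
            n_sig[name] += 1
            _, hit, subj = best
            full = min(q.length, subj.length)
            if full >= min_full_length and hit.identities / full >= identity_thresholds[name]:
                n_full[name] += 1
    return CorrectnessReport(
        n_sequences=len(assembly),
        n_significant_vs_ref=n_sig,
        n_full_length_identity=n_full,
        identity_thresholds=dict(identity_thresholds),
        min_full_length=min_full_length,
    )


def completeness_tsv(report: CompletenessReport) -> str:
    lines = ["class\tn\tsignificant_hits\tidentical_25\tnear_identical_25"]
    lines.append(
        f"all\t{report.n_sequences}\t{report.n_significant_hits}\t"
        f"{report.n_identical_25}\t{report.n_near_identical_25}"
    )
    for src, d in sorted(report.by_source.items()):
        lines.append(f"{src}\t{d['n']}\t-\t{d['identical']}\t{d['near_identical']}")
    return "\n".join(lines) + "\n"


def correctness_tsv(report: CorrectnessReport) -> str:
    lines = ["ref_set\tidentity_threshold\tsignificant\tfull_length_identity"]
    for name in report.n_significant_vs_ref:
        lines.append(
            f"{name}\t{report.identity_thresholds[name]:.2f}\t"
            f"{report.n_significant_vs_ref[name]}\t{report.n_full_length_identity[name]}"
        )
    return "\n".join(lines) + "\n"
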