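"""Deterministic oligo probe design and 244K array-layout accounting.

Re-specifies the commercial web designer's behaviour as explicit rules:
target-length classes decide probe length and count (40-mers for 40-59 nt
targets, one 60-mer for 60-150 nt, two for 151-300 nt, four above 300 nt,
with per-source overrides such as subtracted-library targets always
getting two probes); window placement maximises a deterministic
sequence-quality score; redundant probes are removed within probe groups;
and leftover array capacity is filled with duplicate features.

The window score is an invented, documented stand-in for the vendor's
proprietary criterion — what matters downstream is that it is
deterministic and that placed probes are exact substrings of their target
(sense) or its reverse complement (antisense):

    score = -|GC - 0.5| - 0.05 * max(longest_homopolymer - 4, 0)
            - 0.02 * max(longest_self_complement - 8, 0)

with windows containing more than 10% N ineligible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqcore import SequenceRecord, reverse_complement

TOTAL_SPOTS_244K = 243504
CONTROL_SPOTS = 2105


@dataclass(frozen=True)
class DesignRule:
    probe_length: int
    probes_per_target: int
    method: str  # best_probe | best_distribution

    def __post_init__(self) -> None:
        if self.probe_length not in (40, 60):
            raise ValueError("probe length must be 40 or 60")
        if self.probes_per_target not in (1, 2, 4):
            raise ValueError("probes per target must be 1, 2 or 4")
        if self.method not in ("best_probe", "best_distribution"):
            raise ValueError("unknown design method")
        if self.probes_per_target >= 2 and self.method != "best_distribution":
            raise ValueError("multi-probe rules use best_distribution")
        if self.probe_length == 40 and self.probes_per_target != 1:
            raise ValueError("40-mer rules are single-probe")


#: override used for subtracted-library (SSH) targets regardless of length
SSH_RULE = DesignRule(60, 2, "best_distribution")


@dataclass(frozen=True)
class ProbeCandidate:
    probe_id: str
    target_id: str
    orientation: str  # sense | antisense
    start: int  # 0-based offset on the stated orientation of the target
    length: int
    seq: str
    group: str = ""

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError("orientation must be sense or antisense")
        if len(self.seq) != self.length:
            raise ValueError("probe sequence length mismatch")


@dataclass
class ArrayDesign:
    total_spots: int
    control_spots: int
    features: list[tuple[str, int]]  # (probe_id, replicate_index)
    n_unique: int
    n_duplicate_fill: int

    def __post_init__(self) -> None:
        if self.total_spots != self.control_spots + self.n_unique + self.n_duplicate_fill:
            raise ValueError("spot accounting does not balance")


def classify_target(length: int, source_override: DesignRule | None = None) -> DesignRule | None:
    """Length-class design rule; None marks an undesignable (<40 nt) target.

    Boundaries are read strictly: a 150 nt target gets a single probe and a
    300 nt target gets two ("longer than" 150/300 switches class).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if source_override is not None:
        return source_override
    if length < 40:
        return None
    if length < 60:
        return DesignRule(40, 1, "best_probe")
    if length <= 150:
        return DesignRule(60, 1, "best_probe")
    if length <= 300:
        return DesignRule(60, 2, "best_distribution")
    return DesignRule(60, 4, "best_distribution")


def _longest_homopolymer(window: str) -> int:
    best = run = 1
    for a, b in zip(window, window[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _has_self_complement(window: str, length: int) -> bool:
    subs = {window[i : i + length] for i in range(len(window) - length + 1)}
    return any(reverse_complement(s) in subs for s in subs if "N" not in s)


def _longest_self_complement(window: str) -> int:
    """Longest substring whose reverse complement also occurs in the window.

    Monotone in length (a qualifying pair of length l contains one of
    length l-1), so binary search applies.
    """
    lo, hi = 0, len(window)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_self_complement(window, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def score_window(window: str) -> float:
    """Deterministic probe-quality score; higher is better, -inf ineligible."""
    if len(window) not in (40, 60):
        raise ValueError("window length must be 40 or 60")
    if window.count("N") > 0.10 * len(window):
        return -math.inf
    gc = (window.count("G") + window.count("C")) / len(window)
    score = -abs(gc - 0.5)
    score -= 0.05 * max(_longest_homopolymer(window) - 4, 0)
    score -= 0.02 * max(_longest_self_complement(window) - 8, 0)
    return score


def design_probes(
    target: SequenceRecord, rule: DesignRule, orientation: str = "sense", group: str = ""
) -> list[ProbeCandidate]:
    """Place ``rule.probes_per_target`` windows on one orientation of a target.

    ``best_probe`` takes the single highest-scoring window (ties broken by
    smallest start).  ``best_distribution`` with k probes splits the
    target into k equal segments and takes the best fully-contained window
    per segment; a segment too short to contain a window borrows from its
    neighbours, and chosen windows are kept pairwise distinct.
    """
    plen = rule.probe_length
    seq = target.seq if orientation == "sense" else reverse_complement(target.seq)
    L = len(seq)
    if L < plen:
        warnings.warn(f"target {target.id} shorter than probe length {plen}")
        return []
    scores = [score_window(seq[i : i + plen]) for i in range(L - plen + 1)]

    def best_start(lo: int, hi: int, taken: set[int]) -> int | None:
        cand = [
            (-scores[i], i)
            for i in range(lo, hi)
            if i not in taken and scores[i] > -math.inf
        ]
        return min(cand)[1] if cand else None

    starts: list[int] = []
    if rule.method == "best_probe" or rule.probes_per_target == 1:
        s = best_start(0, L - plen + 1, set())
        if s is not None:
            starts.append(s)
    else:
        k = rule.probes_per_target
        taken: set[int] = set()
        for seg in range(k):
            seg_lo = seg * L // k
            seg_hi = (seg + 1) * L // k
            lo, hi = seg_lo, seg_hi - plen + 1
            if hi <= lo:  # segment shorter than a window: borrow neighbours
                lo = max(0, seg_hi - plen)
                hi = min(seg_lo, L - plen) + 1
            hi = min(hi, L - plen + 1)
            s = best_start(lo, hi, taken)
            if s is not None:
                taken.add(s)
                starts.append(s)
    return [
        ProbeCandidate(
            probe_id=f"{target.id}|{orientation}|{s}",
            target_id=target.id,
            orientation=orientation,
            start=s,
            length=plen,
            seq=seq[s : s + plen],
            group=group,
        )
        for s in sorted(starts)
    ]


def dedup_exact(probes: Sequence[ProbeCandidate]) -> tuple[list[ProbeCandidate], list[ProbeCandidate]]:
    """One representative per distinct probe sequence.

    The representative is the first occurrence by input (group) order,
    ties by target id.  Returns (kept, removed).
    """
    by_seq: dict[str, ProbeCandidate] = {}
    order: list[str] = []
    removed: list[ProbeCandidate] = []
    for p in probes:
        held = by_seq.get(p.seq)
        if held is None:
            by_seq[p.seq] = p
            order.append(p.seq)
        elif p.target_id < held.target_id and p.group == held.group:
            removed.append(held)
            by_seq[p.seq] = p
        else:
            removed.append(p)
    return [by_seq[s] for s in order], removed


def build_layout(
    probe_groups: Iterable[Sequence[ProbeCandidate]] | Sequence[ProbeCandidate],
    total_spots: int = TOTAL_SPOTS_244K,
    control_spots: int = CONTROL_SPOTS,
) -> ArrayDesign:
    """Place unique probes once and fill leftover capacity with duplicates.

    Feature capacity is ``total_spots - control_spots``; duplicates cycle
    through the probes in input order with increasing replicate index.
    """
    if probe_groups and isinstance(next(iter(probe_groups)), ProbeCandidate):
        probes: list[ProbeCandidate] = list(probe_groups)  # type: ignore[arg-type]
    else:
        probes = [p for grp in probe_groups for p in grp]
    capacity = total_spots - control_spots
    n_unique = len(probes)
    if n_unique > capacity:
        raise ValueError(
            f"{n_unique} unique probes exceed feature capacity {capacity} "
            f"by {n_unique - capacity}"
        )
    features = [(p.probe_id, 0) for p in probes]
    n_fill = capacity - n_unique
    if n_unique:
        rep_counts = {p.probe_id: 0 for p in probes}
        for k in range(n_fill):
            p = probes[k % n_unique]
            rep_counts[p.probe_id] += 1
            features.append((p.probe_id, rep_counts[p.probe_id]))
    elif n_fill:
        raise ValueError("cannot fill an array with zero probes")
    return ArrayDesign(
        total_spots=total_spots,
        control_spots=control_spots,
        features=features,
        n_unique=n_unique,
        n_duplicate_fill=n_fill,
    )


def manifest_tsv(probes: Sequence[ProbeCandidate]) -> str:
    lines = ["probe_id\ttarget_id\torientation\tstart\tlength\tgroup\tseq"]
    for p in probes:
        lines.append(
            f"{p.probe_id}\t{p.target_id}\t{p.orientation}\t{p.start}\t{p.length}\t{p.group}\t{p.seq}"
        )
    return "\n".join(lines) + "\n"
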