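"""Pairwise nucleotide local alignment with Karlin-Altschul E-values.

An internal stand-in for BLASTN used by the assembly-quality tests and the
cross-hybridization similarity filter.  The search is seed-and-extend:
exact shared words nominate a (pair, strand) combination, which is then
resolved by a full affine-gap Smith-Waterman so the reported hit is the
true local optimum for that strand.  E-values follow the ungapped
Karlin-Altschul theory: lambda is the positive root of
``sum_ij p_i p_j exp(lambda * s_ij) = 1`` and ``E = K m n exp(-lambda S)``
with no length adjustment (raw ``m * n`` search space), so thresholded
counts are bit-reproducible.

The similarity primitive :func:`has_similar_window` asks whether two
sequences share an ungapped window of at least ``min_overlap`` columns at
identity >= ``min_identity`` on either strand.  Seeding with exact words
of length 11 is lossless for the (50, 0.95) regime used by the probe
filter and the (25, 0.95) regime used by the completeness test: a window
of L >= 50 columns with at most floor(0.05 L) mismatches always contains
an exact run of at least 15 consecutive matches (the worst case is L=60
with 3 mismatches), and a window of 25-39 columns with one mismatch
contains a run of at least 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import gcd
from typing import Iterable, Sequence

import numpy as np

from .seqcore import SequenceRecord, reverse_complement

DEFAULT_WORD_SIZE = 11  # lossless for the >=95% identity regimes used here


@dataclass(frozen=True)
class ScoringParams:
    """Match/mismatch + affine gap scoring with background composition.

    A gap of length L costs ``gap_open + gap_extend * L``.  The expected
    per-column score under ``composition`` must be negative for the
    Karlin-Altschul statistics to exist.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if abs(sum(self.composition) - 1.0) > 1e-9 or min(self.composition) < 0:
            raise ValueError("composition must be 4 non-negative frequencies summing to 1")
        if self.expected_score >= 0:
            raise ValueError("expected per-column score must be negative")

    @property
    def p_match(self) -> float:
        return float(sum(p * p for p in self.composition))

    @property
    def expected_score(self) -> float:
        pm = sum(p * p for p in self.composition)
        return pm * self.match + (1.0 - pm) * self.mismatch


@dataclass(frozen=True)
class KarlinAltschulParams:
    lam: float
    K: float

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment; coordinates 0-based half-open on forward strands."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aligned_cols: int
    identities: int
    score: int
    evalue: float

    def __post_init__(self) -> None:
        if self.identities > self.aligned_cols:
            raise ValueError("identities cannot exceed aligned columns")
        if self.q_end - self.q_start > self.aligned_cols:
            raise ValueError("query span longer than alignment")


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def _score_distribution(params: ScoringParams) -> tuple[np.ndarray, int]:
    """Probabilities over integer column scores [low..high] -> (probs, low)."""
    low = min(params.mismatch, params.match)
    high = max(params.mismatch, params.match)
    probs = np.zeros(high - low + 1)
    probs[params.match - low] += params.p_match
    probs[params.mismatch - low] += 1.0 - params.p_match
    return probs, low


def solve_lambda(params: ScoringParams, tol: float = 1e-12, k_terms: int = 50) -> KarlinAltschulParams:
    """Solve the ungapped Karlin-Altschul equation for lambda and K.

    lambda is the unique positive root of ``E[exp(lambda * S)] = 1`` for a
    single alignment column, found by bracketed bisection/Brent.  K uses
    the standard lattice-case series: with column-score distribution P,
    span gcd d, relative entropy ``H = sum q_s * s * lambda`` and

        sigma = sum_{k=1}^{k_terms} (1/k) * [ sum_{s<0} P_k(s) e^{lambda s}
                                               + P(S_k >= 0) ],

    where ``P_k`` is the k-fold convolution of P,

        K = d * lambda * exp(-2 sigma) / (H * (1 - exp(-lambda d))).

    The series is truncated at ``k_terms`` (default 50) terms; successive
    terms decay geometrically and the truncation error is far below 1e-9
    for the scoring systems used here.
    """
    from scipy.optimize import brentq

    probs, low = _score_distribution(params)
    scores = np.arange(low, low + len(probs))

    def f(lam: float) -> float:
        return float(np.sum(probs * np.exp(lam * scores)) - 1.0)

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - guarded by expected_score < 0
            raise ArithmeticError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=tol))

    # span gcd of attainable scores
    d = 0
    for s, p in zip(scores, probs):
        if p > 0:
            d = gcd(d, abs(int(s)))
    d = d or 1

    weights = probs * np.exp(lam * scores)
    H = lam * float(np.sum(weights * scores))

    # sigma series over k-fold convolutions of the column-score distribution
    sigma = 0.0
    conv = probs.copy()
    conv_low = low
    for k in range(1, k_terms + 1):
        s_axis = np.arange(conv_low, conv_low + len(conv))
        neg = s_axis < 0
        term = float(np.sum(conv[neg] * np.exp(lam * s_axis[neg])) + np.sum(conv[~neg]))
        sigma += term / k
        if term / k < 1e-12 and k > 5:
            break
        conv = np.convolve(conv, probs)
        conv_low += low
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return KarlinAltschulParams(lam=lam, K=K)


def evalue(score: int, m: int, n: int, ka: KarlinAltschulParams) -> float:
    """E = K * m * n * exp(-lambda * score); no length adjustment."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return ka.K * m * n * math.exp(-ka.lam * score)


# ---------------------------------------------------------------------------
# Seeded local alignment
# ---------------------------------------------------------------------------

def _words(seq: str, w: int) -> set[str]:
    return {seq[i : i + w] for i in range(len(seq) - w + 1) if "N" not in seq[i : i + w]}


def shares_word(a: str, b: str, w: int) -> bool:
    if len(a) < w or len(b) < w:
        return False
    wa = _words(a, w)
    return any(b[i : i + w] in wa for i in range(len(b) - w + 1))


def smith_waterman(
    a: str, b: str, params: ScoringParams
) -> tuple[int, int, int, int, int, int, int]:
    """Affine-gap local alignment (Gotoh) with traceback.

    Returns ``(score, a_start, a_end, b_start, b_end, aligned_cols,
    identities)``; all-zero when no positive-scoring alignment exists.
    Among equal-scoring optima the hit with the smallest
    ``(a_start, b_start)`` is returned.  N never counts as an identity and
    always scores as a mismatch.
    """
    la, lb = len(a), len(b)
    match, mismatch = params.match, params.mismatch
    g1 = params.gap_open + params.gap_extend  # cost of opening a 1-long gap
    ge = params.gap_extend
    NEG = -(10**9)

    H = [[0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in a (consume b)
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap in b (consume a)
    best = 0
    ends: list[tuple[int, int]] = []
    for i in range(1, la + 1):
        ai = a[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(1, lb + 1):
            sub = match if (ai == b[j - 1] and ai != "N") else mismatch
            e = max(Ei[j - 1] + ge, Hi[j - 1] + g1)
            f = max(Fp[j] + ge, Hp[j] + g1)
            h = max(0, Hp[j - 1] + sub, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best = h
                ends = [(i, j)]
            elif h == best and h > 0 and len(ends) < 16:
                ends.append((i, j))
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0

    def traceback(ei: int, ej: int) -> tuple[int, int, int, int]:
        i, j = ei, ej
        state = "H"
        cols = ident = 0
        while True:
            if state == "H":
                h = H[i][j]
                if h == 0:
                    break
                sub = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
                if h == H[i - 1][j - 1] + sub:
                    cols += 1
                    if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                        ident += 1
                    i, j = i - 1, j - 1
                elif h == E[i][j]:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":
                cols += 1
                if E[i][j] == H[i][j - 1] + g1:
                    state = "H"
                j -= 1
            else:
                cols += 1
                if F[i][j] == H[i - 1][j] + g1:
                    state = "H"
                i -= 1
        return i, j, cols, ident

    cand = sorted(traceback(ei, ej) + (ei, ej) for ei, ej in ends)
    i0, j0, cols, ident, ei, ej = cand[0]
    return best, i0, ei, j0, ej, cols, ident


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    params: ScoringParams | None = None,
    min_score: int = 1,
    word_size: int = DEFAULT_WORD_SIZE,
    ka: KarlinAltschulParams | None = None,
) -> list[AlignmentHit]:
    """Seeded local alignment of ``query`` against both strands of ``subject``.

    A strand is examined only when the two sequences share an exact word of
    ``word_size`` bases on it; the shared word triggers a full
    Smith-Waterman resolution, so any reported hit is the locally optimal
    alignment for its strand.  Hits scoring below ``min_score`` are
    dropped.  Subject coordinates always refer to the forward strand.
    """
    params = params or ScoringParams()
    ka = ka or solve_lambda(params)
    if not query.seq or not subject.seq:
        raise ValueError("sequences must be non-empty")
    hits: list[AlignmentHit] = []
    for strand in "+-":
        s_seq = subject.seq if strand == "+" else reverse_complement(subject.seq)
        if not shares_word(query.seq, s_seq, word_size):
            continue
        score, qs, qe, ss, se, cols, ident = smith_waterman(query.seq, s_seq, params)
        if score < min_score:
            continue
        if strand == "-":
            ss, se = subject.length - se, subject.length - ss
        hits.append(
            AlignmentHit(
                query_id=query.id,
                subject_id=subject.id,
                q_start=qs,
                q_end=qe,
                s_start=ss,
                s_end=se,
                strand=strand,
                aligned_cols=cols,
                identities=ident,
                score=score,
                evalue=evalue(score, query.length, subject.length, ka),
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.strand))
    return hits


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    """Tab-separated report in BLAST outfmt-6-like column order.

    Coordinates are 1-based closed in this report only; on the minus
    strand the subject interval is written high-to-low, as BLASTN does.
    """
    with open(path, "w") as fh:
        for h in hits:
            pid = 100.0 * h.identities / h.aligned_cols if h.aligned_cols else 0.0
            gaps = h.aligned_cols - (h.q_end - h.q_start)
            mism = (h.q_end - h.q_start) - h.identities if gaps == 0 else h.aligned_cols - h.identities - gaps
            if h.strand == "+":
                s1, s2 = h.s_start + 1, h.s_end
            else:
                s1, s2 = h.s_end, h.s_start + 1
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{pid:.2f}\t{h.aligned_cols}\t{mism}\t{gaps}\t"
                f"{h.q_start + 1}\t{h.q_end}\t{s1}\t{s2}\t{h.evalue:.3g}\t{h.score}\n"
            )


# ---------------------------------------------------------------------------
# Ungapped similarity windows (cross-hybridization primitive)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityWindow:
    """Best ungapped window: ``a[a_start:a_start+length]`` aligned to the
    ``strand`` representation of ``b`` starting at ``b_start`` (coordinates
    on that representation)."""

    strand: str
    a_start: int
    b_start: int
    length: int
    identities: int

    @property
    def identity(self) -> float:
        return self.identities / self.length


def _seed_diagonals(a: str, b: str, w: int) -> set[int]:
    """Diagonals (a_pos - b_pos) carrying an exact shared w-mer."""
    if len(a) < w or len(b) < w:
        return set()
    index: dict[str, list[int]] = {}
    for i in range(len(a) - w + 1):
        word = a[i : i + w]
        if "N" not in word:
            index.setdefault(word, []).append(i)
    diags: set[int] = set()
    for j in range(len(b) - w + 1):
        for i in index.get(b[j : j + w], ()):
            diags.add(i - j)
    return diags


def _best_on_diagonal(
    a: str, b: str, d: int, min_overlap: int
) -> tuple[float, int, int, int] | None:
    """Best (identity, length, a_start, identities) window on diagonal d."""
    a0, b0 = max(d, 0), max(-d, 0)
    L = min(len(a) - a0, len(b) - b0)
    if L < min_overlap:
        return None
    av = np.frombuffer(a[a0 : a0 + L].encode(), dtype=np.uint8)
    bv = np.frombuffer(b[b0 : b0 + L].encode(), dtype=np.uint8)
    m = (av == bv) & (av != ord("N"))
    cs = np.concatenate(([0], np.cumsum(m)))
    best: tuple[float, int, int, int] | None = None
    for start in range(L - min_overlap + 1):
        lens = np.arange(min_overlap, L - start + 1)
        idents = cs[start + min_overlap : L + 1] - cs[start]
        fracs = idents / lens
        k = int(np.argmax(fracs))
        cand = (float(fracs[k]), int(lens[k]), a0 + start, int(idents[k]))
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    return best


def best_window(
    a: str,
    b: str,
    min_overlap: int,
    word_size: int = DEFAULT_WORD_SIZE,
) -> SimilarityWindow | None:
    """Highest-identity ungapped window of >= ``min_overlap`` columns.

    Only diagonals carrying an exact shared ``word_size``-mer (either
    strand) are scanned, which is exhaustive for any window whose identity
    guarantees such a word (see module docstring); windows of lower
    identity on unseeded diagonals may be missed, which is irrelevant for
    thresholded queries at >=95%.
    """
    out: SimilarityWindow | None = None
    for strand in "+-":
        bs = b if strand == "+" else reverse_complement(b)
        for d in _seed_diagonals(a, bs, word_size):
            r = _best_on_diagonal(a, bs, d, min_overlap)
            if r is None:
                continue
            frac, length, a_start, idents = r
            if out is None or (frac, length) > (out.identity, out.length):
                out = SimilarityWindow(strand, a_start, a_start - d, length, idents)
    return out


def has_similar_window(
    a: str,
    b: str,
    min_overlap: int = 50,
    min_identity: float = 0.95,
    word_size: int = DEFAULT_WORD_SIZE,
    strict: bool = False,
) -> tuple[bool, SimilarityWindow | None]:
    """True iff some ungapped window of >= ``min_overlap`` consecutive
    columns on either strand reaches ``min_identity`` (``>=``, or ``>``
    when ``strict``)."""
    if min_overlap < 1 or not (0 < min_identity <= 1):
        raise ValueError("bad similarity thresholds")
    w = best_window(a, b, min_overlap, word_size)
    if w is None:
        return False, None
    ok = w.identity > min_identity if strict else w.identity >= min_identity
    return ok, (w if ok else None)


class SimilarityIndex:
    """Word-indexed collection supporting 'is this similar to anything kept'.

    Used by the greedy cross-hybridization filter: sequences are added in
    priority order and each query is verified exactly (window scan) against
    only the members sharing a seed word on either strand.
    """

    def __init__(self, min_overlap: int = 50, min_identity: float = 0.95,
                 word_size: int = DEFAULT_WORD_SIZE) -> None:
        self.min_overlap = min_overlap
        self.min_identity = min_identity
        self.word_size = word_size
        self._index: dict[str, set[int]] = {}
        self._seqs: list[str] = []
        self._keys: list[object] = []

    def _query_words(self, seq: str) -> set[str]:
        w = self.word_size
        words = _words(seq, w) | _words(reverse_complement(seq), w)
        return words

    def find_similar(self, seq: str) -> object | None:
        """Key of the first indexed member similar to ``seq``, else None."""
        cand: set[int] = set()
        for word in self._query_words(seq):
            cand |= self._index.get(word, set())
        for idx in sorted(cand):
            ok, _ = has_similar_window(
                self._seqs[idx], seq, self.min_overlap, self.min_identity, self.word_size
            )
            if ok:
                return self._keys[idx]
        return None

    def add(self, key: object, seq: str) -> None:
        idx = len(self._seqs)
        self._seqs.append(seq)
        self._keys.append(key)
        for word in _words(seq, self.word_size):
            self._index.setdefault(word, set()).add(idx)


def similar_pairs(
    seqs: Sequence[str],
    min_overlap: int = 50,
    min_identity: float = 0.95,
    word_size: int = DEFAULT_WORD_SIZE,
) -> set[tuple[int, int]]:
    """All index pairs (i < j) with a qualifying similarity window."""
    index: dict[str, set[int]] = {}
    pairs: set[tuple[int, int]] = set()
    for j, seq in enumerate(seqs):
        cand: set[int] = set()
        words = _words(seq, word_size) | _words(reverse_complement(seq), word_size)
        for word in words:
            cand |= index.get(word, set())
        for i in sorted(cand):
            ok, _ = has_similar_window(seqs[i], seq, min_overlap, min_identity, word_size)
            if ok:
                pairs.add((i, j))
        for word in _words(seq, word_size):
            index.setdefault(word, set()).add(j)
    return pairs
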