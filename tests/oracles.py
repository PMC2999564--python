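"""Independent brute-force oracles used to check the package's operations.

These deliberately share no code with the implementation: the translator
uses a literal codon table, the local-alignment oracle is a plain
score-only Gotoh recurrence without seeding, and the similarity oracles
scan every diagonal and window exhaustively.
"""

from __future__ import annotations

import numpy as np

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq))


def translate_codon(codon: str) -> str:
    if codon in CODON_TABLE:
        return CODON_TABLE[codon]
    # ambiguous codon: X unless every resolution agrees
    options = {
        CODON_TABLE["".join(ch)]
        for ch in __import__("itertools").product(
            *(("ACGT" if c == "N" else c) for c in codon)
        )
    }
    return options.pop() if len(options) == 1 else "X"


def six_frame_orfs(seq: str, min_aa: int):
    """All (frame, start_nt, end_nt, peptide) stop-free runs >= min_aa codons,
    forward-strand half-open coordinates."""
    n = len(seq)
    out = []
    for strand, s in ((+1, seq), (-1, rc(seq))):
        for off in range(3):
            aa = "".join(
                translate_codon(s[i : i + 3]) for i in range(off, n - 2, 3)
            )
            i = 0
            while i < len(aa):
                if aa[i] == "*":
                    i += 1
                    continue
                j = i
                while j < len(aa) and aa[j] != "*":
                    j += 1
                if j - i >= min_aa:
                    a, b = off + 3 * i, off + 3 * j
                    if strand == -1:
                        a, b = n - b, n - a
                    out.append((strand * (off + 1), a, b, aa[i:j]))
                i = j
    return out


def sw_score(a: str, b: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Score-only affine-gap local alignment, plain Gotoh recurrence."""
    NEG = -(10**9)
    la, lb = len(a), len(b)
    H = np.zeros((la + 1, lb + 1), dtype=np.int64)
    E = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    F = np.full((la + 1, lb + 1), NEG, dtype=np.int64)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            H[i, j] = max(0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return int(H.max())


def best_local_score(a: str, b: str, match=1, mismatch=-2, gap_open=-5, gap_extend=-2) -> int:
    """Best local score over both strands of b."""
    return max(
        sw_score(a, b, match, mismatch, gap_open, gap_extend),
        sw_score(a, rc(b), match, mismatch, gap_open, gap_extend),
    )


def window_similar(a: str, b: str, min_overlap: int, min_identity: float, strict: bool = False) -> bool:
    """Exhaustive ungapped window scan over every diagonal of both strands."""
    for bs in (b, rc(b)):
        for d in range(-(len(bs) - 1), len(a)):
            a0, b0 = max(d, 0), max(-d, 0)
            L = min(len(a) - a0, len(bs) - b0)
            if L < min_overlap:
                continue
            m = [
                1 if (a[a0 + k] == bs[b0 + k] and a[a0 + k] != "N") else 0
                for k in range(L)
            ]
            cs = [0]
            for v in m:
                cs.append(cs[-1] + v)
            for i in range(L - min_overlap + 1):
                for j in range(i + min_overlap, L + 1):
                    frac = (cs[j] - cs[i]) / (j - i)
                    if (frac > min_identity) if strict else (frac >= min_identity):
                        return True
    return False


def best_window_identity(a: str, b: str, min_overlap: int) -> float:
    """Max identity fraction over all ungapped windows >= min_overlap columns."""
    best = 0.0
    for bs in (b, rc(b)):
        for d in range(-(len(bs) - 1), len(a)):
            a0, b0 = max(d, 0), max(-d, 0)
            L = min(len(a) - a0, len(bs) - b0)
            if L < min_overlap:
                continue
            cs = [0]
            for k in range(L):
                cs.append(cs[-1] + (1 if (a[a0 + k] == bs[b0 + k] and a[a0 + k] != "N") else 0))
            for i in range(L - min_overlap + 1):
                for j in range(i + min_overlap, L + 1):
                    best = max(best, (cs[j] - cs[i]) / (j - i))
    return best


def similar_pairs_60mers(seqs: list[str]) -> set[tuple[int, int]]:
    """Exhaustive (i < j) pairs of 60-mers with an ungapped window of >= 50
    columns at >= 95% identity on either strand.

    For 60-mers the criterion reduces exactly to: some diagonal overlap
    carries a 50-column window with <= 2 mismatches, or a full 60-column
    overlap (diagonal 0) with <= 3 mismatches — any qualifying window of
    length 51-59 allows floor(0.05 L) = 2 mismatches and therefore
    contains a qualifying 50-column window.
    """
    n = len(seqs)
    enc = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(n, 60)
    renc = np.frombuffer("".join(rc(s) for s in seqs).encode(), dtype=np.uint8).reshape(n, 60)
    nmask = ord("N")
    pairs: set[tuple[int, int]] = set()
    for i in range(n - 1):
        rest = slice(i + 1, n)
        for B in (enc, renc):
            for d in range(-10, 11):
                a0, b0 = max(d, 0), max(-d, 0)
                L = 60 - abs(d)
                av = enc[i, a0 : a0 + L]
                bv = B[rest, b0 : b0 + L]
                mism = (bv != av[None, :]) | (av[None, :] == nmask)
                cs = np.zeros((bv.shape[0], L + 1), dtype=np.int32)
                np.cumsum(mism, axis=1, out=cs[:, 1:])
                win = cs[:, 50:] - cs[:, : L - 49]
                hit = win.min(axis=1) <= 2
                if L == 60:
                    hit |= cs[:, 60] <= 3
                for k in np.nonzero(hit)[0]:
                    pairs.add((i, i + 1 + int(k)))
    return pairs
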