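"""Pairwise nucleotide alignment (Smith-Waterman / overlap) with affine gaps.

This is the workhorse behind genome scanning, clustering and consensus
building.  Scoring follows the usual repeat-annotation convention: unit
match/mismatch scores with affine gaps, where a gap of length L costs
``gap_open + (L-1) * gap_extend``.  ``N`` and IUPAC ambiguity codes match
nothing and are scored as mismatches, including against themselves.

The dynamic programming fill is JIT-compiled with numba; the traceback is
deterministic (diagonal preferred over a gap in the target, over a gap in
the query), and among equally scoring end cells the alignment with the
smallest start in the first sequence, then in the second, then with the
fewest gaps, is returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .seqio import IUPAC_DNA

NEG_INF = np.int32(-(2**30))


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/affine-gap scores; gap penalties must be negative."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -5
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.gap_open >= 0 or self.gap_extend >= 0 or self.mismatch >= 0:
            raise ValueError("mismatch and gap penalties must be negative")


DEFAULT_SCORING = ScoringScheme()

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode DNA to int8: A,C,G,T -> 0..3; N/ambiguity -> 4 (matches nothing)."""
    bad = set(seq) - IUPAC_DNA
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Alignment:
    """A pairwise alignment of ``a`` against ``b``.

    Coordinates are 0-based half-open on the unaligned input strings.
    ``identity`` is matches / aligned columns with gaps counted as columns.
    An empty alignment (no positive-scoring cell) has score 0 and zero-length
    intervals.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    score: int
    n_matches: int
    n_columns: int
    n_gaps: int
    a_aligned: str = ""
    b_aligned: str = ""

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0


@njit(cache=True)
def _gotoh_fill(a, b, match, mismatch, gap_open, gap_extend, local):
    """Fill H/E/F. local=True: Smith-Waterman; False: overlap (free end gaps)."""
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[i, j - 1] + gap_extend
            e2 = H[i, j - 1] + gap_open
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] + gap_extend
            f2 = H[i - 1, j] + gap_open
            if f2 > f:
                f = f2
            F[i, j] = f
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def _traceback(a, b, H, E, F, scheme, end_i, end_j, local):
    """Deterministic traceback from (end_i, end_j); diagonal > gap-in-b > gap-in-a."""
    i, j = end_i, end_j
    a_parts: list[str] = []
    b_parts: list[str] = []
    n_matches = 0
    n_gaps = 0
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            h = H[i, j]
            if local and h == 0:
                break
            if not local and (i == 0 or j == 0):
                break  # free end gaps: stop at matrix edge
            s = (
                scheme.match
                if (a[i - 1] == b[j - 1] and a[i - 1] < 4)
                else scheme.mismatch
            )
            if i > 0 and j > 0 and h == H[i - 1, j - 1] + s:
                a_parts.append(chr(a[i - 1]))
                b_parts.append(chr(b[j - 1]))
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    n_matches += 1
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            elif h == E[i, j]:
                state = "E"
            else:  # pragma: no cover - matrices are consistent by construction
                raise AssertionError("inconsistent DP matrices")
        elif state == "F":  # gap in b, consumes a
            a_parts.append(chr(a[i - 1]))
            b_parts.append("-")
            n_gaps += 1
            if F[i, j] == H[i - 1, j] + scheme.gap_open:
                state = "H"
            i -= 1
        else:  # state == "E": gap in a, consumes b
            a_parts.append("-")
            b_parts.append(chr(b[j - 1]))
            n_gaps += 1
            if E[i, j] == H[i, j - 1] + scheme.gap_open:
                state = "H"
            j -= 1
    return i, j, n_matches, n_gaps, a_parts, b_parts


_DECODE = "ACGT" + "N" * 28


def _decode_parts(parts: list[str], src: str, start: int) -> str:
    # traceback emitted encoded bytes as chr(code); rebuild from source string
    out = []
    pos = start
    for ch in reversed(parts):
        if ch == "-":
            out.append("-")
        else:
            out.append(src[pos])
            pos += 1
    return "".join(out)


def local_align(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Optimal local (Smith-Waterman) alignment of ``a`` against ``b``.

    Among co-optimal alignments, the one with the smallest start in ``a``,
    then in ``b``, then with the fewest gaps, is returned.  When no cell
    scores positively the empty alignment (score 0) is returned.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = encode(a), encode(b)
    H, E, F = _gotoh_fill(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open,
        scoring.gap_extend, True,
    )
    best = int(H.max())
    if best == 0:
        return Alignment(0, 0, 0, 0, 0, 0, 0, 0)
    ends = np.argwhere(H == best)
    # examine up to 16 co-optimal end cells in (i, j) order
    candidates = []
    for end_i, end_j in ends[:16]:
        si, sj, nm, ng, ap, bp = _traceback(
            ea, eb, H, E, F, scoring, int(end_i), int(end_j), True
        )
        candidates.append((si, sj, ng, int(end_i), int(end_j), nm, ap, bp))
    si, sj, ng, ei, ej, nm, ap, bp = min(candidates, key=lambda c: c[:3])
    return Alignment(
        si, ei, sj, ej, best, nm, len(ap), ng,
        _decode_parts(ap, a, si), _decode_parts(bp, b, sj),
    )


def overlap_align(
    a: str, b: str, scoring: ScoringScheme = DEFAULT_SCORING
) -> Alignment:
    """Global alignment with free end gaps (overlap alignment).

    The returned aligned strings cover only the aligned cores; the
    ``*_start``/``*_end`` fields say which parts of the inputs they span.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ea, eb = encode(a), encode(b)
    H, E, F = _gotoh_fill(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open,
        scoring.gap_extend, False,
    )
    n, m = len(a), len(b)
    # best cell on the last row or column (free trailing gaps)
    best = NEG_INF
    end_i = end_j = 0
    for j in range(m + 1):
        if H[n, j] > best:
            best, end_i, end_j = H[n, j], n, j
    for i in range(n + 1):
        if H[i, m] > best:
            best, end_i, end_j = H[i, m], i, m
    si, sj, nm, ng, ap, bp = _traceback(
        ea, eb, H, E, F, scoring, end_i, end_j, False
    )
    return Alignment(
        si, end_i, sj, end_j, int(best), nm, len(ap), ng,
        _decode_parts(ap, a, si), _decode_parts(bp, b, sj),
    )
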