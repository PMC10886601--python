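"""Structural annotation of TRIM elements.

The defining features of a TRIM are detected here: the terminal repeat
pair (LTRs), the target site duplication (TSD) in the flanking genomic
sequence, the primer-binding site (PBS) complementary to a tRNA just
inside the 5' LTR, the polypurine tract (PPT) just before the 3' LTR, and
solo LTRs left behind by LTR-LTR recombination.

PBS typing supports the two priming modes seen in LTR retrotransposons:
complementarity to the mature tRNA 3' terminus (including the
post-transcriptional CCA), and complementarity to the anticodon loop of
the spliced tRNA (3'-truncated priming).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import DEFAULT_SCORING, ScoringScheme, encode, local_align
from .seqio import SeqRecord, TrnaRecord, revcomp

#: anticodon loop region on the spliced tRNA, 0-based half-open
#: (conventional positions 32-40)
ANTICODON_LOOP = (31, 40)


@dataclass(frozen=True)
class LtrPair:
    """Detected terminal repeat pair (0-based half-open on the input)."""

    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    identity: float

    @property
    def element(self) -> tuple[int, int]:
        return (self.ltr5[0], self.ltr3[1])

    @property
    def internal(self) -> tuple[int, int]:
        return (self.ltr5[1], self.ltr3[0])


def detect_ltr_pair(
    seq: str,
    min_ltr: int = 80,
    max_ltr: int = 400,
    min_identity: float = 0.8,
    search_depth: Optional[int] = None,
    anchored: bool = False,
    anchor_slack: int = 5,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Optional[LtrPair]:
    """Locate the highest-scoring repeat between a prefix and a suffix window.

    The prefix and suffix windows span ``search_depth`` nt (default
    ``max_ltr + 100``), capped at half the sequence so they never overlap.
    A qualifying repeat has at least ``min_ltr`` aligned columns at
    ``min_identity`` or better; its boundaries are then extended outward
    while the flanking columns still match.  With ``anchored=True`` (for a
    sequence that is exactly one element) boundaries within ``anchor_slack``
    of the sequence ends are snapped to them, preserving the repeat
    relation.  Returns None when no qualifying repeat exists.
    """
    n = len(seq)
    if n < 2 * min_ltr:
        return None
    w = search_depth if search_depth is not None else max_ltr + 100
    w = min(w, n // 2)
    if w < min_ltr:
        return None
    off = n - w
    aln = local_align(seq[:w], seq[off:], scoring)
    if aln.is_empty or aln.n_columns < min_ltr or aln.identity < min_identity:
        return None
    s5, e5 = aln.a_start, aln.a_end
    s3, e3 = off + aln.b_start, off + aln.b_end
    matches, cols = aln.n_matches, aln.n_columns
    # extend outward while columns match exactly (never into the other LTR)
    while s5 > 0 and s3 > e5 and seq[s5 - 1] == seq[s3 - 1] and seq[s5 - 1] != "N":
        s5 -= 1
        s3 -= 1
        matches += 1
        cols += 1
    while e3 < n and e5 < s3 and seq[e5] == seq[e3] and seq[e5] != "N":
        e5 += 1
        e3 += 1
        matches += 1
        cols += 1
    if anchored:
        d5, d3 = s5, n - e3
        if d5 <= anchor_slack and d3 <= anchor_slack and e5 + d3 <= s3 - d5:
            s5, s3 = 0, s3 - d5
            e5, e3 = e5 + d3, n
            cols += d5 + d3
    if e5 > s3:
        return None
    return LtrPair((s5, e5), (s3, e3), matches / cols)


def detect_tsd(
    seq: str, start: int, end: int, min_len: int = 4, max_len: int = 6
) -> Optional[str]:
    """Longest exact 4-6 bp duplication flanking ``seq[start:end]``.

    Compares the suffix of the left flank with the prefix of the right
    flank; the longest exact match in ``[min_len, max_len]`` wins.  Returns
    None when the flanks disagree or are shorter than ``min_len``.
    """
    avail = min(start, len(seq) - end, max_len)
    for L in range(avail, min_len - 1, -1):
        left = seq[start - L : start]
        if "N" not in left and left == seq[end : end + L]:
            return left
    return None


def detect_tsd_interval(genome: Sequence[SeqRecord], interval) -> Optional[str]:
    """TSD detection addressed by a :class:`~trimp3.seqio.GenomeInterval`."""
    by_id = {r.id: r.residues for r in genome}
    return detect_tsd(by_id[interval.seq_id], interval.start, interval.end)


@dataclass(frozen=True)
class PbsCall:
    """A primer-binding-site call against one tRNA."""

    trna_id: str
    mode: str  # "three_prime_end" | "anticodon_loop"
    pbs_interval: tuple[int, int]
    complementary_length: int
    mismatches: int


def _mismatch_matrix(win: np.ndarray, pat: np.ndarray) -> np.ndarray:
    """mm[p, l]: window position p+l does not pair with pattern position l."""
    P = win.shape[0]
    L = pat.shape[0]
    padded = np.full(P + L, 5, dtype=np.int8)
    padded[:P] = win
    view = np.lib.stride_tricks.sliding_window_view(padded, L)[:P]
    return (view != pat) | (view >= 4) | (pat >= 4)


def _budget_ok(length: int, mism: int, max_mismatch: int, mismatch_min_len: int) -> bool:
    allowed = max_mismatch if length >= mismatch_min_len else 0
    return mism <= allowed


def detect_pbs(
    internal_seq: str,
    trna_library: Sequence[TrnaRecord],
    min_match: int = 8,
    max_mismatch: int = 1,
    window: int = 50,
    mismatch_min_len: int = 12,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Optional[PbsCall]:
    """Type the PBS in the first ``window`` nt of the internal region.

    Two priming modes are searched for every library tRNA: complementarity
    anchored at the mature 3' terminus (CCA included), and complementarity
    covering the anticodon loop of the spliced tRNA.  The best call is the
    longest complementary stretch; stretches must begin and end with paired
    bases, and a mismatch is tolerated only in stretches of at least
    ``mismatch_min_len`` nt (a mismatch in a shorter duplex is not credible
    complementarity).  Ties break toward fewer mismatches, 3'-end mode,
    library order, then the leftmost position.
    """
    if len(internal_seq) < min_match or not trna_library:
        return None
    win_seq = internal_seq[:window]
    win = encode(win_seq)
    P = win.shape[0]
    loop_lo, loop_hi = ANTICODON_LOOP
    candidates: list[tuple] = []

    for t_idx, trna in enumerate(trna_library):
        # --- mode 1: anchored at the mature 3' terminus ------------------
        pat = encode(revcomp(trna.mature))
        mm = _mismatch_matrix(win, pat)
        cs = np.cumsum(mm, axis=1)
        Larr = np.arange(1, pat.shape[0] + 1)[None, :]
        valid = (
            ~mm
            & ~mm[:, :1]
            & ((cs == 0) | ((cs <= max_mismatch) & (Larr >= mismatch_min_len)))
            & (Larr >= min_match)
        )
        ps, ls = np.nonzero(valid)
        if ps.size:
            lengths = ls + 1
            mism = cs[ps, ls]
            # best per tRNA: longest, then fewest mismatches, then leftmost
            order = np.lexsort((ps, mism, -lengths))
            k = order[0]
            candidates.append(
                (
                    -int(lengths[k]),
                    int(mism[k]),
                    0,
                    t_idx,
                    int(ps[k]),
                    trna.id,
                    "three_prime_end",
                )
            )

        # --- mode 2: anticodon loop of the spliced tRNA ------------------
        spliced = trna.spliced
        if len(spliced) >= loop_hi:
            pat_full = encode(revcomp(spliced))
            lp_lo = len(spliced) - loop_hi
            lp_hi = len(spliced) - loop_lo
            seed = pat_full[lp_lo:lp_hi]
            seed_len = seed.shape[0]
            if P < seed_len:
                continue
            mm9 = _mismatch_matrix(win, seed)
            seed_sums = mm9.sum(axis=1)
            for p in np.nonzero(seed_sums[: P - seed_len + 1] <= max_mismatch)[0]:
                p = int(p)
                seed_mm = int(seed_sums[p])
                # exact extension on both sides of the seed
                lo_w, lo_p = p, lp_lo
                while lo_w > 0 and lo_p > 0:
                    cw, cp = win[lo_w - 1], pat_full[lo_p - 1]
                    if cw != cp or cw >= 4:
                        break
                    lo_w -= 1
                    lo_p -= 1
                hi_w, hi_p = p + seed_len, lp_hi
                while hi_w < P and hi_p < pat_full.shape[0]:
                    cw, cp = win[hi_w], pat_full[hi_p]
                    if cw != cp or cw >= 4:
                        break
                    hi_w += 1
                    hi_p += 1
                # trim terminal mismatches (stretch must end in pairs)
                a, b, pa = lo_w, hi_w, lo_p
                while a < b and (win[a] != pat_full[pa] or win[a] >= 4):
                    a += 1
                    pa += 1
                    seed_mm -= 1
                pb = hi_p
                while b > a and (win[b - 1] != pat_full[pb - 1] or win[b - 1] >= 4):
                    b -= 1
                    pb -= 1
                    seed_mm -= 1
                L = b - a
                if L >= max(min_match, 1) and _budget_ok(
                    L, seed_mm, max_mismatch, mismatch_min_len
                ):
                    candidates.append(
                        (-L, seed_mm, 1, t_idx, a, trna.id, "anticodon_loop")
                    )
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[:5])
    negL, m, _, _, p, trna_id, mode = candidates[0]
    return PbsCall(trna_id, mode, (p, p - negL), -negL, m)


def detect_ppt(
    internal_seq: str,
    window: int = 10,
    min_purine_frac: float = 0.8,
    max_gap_to_ltr: int = 5,
) -> Optional[tuple[int, int]]:
    """Find the polypurine tract at the 3' end of the internal region.

    The right-most window of at least ``window`` nt with a purine (A/G)
    fraction of ``min_purine_frac`` ending within ``max_gap_to_ltr`` nt of
    the internal/3'-LTR junction is reported, extended leftward one base at
    a time while the fraction holds.
    """
    n = len(internal_seq)
    if n < window:
        return None
    purine = np.frombuffer(internal_seq.encode(), dtype=np.uint8)
    is_pur = (purine == ord("A")) | (purine == ord("G"))
    for gap in range(0, max_gap_to_ltr + 1):
        e = n - gap
        if e < window:
            break
        s = e - window
        if is_pur[s:e].sum() / window < min_purine_frac:
            continue
        while s > 0 and is_pur[s - 1 : e].sum() / (e - s + 1) >= min_purine_frac:
            s -= 1
        return (s, e)
    return None


@dataclass(frozen=True)
class SoloLtr:
    """A solo-LTR call: the hit plus the TSD directly flanking the lone LTR."""

    hit: object
    tsd: str


def find_solo_ltrs(
    ltr_hits,
    internal_hits,
    family,
    genome: Sequence[SeqRecord],
    min_coverage: float = 0.9,
    max_internal_distance: int = 50,
) -> list[SoloLtr]:
    """Identify solo LTRs among genome hits of a partitioned family.

    A hit is a solo LTR when it covers at least ``min_coverage`` of the LTR
    consensus, no same-family internal hit lies within
    ``max_internal_distance`` nt, and a single exact 4-6 bp TSD directly
    flanks the lone LTR.
    """
    if family.partition is None:
        raise ValueError(f"family {family.family_id!r} is not partitioned")
    ltr_len = family.partition.ltr_length
    by_id = {r.id: r.residues for r in genome}
    solos: list[SoloLtr] = []
    for h in ltr_hits:
        if h.query_coverage < min_coverage:
            continue
        near_internal = any(
            ih.seq_id == h.seq_id
            and ih.start - max_internal_distance <= h.end
            and h.start <= ih.end + max_internal_distance
            for ih in internal_hits
        )
        if near_internal:
            continue
        src = by_id[h.seq_id]
        # project the full LTR extent from the aligned part (a mutated edge
        # base is trimmed by local alignment), then allow +-2 nt of drift
        if h.strand == "+":
            est_s = h.start - h.q_start
            est_e = h.end + (ltr_len - h.q_end)
        else:
            est_s = h.start - (ltr_len - h.q_end)
            est_e = h.end + h.q_start
        best = None
        for d1 in (0, -1, 1, -2, 2):
            for d2 in (0, -1, 1, -2, 2):
                tsd = detect_tsd(src, est_s + d1, est_e + d2)
                if tsd is not None and (
                    best is None
                    or (len(tsd), -abs(d1) - abs(d2)) > (len(best), -best_d)
                ):
                    best, best_d = tsd, abs(d1) + abs(d2)
        if best is None:
            continue
        solos.append(SoloLtr(h, best))
    return solos


@dataclass
class TrimAnnotation:
    """Structural annotation of one element consensus or copy."""

    ltr5: tuple[int, int]
    internal: tuple[int, int]
    ltr3: tuple[int, int]
    ltr_identity: float
    tsd: Optional[str] = None
    pbs: Optional[PbsCall] = None
    ppt: Optional[tuple[int, int]] = None
    boxes: Optional[object] = None  # PromoterAnnotation


def annotate_element(
    seq: str,
    trna_library: Optional[Sequence[TrnaRecord]] = None,
    min_ltr: int = 80,
    max_ltr: int = 400,
    min_ltr_identity: float = 0.8,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> Optional[TrimAnnotation]:
    """Full structural annotation of a trimmed element sequence.

    Detects the LTR pair (anchored at the sequence ends), then the PBS (if
    a tRNA library is given), the PPT, and the pol III promoter boxes in
    the 5' LTR.  Returns None when no LTR pair is found.
    """
    from .promoter import scan_5s_promoter, scan_trna_promoter

    pair = detect_ltr_pair(
        seq, min_ltr, max_ltr, min_ltr_identity, anchored=True, scoring=scoring
    )
    if pair is None:
        return None
    internal_seq = seq[pair.internal[0] : pair.internal[1]]
    pbs = None
    if trna_library and len(internal_seq) >= 8:
        pbs = detect_pbs(internal_seq, trna_library, scoring=scoring)
    ppt = detect_ppt(internal_seq) if internal_seq else None
    if ppt is not None:
        ppt = (ppt[0] + pair.internal[0], ppt[1] + pair.internal[0])
    ltr_seq = seq[pair.ltr5[0] : pair.ltr5[1]]
    boxes = scan_trna_promoter(ltr_seq) if len(ltr_seq) >= 40 else None
    if boxes is None or boxes.promoter_type == "none":
        alt = scan_5s_promoter(ltr_seq) if len(ltr_seq) >= 60 else None
        if alt is not None and alt.promoter_type != "none":
            boxes = alt
    if pbs is not None:
        pbs = PbsCall(
            pbs.trna_id,
            pbs.mode,
            (
                pbs.pbs_interval[0] + pair.internal[0],
                pbs.pbs_interval[1] + pair.internal[0],
            ),
            pbs.complementary_length,
            pbs.mismatches,
        )
    return TrimAnnotation(
        ltr5=pair.ltr5,
        internal=pair.internal,
        ltr3=pair.ltr3,
        ltr_identity=pair.identity,
        pbs=pbs,
        ppt=ppt,
        boxes=boxes,
    )
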