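"""Family consensus construction and iterative extension to element termini.

Consensus sequences are built from a center-star multiple alignment by the
50% majority rule: columns that are mostly gaps are dropped, a base is
emitted when it reaches half of the non-gap characters, and ambiguous
columns become ``N``.  ``extend_to_termini`` reproduces the classic repeat
library refinement loop: re-scan the genome with the current consensus,
extract the best copies with generous flanks, rebuild the consensus, and
look for the element boundaries (an LTR pair whose ends are corroborated by
4-6 bp target site duplications in the individual copies); the loop stops
once the detected boundaries are stable between rounds.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import DEFAULT_SCORING, Alignment, ScoringScheme, local_align
from .seqio import SeqRecord

_BASE_ORDER = {c: i for i, c in enumerate("ACGTN")}


@dataclass(frozen=True)
class Partition:
    """LTR/internal partition of a full-length consensus (0-based half-open)."""

    ltr5: tuple[int, int]
    internal: tuple[int, int]
    ltr3: tuple[int, int]

    def __post_init__(self) -> None:
        if self.ltr5[0] != 0:
            raise ValueError("5' LTR must start at the element start")
        if not (self.ltr5[1] == self.internal[0] and self.internal[1] == self.ltr3[0]):
            raise ValueError("LTR/internal intervals must tile the consensus")

    @property
    def ltr_length(self) -> int:
        return self.ltr5[1] - self.ltr5[0]

    @property
    def internal_length(self) -> int:
        return self.internal[1] - self.internal[0]


@dataclass
class FamilyModel:
    """A repeat family: consensus plus (optionally) its structural partition."""

    family_id: str
    consensus: str
    partition: Optional[Partition] = None
    family_class: str = "unclassified"
    tsd_length: Optional[int] = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.partition is not None and self.partition.ltr3[1] != len(self.consensus):
            raise ValueError("3' LTR must end at the element end")

    @property
    def ltr_consensus(self) -> str:
        if self.partition is None:
            raise ValueError(f"family {self.family_id!r} is not partitioned")
        return self.consensus[slice(*self.partition.ltr5)]

    @property
    def ltr3_consensus(self) -> str:
        if self.partition is None:
            raise ValueError(f"family {self.family_id!r} is not partitioned")
        return self.consensus[slice(*self.partition.ltr3)]

    @property
    def internal_consensus(self) -> str:
        if self.partition is None:
            raise ValueError(f"family {self.family_id!r} is not partitioned")
        return self.consensus[slice(*self.partition.internal)]


@dataclass
class Msa:
    """A multiple sequence alignment: (member id, gapped row) pairs."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA needs at least one row")
        width = len(self.rows[0][1])
        if any(len(r) != width for _, r in self.rows):
            raise ValueError("MSA rows differ in length")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1])

    def member_sequence(self, i: int) -> str:
        return self.rows[i][1].replace("-", "")

    def to_member(self, i: int, column: int) -> int:
        """Member coordinate of the first residue at or after ``column``."""
        return sum(1 for c in self.rows[i][1][:column] if c != "-")


def _merge_to_center(
    center_seq: str,
    members: Sequence[SeqRecord],
    alignments: Sequence,
    center_id: Optional[str] = None,
) -> Msa:
    """Merge pairwise member-vs-center alignments into common columns.

    ``alignments[i]`` is the overlap alignment of ``members[i].residues``
    (as sequence a) against ``center_seq`` (as sequence b).  When
    ``center_id`` is given the center itself is included as the first row.
    """
    Lc = len(center_seq)
    col_chars: list[list[str]] = []
    inserts: list[dict[int, str]] = []
    for member, aln in zip(members, alignments):
        m_seq = member.residues
        chars = ["-"] * Lc
        ins: dict[int, str] = {}
        if aln.a_start:
            ins[aln.b_start] = m_seq[: aln.a_start]
        cpos = aln.b_start
        for mc, cc in zip(aln.a_aligned, aln.b_aligned):
            if cc == "-":
                ins[cpos] = ins.get(cpos, "") + mc
            else:
                if mc != "-":
                    chars[cpos] = mc
                cpos += 1
        if aln.a_end < len(m_seq):
            ins[aln.b_end] = ins.get(aln.b_end, "") + m_seq[aln.a_end :]
        col_chars.append(chars)
        inserts.append(ins)

    ins_len = [0] * (Lc + 1)
    for ins in inserts:
        for pos, s in ins.items():
            ins_len[pos] = max(ins_len[pos], len(s))

    def _row(chars: list[str], ins: dict[int, str]) -> str:
        parts = []
        for pos in range(Lc + 1):
            if ins_len[pos]:
                mine = ins.get(pos, "")
                parts.append("-" * (ins_len[pos] - len(mine)) + mine)
            if pos < Lc:
                parts.append(chars[pos])
        return "".join(parts)

    rows = []
    if center_id is not None:
        rows.append((center_id, _row(list(center_seq), {})))
    for member, chars, ins in zip(members, col_chars, inserts):
        rows.append((member.id, _row(chars, ins)))
    return Msa(rows)


def build_msa(
    members: Sequence[SeqRecord],
    scoring: ScoringScheme = DEFAULT_SCORING,
    refine: bool = True,
) -> Msa:
    """Center-star multiple alignment.

    The center is the member with the greatest total pairwise alignment
    score against all others (ties broken by input order); every other
    member is aligned to the center with free end gaps and the pairwise gap
    patterns are merged into common columns.  With ``refine=True`` a second
    pass realigns every member against the first-pass majority consensus,
    which restores characters lost when the center itself carries a
    deletion (single-member insertions can otherwise scatter over adjacent
    columns and fall below the majority threshold).
    """
    if not members:
        raise ValueError("need at least one member")
    if len(members) == 1:
        return Msa([(members[0].id, members[0].residues)])
    n = len(members)
    pair: dict[tuple[int, int], object] = {}
    totals = [0] * n
    for i in range(n):
        for j in range(i + 1, n):
            aln = local_align(members[i].residues, members[j].residues, scoring)
            pair[(i, j)] = aln
            totals[i] += aln.score
            totals[j] += aln.score
    center = max(range(n), key=lambda i: (totals[i], -i))
    c_seq = members[center].residues
    others = [m for i, m in enumerate(members) if i != center]
    alns = []
    for i, m in enumerate(members):
        if i == center:
            continue
        aln = pair[(min(i, center), max(i, center))]
        if i > center:  # stored as (center, member): swap to (member, center)
            aln = Alignment(
                aln.b_start, aln.b_end, aln.a_start, aln.a_end, aln.score,
                aln.n_matches, aln.n_columns, aln.n_gaps,
                aln.b_aligned, aln.a_aligned,
            )
        alns.append(aln)
    msa = _merge_to_center(c_seq, others, alns, center_id=members[center].id)
    if refine and n >= 3:
        cons = majority_consensus(msa)
        if cons and cons != c_seq:
            # splice the corrected core into the center's own context so the
            # realignment keeps the center's geometry (members' tails stay
            # in real columns instead of piling into insert blocks)
            loc = local_align(cons, c_seq, scoring)
            if not loc.is_empty:
                scaffold = (
                    c_seq[: loc.b_start]
                    + cons[loc.a_start : loc.a_end]
                    + c_seq[loc.b_end :]
                )
                alns = [local_align(m.residues, scaffold, scoring) for m in members]
                msa = _merge_to_center(scaffold, members, alns, center_id=None)
    # restore input order of members
    rows_by_id = dict(msa.rows)
    return Msa([(m.id, rows_by_id[m.id]) for m in members])


def majority_consensus(msa: Msa, threshold: float = 0.5) -> str:
    """50% majority-rule consensus (see :func:`majority_consensus_columns`)."""
    return majority_consensus_columns(msa, threshold)[0]


def majority_consensus_columns(
    msa: Msa, threshold: float = 0.5
) -> tuple[str, list[int]]:
    """Majority-rule consensus plus the MSA column index of each emitted char.

    Per column: if the gap frequency is at least ``threshold`` the column is
    dropped; otherwise the most frequent non-gap character is emitted when
    its frequency among non-gap characters reaches ``threshold`` and ``N``
    is emitted otherwise.  Ties break by fixed base order A<C<G<T.
    """
    n = len(msa.rows)
    out = []
    columns = []
    for col in range(msa.column_count):
        chars = [r[col] for _, r in msa.rows]
        gaps = chars.count("-")
        if gaps / n >= threshold:
            continue
        counts = Counter(c for c in chars if c != "-")
        nongap = n - gaps
        best = min(
            counts.items(),
            key=lambda kv: (-kv[1], _BASE_ORDER.get(kv[0], 99), kv[0]),
        )
        out.append(best[0] if best[1] / nongap >= threshold else "N")
        columns.append(col)
    return "".join(out), columns


def supported_consensus(
    msa: Msa, threshold: float = 0.55, window: int = 15, margin: int = 50
) -> str:
    """Majority consensus trimmed to its well-supported core.

    Support of a consensus column is the fraction of rows whose character
    equals the consensus character.  Columns outside the homologous core
    (superimposed unrelated flanks) rarely exceed ~0.35 while genuinely
    homologous columns stay near 1; the longest contiguous run whose
    moving-average support reaches ``threshold`` is returned, padded by
    ``margin`` extra columns on each side so that smoothing losses at the
    core edges never cut genuine terminal bases.
    """
    cons, cols = majority_consensus_columns(msa)
    if not cons:
        return cons
    n_rows = len(msa.rows)
    support = []
    for ch, col in zip(cons, cols):
        if ch == "N":
            support.append(0.0)
            continue
        agree = sum(1 for _, r in msa.rows if r[col] == ch)
        support.append(agree / n_rows)
    s = np.asarray(support)
    w = min(window, len(s))
    kernel = np.ones(w)
    # normalize by the actual window coverage so edge columns are not
    # penalized by the implicit zero padding
    smooth = np.convolve(s, kernel, mode="same") / np.convolve(
        np.ones_like(s), kernel, mode="same"
    )
    good = smooth >= threshold
    # longest contiguous run of well-supported columns
    best_len = best_start = cur_start = 0
    cur_len = 0
    for i, g in enumerate(good):
        if g:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    if best_len == 0:
        return cons
    lo = max(0, best_start - margin)
    hi = min(len(cons), best_start + best_len + margin)
    return cons[lo:hi]


def extend_to_termini(
    hits,
    genome,
    flank: int = 500,
    max_rounds: int = 10,
    max_copies: int = 10,
    family_id: Optional[str] = None,
    min_ltr: int = 80,
    max_ltr: int = 400,
    min_ltr_identity: float = 0.8,
    min_identity: float = 0.6,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> FamilyModel:
    """Iteratively extend a cluster's consensus until the element termini are found.

    Each round re-scans the genome with the current consensus, extracts up
    to ``max_copies`` best hits with ``flank`` nt of genomic context,
    rebuilds the majority-rule consensus and attempts to locate the LTR
    pair; candidate boundaries are refined by up to +-3 nt so that as many
    individual copies as possible show an exact 4-6 bp target site
    duplication at them.  The loop stops when boundaries are stable (+-2 nt)
    in two consecutive rounds.  The returned consensus is trimmed to the
    element (TSDs excluded).  If no termini are found the model is returned
    unpartitioned with a ``no_termini`` flag.
    """
    from .scan import GenomeIndex, hit_sequence, scan_genome
    from .structure import detect_ltr_pair, detect_tsd

    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    if not hits:
        raise ValueError("empty hit cluster")
    fid = family_id or hits[0].family_id

    top = _select_members(hits, max_copies)
    members = [
        SeqRecord(f"{fid}|m{i}", hit_sequence(index.records, h)[0])
        for i, h in enumerate(top)
    ]
    cons = supported_consensus(build_msa(members, scoring))

    prev_dims: Optional[tuple[int, int]] = None
    best: Optional[FamilyModel] = None
    for _round in range(max_rounds):
        if len(cons) < max(30, 2 * min_ltr // 2):
            break  # cluster of short fragments: cannot carry an LTR pair
        round_hits = scan_genome(
            index, FamilyModel(fid, cons), min_identity=min_identity, scoring=scoring
        )
        if not round_hits:
            break
        top = _select_members(round_hits, max_copies)
        members = [
            SeqRecord(f"{fid}|m{i}", hit_sequence(index.records, h, flank)[0])
            for i, h in enumerate(top)
        ]
        msa = build_msa(members, scoring)
        cons_full = supported_consensus(msa)
        det = detect_ltr_pair(
            cons_full,
            min_ltr=min_ltr,
            max_ltr=max_ltr,
            min_identity=min_ltr_identity,
            search_depth=flank + max_ltr + 100,
            scoring=scoring,
        )
        if det is None:
            cons = cons_full
            prev_dims = None
            continue
        s5, e5 = det.ltr5
        s3, e3 = det.ltr3
        s5, s3, e5, e3, tsd_seqs = _refine_boundaries_by_tsd(
            [m.residues for m in members], cons_full, s5, e5, s3, e3, scoring=scoring
        )
        if not (0 <= s5 < e5 <= s3 < e3 <= len(cons_full)):
            cons = cons_full
            prev_dims = None
            continue
        elem = cons_full[s5:e3]
        L = e5 - s5
        part = Partition(
            ltr5=(0, L), internal=(L, s3 - s5), ltr3=(s3 - s5, len(elem))
        )
        tsd_len = None
        if tsd_seqs:
            tsd_len = Counter(len(t) for t in tsd_seqs).most_common(1)[0][0]
        best = FamilyModel(fid, elem, partition=part, tsd_length=tsd_len)
        dims = (len(elem), L)
        if prev_dims is not None and all(
            abs(a - b) <= 2 for a, b in zip(dims, prev_dims)
        ):
            return best
        prev_dims = dims
        cons = elem
    if best is not None:
        best.flags.append("unconverged")
        return best
    model = FamilyModel(fid, cons)
    model.flags.append("no_termini")
    return model


def _select_members(hits, max_copies: int, min_coverage: float = 0.6):
    """Choose the copies whose alignment backs the consensus rebuild.

    Prefers hits covering most of the current consensus (partial copies
    such as solo LTRs all stack on one LTR and would push genuine terminal
    columns over the gap-majority threshold); falls back to the raw score
    ranking when fewer than two near-full-length hits exist.
    """
    ranked = sorted(hits, key=lambda h: (-h.score, h.seq_id, h.start))
    full = [h for h in ranked if h.query_coverage >= min_coverage]
    if len(full) >= 2:
        return full[:max_copies]
    return ranked[:max_copies]


def _refine_boundaries_by_tsd(
    member_windows: list[str],
    cons_full: str,
    s5: int,
    e5: int,
    s3: int,
    e3: int,
    slack: int = 8,
    scoring: ScoringScheme = DEFAULT_SCORING,
):
    """Nudge element boundaries so that member copies show exact 4-6 bp TSDs.

    Each member window is re-anchored by locally aligning the candidate
    element consensus to it; trimmed alignment termini are compensated via
    the query offsets, so a copy whose edge base mutated still projects to
    the right position.  Returns possibly adjusted (s5, s3, e5, e3) plus
    the member TSD sequences at the chosen boundaries.  A start shift moves
    both LTR unit starts; an end shift stretches both LTR unit ends,
    preserving the repeat relation.
    """
    from .align import local_align
    from .structure import detect_tsd

    elem = cons_full[s5:e3]
    ests: list[tuple[str, int, int]] = []
    for w in member_windows:
        aln = local_align(elem, w, scoring)
        if aln.is_empty or (aln.a_end - aln.a_start) < 0.5 * len(elem):
            continue  # partial member (e.g. a solo LTR): no boundary vote
        est_s = aln.b_start - aln.a_start
        est_e = aln.b_end + (len(elem) - aln.a_end)
        ests.append((w, est_s, est_e))

    def member_tsds(a5, a3):
        found = []
        for w, est_s, est_e in ests:
            ms, me = est_s + a5, est_e + a3
            if ms < 4 or me > len(w) - 4 or me - ms < 10:
                continue
            tsd = detect_tsd(w, ms, me)
            if tsd is not None:
                found.append(tsd)
        return found

    candidates = []
    for a5 in range(-slack, slack + 1):
        for a3 in range(-slack, slack + 1):
            if s5 + a5 < 0 or e3 + a3 > len(cons_full) or (e3 + a3) - (s5 + a5) < 20:
                continue
            tsds = member_tsds(a5, a3)
            # Real TSDs are target-derived and differ between copies, while
            # an element-internal near-terminal repeat produces the SAME
            # fake duplication in every copy; cap the contribution of any
            # one sequence so such coincidences cannot outvote the truth.
            # A boundary overshooting into the TSD still matches a shorter
            # duplication, so longer total duplication also outranks a
            # larger raw member count.
            div_score = sum(
                len(t) * min(c, 2) for t, c in Counter(tsds).items()
            )
            candidates.append(
                (
                    -div_score,
                    -len(tsds),
                    abs(a5) + abs(a3),
                    a5,
                    a3,
                    tsds,
                )
            )
    candidates.sort(key=lambda c: c[:5])
    _, neg_count, _, a5, a3, tsds = candidates[0]
    if neg_count == 0:  # no TSD support anywhere: keep alignment boundaries
        return s5, s3, e5, e3, []
    return s5 + a5, s3 + a5, e5 + a3, e3 + a3, tsds
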