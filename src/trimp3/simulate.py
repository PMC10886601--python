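"""Synthetic genomes with planted TRIM/TRIMp3 families and a full truth table.

The generator builds ancestral elements with the canonical TRIM anatomy —
two identical LTRs flanking a short internal region that starts with a PBS
complementary to a chosen tRNA (3'-end or anticodon-loop mode) and ends
with a purine-rich PPT — optionally embedding a pol III promoter (tRNA-type
box A/box B or 5S-type box A/IE/box C) in the LTRs.  Copies are planted in
an i.i.d. random background with per-copy substitutions and short indels,
flanked by exact target site duplications; a configurable fraction of
copies is collapsed to solo LTRs (LTR-LTR recombination), which keep the
original TSD pair.

Everything is driven by a single seeded generator: the same seed yields the
same genome bytes and truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .promoter import FiveSMotifs, default_5s_motifs
from .seqio import SeqRecord, TrnaRecord, revcomp
from .structure import ANTICODON_LOOP

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


#: (name, has_intron) of the default synthetic tRNA library
DEFAULT_TRNAS = [
    ("tRNA-Lys-CTT", False),
    ("tRNA-Leu-CAA", False),
    ("tRNA-His-GTG", False),
    ("tRNA-Trp-CCA", False),
    ("tRNA-Thr-AGT", False),
    ("tRNA-Tyr-GTA", True),
    ("tRNA-Ile-AAT", True),
    ("tRNA-iMet-CAT", True),
]

#: intron insertion point (just downstream of the anticodon) and length
_INTRON_AT = 38
_INTRON_LEN = 14
_TRNA_LEN = 72  # spliced length


def make_trna_library(
    seed: int, trnas: Sequence[tuple[str, bool]] = tuple(DEFAULT_TRNAS)
) -> list[TrnaRecord]:
    """A synthetic tRNA library with the conventional anticodon-loop layout.

    Sequences are random 72-mers (spliced length); intron-containing tRNAs
    carry a 14 nt intron inserted just downstream of the anticodon, with the
    interval recorded in the description the way genomic tRNA dumps annotate
    it.  Only the features the pipeline relies on are emulated: anticodon
    loop position, intron placement, and the mature CCA terminus.
    """
    rng = np.random.default_rng(seed)
    out = []
    for name, has_intron in trnas:
        spliced = _rand_seq(rng, _TRNA_LEN)
        if has_intron:
            intron = _rand_seq(rng, _INTRON_LEN)
            unspliced = spliced[:_INTRON_AT] + intron + spliced[_INTRON_AT:]
            desc = f"intron={_INTRON_AT}-{_INTRON_AT + _INTRON_LEN}"
            out.append(
                TrnaRecord(name, unspliced, desc, (_INTRON_AT, _INTRON_AT + _INTRON_LEN))
            )
        else:
            out.append(TrnaRecord(name, spliced))
    return out


@dataclass
class FamilySpec:
    """Parameters of one planted family (ranges follow observed TRIM anatomy)."""

    family_id: str
    ltr_len: int = 150
    internal_len: int = 200
    promoter: str = "none"  # none | tRNA_type2 | fiveS_type1
    pbs_mode: str = "three_prime_end"  # three_prime_end | anticodon_loop
    pbs_trna_id: Optional[str] = None
    tsd_len: int = 5
    copy_count: int = 10
    divergence: float = 0.0
    indel_prob: Optional[float] = None  # default: 0.2 x divergence
    solo_fraction: float = 0.0
    pbs_len: int = 12

    def __post_init__(self) -> None:
        if not 80 <= self.ltr_len <= 400:
            raise ValueError("ltr_len must be in [80, 400]")
        if not 50 <= self.internal_len <= 700:
            raise ValueError("internal_len must be in [50, 700]")
        if not 4 <= self.tsd_len <= 6:
            raise ValueError("tsd_len must be in [4, 6]")
        if self.promoter not in ("none", "tRNA_type2", "fiveS_type1"):
            raise ValueError(f"unknown promoter type {self.promoter!r}")
        if self.pbs_mode not in ("three_prime_end", "anticodon_loop"):
            raise ValueError(f"unknown pbs mode {self.pbs_mode!r}")
        for p in (self.divergence, self.solo_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.indel_prob is None:
            self.indel_prob = 0.2 * self.divergence


def _instantiate_iupac(pattern: str, rng: np.random.Generator) -> str:
    from .promoter import IUPAC_SETS

    return "".join(
        c if c in "ACGT" else IUPAC_SETS[c][rng.integers(len(IUPAC_SETS[c]))]
        for c in pattern
    )


def make_family(
    spec: FamilySpec,
    trna_library: Sequence[TrnaRecord],
    rng: np.random.Generator,
    motifs: Optional[FiveSMotifs] = None,
) -> tuple[str, dict]:
    """Build the ancestral element for a family spec.

    Returns ``(element, meta)`` where the element is LTR + internal + LTR
    (both LTRs identical) and ``meta`` records where every planted feature
    sits (promoter boxes, PBS, PPT) for truth-table checks.
    """
    meta: dict = {"ltr_len": spec.ltr_len, "internal_len": spec.internal_len}
    ltr = list(_rand_seq(rng, spec.ltr_len))

    if spec.promoter == "tRNA_type2":
        gap = int(rng.integers(2, 13))
        span_a = 5 + gap + 3
        b_rel_min = max(20, span_a + 2)
        a_max = spec.ltr_len - (b_rel_min + 5) - 2
        if a_max < 2:
            raise ValueError("promoter boxes cannot fit in ltr_len")
        a0 = int(rng.integers(2, min(a_max, 40) + 1))
        b_rel_max = min(80, spec.ltr_len - a0 - 5)
        b0 = a0 + int(rng.integers(b_rel_min, b_rel_max + 1))
        box_a = _instantiate_iupac("TRGCY", rng)
        ygg = _instantiate_iupac("YGG", rng)
        ltr[a0 : a0 + 5] = box_a
        ltr[a0 + 5 + gap : a0 + 8 + gap] = ygg
        ltr[b0 : b0 + 5] = "GGTTC"
        meta["boxes"] = {"box_a": a0, "box_a_gap": gap, "box_b": b0}
    elif spec.promoter == "fiveS_type1":
        m = motifs or default_5s_motifs()
        g1 = int(rng.integers(m.gap_a_ie[0], m.gap_a_ie[1] + 1))
        g2 = int(rng.integers(m.gap_ie_c[0], m.gap_ie_c[1] + 1))
        span = len(m.box_a) + g1 + len(m.ie) + g2 + len(m.box_c)
        if spec.ltr_len < span + 4:
            raise ValueError("promoter boxes cannot fit in ltr_len")
        a0 = int(rng.integers(2, spec.ltr_len - span - 1))
        pos = a0
        ltr[pos : pos + len(m.box_a)] = m.box_a
        pos += len(m.box_a) + g1
        ltr[pos : pos + len(m.ie)] = m.ie
        ie0 = pos
        pos += len(m.ie) + g2
        ltr[pos : pos + len(m.box_c)] = m.box_c
        meta["boxes"] = {"box_a": a0, "ie": ie0, "box_c": pos}
    ltr_seq = "".join(ltr)

    by_id = {t.id: t for t in trna_library}
    internal = list(_rand_seq(rng, spec.internal_len))
    trna = None
    if spec.pbs_trna_id is not None:
        trna = by_id[spec.pbs_trna_id]
    elif trna_library:
        trna = trna_library[int(rng.integers(len(trna_library)))]
    if trna is not None:
        if spec.pbs_mode == "three_prime_end":
            pbs = revcomp(trna.mature[-spec.pbs_len :])
        else:
            lo = ANTICODON_LOOP[1] - max(spec.pbs_len, 16)
            pbs = revcomp(trna.spliced[lo : ANTICODON_LOOP[1]])
        p0 = int(rng.integers(0, 6))
        if spec.internal_len < p0 + len(pbs) + 16:
            raise ValueError("internal region too short for PBS + PPT")
        internal[p0 : p0 + len(pbs)] = pbs
        meta["pbs"] = {"trna": trna.id, "mode": spec.pbs_mode, "offset": p0,
                       "length": len(pbs)}
    ppt = "".join("AG"[int(rng.integers(2))] for _ in range(12))
    ppt_gap = int(rng.integers(0, 3))
    e = spec.internal_len - ppt_gap
    internal[e - 12 : e] = ppt
    meta["ppt"] = {"start": e - 12, "end": e}
    internal_seq = "".join(internal)

    return ltr_seq + internal_seq + ltr_seq, meta


def mutate(
    seq: str, divergence: float, indel_prob: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Apply i.i.d. substitutions and short (1-3 nt) indels to a sequence."""
    out: list[str] = []
    n_sub = n_indel = 0
    i, n = 0, len(seq)
    while i < n:
        r = rng.random()
        if r < indel_prob:
            n_indel += 1
            length = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                i += length  # deletion of 1-3 nt
            else:
                out.append(_rand_seq(rng, length))  # insertion before this base
                out.append(seq[i])
                i += 1
        elif r < indel_prob + divergence:
            n_sub += 1
            c = seq[i]
            choices = "ACGT".replace(c, "") if c in "ACGT" else "ACGT"
            out.append(choices[int(rng.integers(len(choices)))])
            i += 1
        else:
            out.append(seq[i])
            i += 1
    return "".join(out), n_sub, n_indel


@dataclass
class TruthTable:
    """Everything the generator planted: per-copy rows plus family ancestors."""

    copies: pd.DataFrame
    ancestors: dict[str, str]
    family_meta: dict[str, dict]
    trna_library: list[TrnaRecord] = field(default_factory=list)

    def family_rows(self, family_id: str) -> pd.DataFrame:
        return self.copies[self.copies.family_id == family_id]


def plant_elements(
    genome_len: int,
    families: Sequence[FamilySpec],
    seed: int,
    trna_library: Optional[Sequence[TrnaRecord]] = None,
    gc: float = 0.5,
    margin: int = 700,
    min_gap: int = 200,
    seq_id: str = "chr1",
    motifs: Optional[FiveSMotifs] = None,
) -> tuple[SeqRecord, TruthTable]:
    """Plant family copies in a random background genome.

    The number of solo LTRs per family is ``round(solo_fraction *
    copy_count)`` (which copies become solos is drawn at random); solos keep
    the full TSD pair.  Elements are placed non-overlapping, at least
    ``min_gap`` apart and ``margin`` away from the sequence ends.  Raises
    when the total planted length exceeds half the genome or placement
    fails repeatedly.
    """
    rng = np.random.default_rng(seed)
    if trna_library is None:
        trna_library = make_trna_library(int(rng.integers(2**31)))
    ancestors: dict[str, str] = {}
    family_meta: dict[str, dict] = {}
    planned: list[tuple[str, int, str, bool, str, int, int]] = []
    total_planted = 0
    for spec in families:
        anc, meta = make_family(spec, trna_library, rng, motifs)
        ancestors[spec.family_id] = anc
        family_meta[spec.family_id] = meta | {"spec": spec}
        n_solo = int(round(spec.solo_fraction * spec.copy_count))
        solo_idx = set(rng.permutation(spec.copy_count)[:n_solo].tolist())
        ltr_anc = anc[: spec.ltr_len]
        for ci in range(spec.copy_count):
            src = ltr_anc if ci in solo_idx else anc
            mut, n_sub, n_indel = mutate(src, spec.divergence, spec.indel_prob, rng)
            planned.append(
                (spec.family_id, ci, mut, ci in solo_idx, "", n_sub, n_indel)
            )
            total_planted += len(mut) + 2 * spec.tsd_len
    if total_planted >= 0.5 * genome_len:
        raise ValueError("total planted length exceeds half the genome")

    background = np.frombuffer(_rand_seq(rng, genome_len).encode(), dtype=np.uint8).copy()
    placed: list[tuple[int, int]] = []
    rows = []
    spec_by_id = {s.family_id: s for s in families}
    for family_id, ci, mut, is_solo, _, n_sub, n_indel in planned:
        spec = spec_by_id[family_id]
        tsd = _rand_seq(rng, spec.tsd_len)
        need = len(mut) + 2 * spec.tsd_len
        pos = None
        for _attempt in range(1000):
            cand = int(rng.integers(margin, genome_len - margin - need))
            lo, hi = cand - min_gap, cand + need + min_gap
            if all(hi <= s or lo >= e for s, e in placed):
                pos = cand
                break
        if pos is None:
            raise ValueError("could not place element without overlap")
        placed.append((pos, pos + need))
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = mut if strand == "+" else revcomp(mut)
        block = (tsd + inserted + tsd).encode()
        background[pos : pos + need] = np.frombuffer(block, dtype=np.uint8)
        start = pos + spec.tsd_len
        rows.append(
            {
                "family_id": family_id,
                "copy_id": ci,
                "seq_id": seq_id,
                "start": start,
                "end": start + len(mut),
                "strand": strand,
                "is_solo": is_solo,
                "tsd": tsd,
                "n_sub": n_sub,
                "n_indel": n_indel,
            }
        )
    copies = pd.DataFrame(rows).sort_values(["seq_id", "start"]).reset_index(drop=True)
    genome = SeqRecord(seq_id, background.tobytes().decode())
    return genome, TruthTable(copies, ancestors, family_meta, list(trna_library))


def write_truth_tsv(truth: TruthTable, path) -> None:
    truth.copies.to_csv(path, sep="\t", index=False)


#: characteristic (ltr_len, internal_len, promoter, pbs tRNA, tsd) of named
#: TRIM families spanning the reported size range: the compact plant-type
#: Helenus (120 bp LTRs / 85 bp internal), the long hymenopteran Helenus
#: families (321-323 bp LTRs, 621 bp internal, 1263 bp total), the shortest
#: Helenus (311 bp total) and the two nemertean 5S-type Ajax families
#: (421 / 434 bp total).
DEMO_FAMILY_DIMENSIONS = {
    "Helenus-1_SyUm-like": (321, 621, "tRNA_type2", "tRNA-Lys-CTT", 4),
    "Helenus-1_SyJa-like": (323, 400, "tRNA_type2", "tRNA-Leu-CAA", 4),
    "Helenus-1_SMo-like": (120, 85, "tRNA_type2", "tRNA-Lys-CTT", 5),
    "Helenus-min-like": (100, 111, "tRNA_type2", "tRNA-iMet-CAT", 5),
    "Ajax-1_LiLo-like": (150, 121, "fiveS_type1", "tRNA-Leu-CAA", 5),
    "Ajax-1_NGe-like": (150, 134, "fiveS_type1", "tRNA-Leu-CAA", 5),
}


def demo_library(seed: int = 0) -> list[tuple[str, str]]:
    """Synthetic stand-in consensus elements for named TRIM families.

    These are generated sequences with the characteristic LTR/internal
    dimensions, promoter type and PBS of the corresponding families — NOT
    the real consensus sequences (which live in curated repeat databases).
    They exercise the structural annotators on realistically proportioned
    elements.  Returns ``(family_id, element)`` pairs.
    """
    rng = np.random.default_rng(seed)
    lib = make_trna_library(int(rng.integers(2**31)))
    out = []
    for fid, (ltr, internal, promoter, trna, tsd) in DEMO_FAMILY_DIMENSIONS.items():
        spec = FamilySpec(
            fid, ltr_len=ltr, internal_len=internal, promoter=promoter,
            pbs_trna_id=trna, tsd_len=tsd,
        )
        elem, _ = make_family(spec, lib, rng)
        out.append((fid, elem))
    return out
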