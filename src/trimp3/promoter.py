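"""RNA polymerase III internal promoter detection and TRIM classification.

Two internal promoter architectures are scanned for inside LTR sequences:

* the tRNA-type (type 2) bipartite promoter — box A, matching the IUPAC
  pattern ``TRGCY`` followed 2-12 nt later by ``YGG``, and box B, the
  conserved ``GGTTC``, 20-80 nt downstream of box A;
* the 5S-type (type 1) internal control region — box A, intermediate
  element (IE) and box C in order, with patterns and spacing read from a
  plain-text config (see ``data/pol3_5s_motifs.yaml``).

Families whose LTRs carry a tRNA-type promoter are classified TRIMp3_tRNA,
families with a 5S-type promoter TRIMp3_5S, and canonical TRIMs without a
small-RNA-derived promoter TRIMp2.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

BOX_A_PART1 = "TRGCY"
BOX_A_PART2 = "YGG"
BOX_B = "GGTTC"


def iupac_mismatches(pattern: str, text: str) -> int:
    """Number of positions of ``text`` not covered by the IUPAC ``pattern``."""
    if len(text) != len(pattern):
        raise ValueError("pattern/text length mismatch")
    return sum(1 for p, t in zip(pattern, text) if t not in IUPAC_SETS[p])


@dataclass(frozen=True)
class Box:
    interval: tuple[int, int]
    matched: str
    mismatches: int = 0


@dataclass
class PromoterAnnotation:
    """Result of a promoter scan on one LTR sequence."""

    promoter_type: str  # "tRNA_type2" | "fiveS_type1" | "none"
    box_a: Optional[Box] = None
    box_b: Optional[Box] = None
    ie: Optional[Box] = None
    box_c: Optional[Box] = None
    score: int = 0


def scan_trna_promoter(
    ltr_seq: str,
    max_boxA_mismatch: int = 1,
    boxB_exact: bool = True,
    spacing: tuple[int, int] = (20, 80),
    boxA_gap: tuple[int, int] = (2, 12),
) -> PromoterAnnotation:
    """Scan an LTR for the tRNA-type (pol III type-2) promoter.

    Box A is the bipartite ``TRGCY`` + ``YGG`` pattern with at most
    ``max_boxA_mismatch`` mismatches across both parts; box B is ``GGTTC``
    (exact by default) starting ``spacing`` nt downstream of the box A
    start.  The earliest qualifying pair wins.  The score counts matched
    motif positions.
    """
    n = len(ltr_seq)
    p1, p2 = len(BOX_A_PART1), len(BOX_A_PART2)
    for a in range(0, n - p1 + 1):
        m1 = iupac_mismatches(BOX_A_PART1, ltr_seq[a : a + p1])
        if m1 > max_boxA_mismatch:
            continue
        for gap in range(boxA_gap[0], boxA_gap[1] + 1):
            y = a + p1 + gap
            if y + p2 > n:
                break
            m2 = iupac_mismatches(BOX_A_PART2, ltr_seq[y : y + p2])
            if m1 + m2 > max_boxA_mismatch:
                continue
            for b in range(a + spacing[0], min(a + spacing[1], n - len(BOX_B)) + 1):
                mb = iupac_mismatches(BOX_B, ltr_seq[b : b + len(BOX_B)])
                if (boxB_exact and mb > 0) or mb > 1:
                    continue
                if b < y + p2:
                    continue
                score = (p1 + p2 - m1 - m2) + (len(BOX_B) - mb)
                return PromoterAnnotation(
                    "tRNA_type2",
                    box_a=Box((a, y + p2), ltr_seq[a : y + p2], m1 + m2),
                    box_b=Box((b, b + len(BOX_B)), ltr_seq[b : b + len(BOX_B)], mb),
                    score=score,
                )
    return PromoterAnnotation("none")


@dataclass(frozen=True)
class FiveSMotifs:
    """5S internal-control-region motif strings and spacing ranges."""

    box_a: str
    ie: str
    box_c: str
    gap_a_ie: tuple[int, int]
    gap_ie_c: tuple[int, int]
    reference: str = ""
    reference_id: str = ""


def load_5s_motifs(path=None) -> FiveSMotifs:
    """Load 5S ICR motifs from a YAML config (bundled defaults when None)."""
    if path is None:
        text = (
            resources.files("trimp3").joinpath("data/pol3_5s_motifs.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    ref = cfg["reference"].upper()
    return FiveSMotifs(
        box_a=ref[cfg["box_a"][0] : cfg["box_a"][1]],
        ie=ref[cfg["ie"][0] : cfg["ie"][1]],
        box_c=ref[cfg["box_c"][0] : cfg["box_c"][1]],
        gap_a_ie=tuple(cfg["gap_a_ie"]),
        gap_ie_c=tuple(cfg["gap_ie_c"]),
        reference=ref,
        reference_id=cfg.get("reference_id", ""),
    )


_DEFAULT_5S: Optional[FiveSMotifs] = None


def default_5s_motifs() -> FiveSMotifs:
    global _DEFAULT_5S
    if _DEFAULT_5S is None:
        _DEFAULT_5S = load_5s_motifs()
    return _DEFAULT_5S


def scan_5s_promoter(
    ltr_seq: str,
    max_mismatch_per_box: int = 1,
    motifs: Optional[FiveSMotifs] = None,
) -> PromoterAnnotation:
    """Scan an LTR for the 5S-type (pol III type-1) internal control region.

    The three motifs (box A, IE, box C) must occur in order with the
    configured spacing, each with at most ``max_mismatch_per_box``
    mismatches.  The earliest qualifying triple wins.
    """
    m = motifs or default_5s_motifs()
    n = len(ltr_seq)
    la, li, lc = len(m.box_a), len(m.ie), len(m.box_c)
    for a in range(0, n - la + 1):
        ma = iupac_mismatches(m.box_a, ltr_seq[a : a + la])
        if ma > max_mismatch_per_box:
            continue
        a_end = a + la
        for i in range(a_end + m.gap_a_ie[0], min(a_end + m.gap_a_ie[1], n - li) + 1):
            mi = iupac_mismatches(m.ie, ltr_seq[i : i + li])
            if mi > max_mismatch_per_box:
                continue
            i_end = i + li
            for c in range(
                i_end + m.gap_ie_c[0], min(i_end + m.gap_ie_c[1], n - lc) + 1
            ):
                mc = iupac_mismatches(m.box_c, ltr_seq[c : c + lc])
                if mc > max_mismatch_per_box:
                    continue
                score = (la - ma) + (li - mi) + (lc - mc)
                return PromoterAnnotation(
                    "fiveS_type1",
                    box_a=Box((a, a_end), ltr_seq[a:a_end], ma),
                    ie=Box((i, i_end), ltr_seq[i:i_end], mi),
                    box_c=Box((c, c + lc), ltr_seq[c : c + lc], mc),
                    score=score,
                )
    return PromoterAnnotation("none")


#: soft length limits for the TRIM label
TRIM_MAX_LEN = 1000
TRIM_HARD_MAX_LEN = 1300


def classify_family(
    family,
    motifs: Optional[FiveSMotifs] = None,
    max_boxA_mismatch: int = 1,
    max_mismatch_per_box: int = 1,
) -> str:
    """Classify a partitioned family as TRIMp2, TRIMp3_tRNA or TRIMp3_5S.

    Both LTR consensi are scanned for both promoter architectures; a
    tRNA-type promoter in either LTR yields TRIMp3_tRNA and a 5S-type
    promoter TRIMp3_5S.  If both architectures are found the higher score
    wins (a tie is left unclassified with an ``ambiguous_promoter`` flag);
    with neither the family is a canonical TRIMp2.  Families of 1000-1300
    bp get a ``long_trim`` flag and longer ones a ``not_trim_length`` flag
    (the classification is then withheld).  The class is stored on the
    family and returned.
    """
    if family.partition is None:
        raise ValueError(f"family {family.family_id!r} is not partitioned")
    total = len(family.consensus)
    best_trna: Optional[PromoterAnnotation] = None
    best_5s: Optional[PromoterAnnotation] = None
    for ltr in (family.ltr_consensus, family.ltr3_consensus):
        if len(ltr) >= 13:
            ann = scan_trna_promoter(ltr, max_boxA_mismatch=max_boxA_mismatch)
            if ann.promoter_type != "none" and (
                best_trna is None or ann.score > best_trna.score
            ):
                best_trna = ann
        if len(ltr) >= 30:
            ann = scan_5s_promoter(
                ltr, max_mismatch_per_box=max_mismatch_per_box, motifs=motifs
            )
            if ann.promoter_type != "none" and (
                best_5s is None or ann.score > best_5s.score
            ):
                best_5s = ann

    if total >= TRIM_HARD_MAX_LEN:
        family.flags.append("not_trim_length")
        family.family_class = "unclassified"
        return family.family_class
    if total >= TRIM_MAX_LEN:
        family.flags.append("long_trim")

    if best_trna and best_5s:
        if best_trna.score > best_5s.score:
            cls = "TRIMp3_tRNA"
        elif best_5s.score > best_trna.score:
            cls = "TRIMp3_5S"
        else:
            family.flags.append("ambiguous_promoter")
            cls = "unclassified"
    elif best_trna:
        cls = "TRIMp3_tRNA"
    elif best_5s:
        cls = "TRIMp3_5S"
    else:
        cls = "TRIMp2"
    family.family_class = cls
    return cls
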