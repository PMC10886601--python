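"""Full-length copy counting.

A genome hit of the LTR (or internal) consensus counts as full length when
its aligned length exceeds 90% of that consensus length AND its identity
exceeds 90% — both strictly, reading "longer than 90%" and "over 90%"
literally.  LTR and internal portions are tallied independently, so a
family's LTR count can exceed twice its internal count when solo LTRs are
present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence


@dataclass(frozen=True)
class CopyCount:
    family_id: str
    ltr_full: int
    internal_full: int
    solo_ltr: int
    length_frac: float
    identity_min: float


def _count(hits, consensus_len: int, length_frac: float, identity_min: float) -> int:
    n = 0
    for h in hits:
        aligned = h.q_end - h.q_start
        if aligned > length_frac * consensus_len and h.identity > identity_min:
            n += 1
    return n


def count_full_length(
    ltr_hits,
    internal_hits,
    family,
    length_frac: float = 0.9,
    identity_min: float = 0.9,
    solo_calls: Optional[Sequence] = None,
) -> CopyCount:
    """Count full-length LTR and internal copies of a partitioned family.

    ``ltr_hits`` and ``internal_hits`` come from scanning the genome with
    the family's LTR consensus and internal consensus separately.  Both
    thresholds are strict: a hit at identity exactly ``identity_min`` is
    excluded.  Solo-LTR calls (from structural annotation) are reported
    alongside.
    """
    if family.partition is None:
        raise ValueError(f"family {family.family_id!r} is not partitioned")
    ltr_len = family.partition.ltr_length
    internal_len = family.partition.internal_length
    return CopyCount(
        family.family_id,
        _count(ltr_hits, ltr_len, length_frac, identity_min),
        _count(internal_hits, internal_len, length_frac, identity_min),
        len(solo_calls) if solo_calls is not None else 0,
        length_frac,
        identity_min,
    )


def write_counts_tsv(counts: Sequence[CopyCount], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "family_id\tltr_full\tinternal_full\tsolo_ltr\tlength_frac\tidentity_min\n"
        )
        for c in counts:
            fh.write(
                f"{c.family_id}\t{c.ltr_full}\t{c.internal_full}\t{c.solo_ltr}"
                f"\t{c.length_frac}\t{c.identity_min}\n"
            )
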