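"""Sequence I/O and coordinate conventions.

All pipeline stages exchange plain :class:`SeqRecord` objects and 0-based
half-open :class:`GenomeInterval` coordinates.  GFF3 output converts to the
1-based inclusive convention of that format.  FASTA parsing goes through
Bio.SeqIO; records are upper-cased and RNA ``U`` is mapped to DNA ``T`` on
input.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_DNA = set("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTNRYSWKMBDHVacgtnryswkmbdhv",
    "TGCANYRSWMKVHDBtgcanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-ambiguous) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence.

    ``residues`` is an upper-case string over the IUPAC DNA alphabet;
    ``id`` is a whitespace-free token unique within a file.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or re.search(r"\s", self.id):
            raise ValueError(f"sequence id {self.id!r} is empty or contains whitespace")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def _normalise(residues: str) -> str:
    return residues.upper().replace("U", "T")


def read_fasta(path) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Order is preserved; residues are upper-cased with U mapped to T.
    Raises on an empty file and on duplicate ids.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, _normalise(str(rec.seq)), desc))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path, wrap: int = 60) -> None:
    """Write records as FASTA with ``wrap``-column line wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


_INTRON_RE = re.compile(r"intron=(\d+)-(\d+)")


@dataclass(frozen=True)
class TrnaRecord:
    """A genomic tRNA sequence with an optional intron annotation.

    The intron interval (0-based half-open, on the unspliced sequence) is
    parsed from an ``intron=<start>-<end>`` token in the FASTA description.
    The mature 3' terminus is the spliced sequence with ``CCA`` appended when
    not already present (CCA addition is post-transcriptional, and primer
    binding sites pair with the mature terminus).
    """

    id: str
    residues: str
    description: str = ""
    intron: Optional[tuple[int, int]] = None

    @property
    def spliced(self) -> str:
        if self.intron is None:
            return self.residues
        s, e = self.intron
        return self.residues[:s] + self.residues[e:]

    @property
    def mature(self) -> str:
        """Spliced sequence with the post-transcriptional CCA terminus."""
        s = self.spliced
        return s if s.endswith("CCA") else s + "CCA"


def read_trna_library(path) -> list[TrnaRecord]:
    """Read a tRNA FASTA library, parsing intron annotations from descriptions."""
    out: list[TrnaRecord] = []
    for rec in read_fasta(path):
        intron = None
        m = _INTRON_RE.search(rec.description)
        if m:
            s, e = int(m.group(1)), int(m.group(2))
            if not (0 <= s < e <= len(rec.residues)):
                raise ValueError(
                    f"intron interval {s}-{e} outside tRNA {rec.id!r} "
                    f"(length {len(rec.residues)})"
                )
            intron = (s, e)
        out.append(TrnaRecord(rec.id, rec.residues, rec.description, intron))
    return out


def read_family_library(path):
    """Read a repeat family FASTA library into :class:`~trimp3.consensus.FamilyModel`s.

    Two storage conventions are supported and may be mixed in one file:

    * a single record holding a full-length consensus, and
    * the split convention where family ``X`` is stored as record ``X``
      (the LTR) plus record ``X-I`` (the internal portion); the full-length
      consensus is reconstructed as LTR + internal + LTR and the partition
      recorded.
    """
    from .consensus import FamilyModel, Partition

    records = read_fasta(path)
    by_id = {r.id: r for r in records}
    families: list = []
    consumed: set[str] = set()
    for rec in records:
        if rec.id in consumed:
            continue
        if rec.id.endswith("-I"):
            base = rec.id[:-2]
            if base not in by_id:
                raise ValueError(
                    f"internal record {rec.id!r} present without LTR record {base!r}"
                )
            continue  # handled when the LTR record is reached
        internal_id = rec.id + "-I"
        if internal_id in by_id:
            ltr = rec.residues
            internal = by_id[internal_id].residues
            consensus = ltr + internal + ltr
            part = Partition(
                ltr5=(0, len(ltr)),
                internal=(len(ltr), len(ltr) + len(internal)),
                ltr3=(len(ltr) + len(internal), len(consensus)),
            )
            families.append(FamilyModel(rec.id, consensus, partition=part))
            consumed.update({rec.id, internal_id})
        else:
            families.append(FamilyModel(rec.id, rec.residues))
            consumed.add(rec.id)
    return families


#: GFF3 feature types used for structural annotation output.
GFF_ELEMENT = "LTR_retrotransposon"
GFF_LTR = "long_terminal_repeat"
GFF_TSD = "target_site_duplication"
GFF_PBS = "primer_binding_site"
GFF_PPT = "RR_tract"


@dataclass
class GffFeature:
    interval: GenomeInterval
    ftype: str
    attributes: dict = field(default_factory=dict)
    source: str = "trimp3"
    score: Optional[float] = None


def write_gff3(features: Sequence[GffFeature], path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            score = "." if f.score is None else f"{f.score:g}"
            fh.write(
                "\t".join(
                    [
                        f.interval.seq_id,
                        f.source,
                        f.ftype,
                        str(f.interval.start + 1),
                        str(f.interval.end),
                        score,
                        f.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3_intervals(path) -> list[tuple[str, GenomeInterval]]:
    """Parse a GFF3 file back into (feature type, interval) pairs."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append(
                (
                    cols[2],
                    GenomeInterval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]),
                )
            )
    return out
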