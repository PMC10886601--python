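"""Seeded genome scanning for repeat copies and 75/75 family clustering.

Scanning is seed-and-extend: exact k-mer seed matches between the family
consensus and the genome (both strands) are grouped into candidate loci,
each locus is verified with an optimal local alignment of the consensus
against the surrounding genomic window, and overlapping hits of the same
family are merged.  A :class:`GenomeIndex` can be built once and reused
across many families scanned against the same genome.

Clustering reproduces the BLASTCLUST-style single-linkage rule used for
repeat library construction: two sequences are linked when a local
alignment covers at least ``min_coverage`` of the shorter sequence at
``min_identity`` or better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .align import DEFAULT_SCORING, ScoringScheme, encode, local_align
from .seqio import SeqRecord, revcomp


@dataclass(frozen=True)
class Hit:
    """One local alignment of a family consensus against a genome.

    ``start``/``end`` are 0-based half-open genome coordinates of the
    aligned region.  Minus-strand hits were found on the reverse complement
    of the genome; their coordinates refer to the forward strand.
    ``query_coverage`` is the aligned fraction of the consensus length.
    """

    family_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    identity: float
    query_coverage: float
    score: int
    q_start: int = 0
    q_end: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def hit_sequence(genome: dict[str, str], hit: Hit, flank: int = 0) -> tuple[str, int, int]:
    """Extract the (strand-oriented) hit sequence with up to ``flank`` nt of context.

    Returns ``(sequence, left_used, right_used)`` where the ``*_used`` values
    are the flank lengths actually available (clipped at sequence ends), on
    the oriented sequence.
    """
    src = genome[hit.seq_id]
    lo = max(0, hit.start - flank)
    hi = min(len(src), hit.end + flank)
    seq = src[lo:hi]
    left, right = hit.start - lo, hi - hit.end
    if hit.strand == "-":
        return revcomp(seq), right, left
    return seq, left, right


def _kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Pack k-mers into uint64 codes; windows containing non-ACGT get code 2**63."""
    n = encoded.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    bad = np.zeros(n, dtype=bool)
    e = encoded.astype(np.uint64)
    for off in range(k):
        codes = (codes << np.uint64(2)) | (e[off : off + n] & np.uint64(3))
        bad |= encoded[off : off + n] >= 4
    codes[bad] = np.uint64(1) << np.uint64(63)
    return codes


class GenomeIndex:
    """Sorted k-mer index over both strands of a genome.

    Built once per genome; ``scan_genome`` accepts it in place of the raw
    records to avoid re-indexing when many families are scanned.
    """

    def __init__(self, genome: Sequence[SeqRecord], k: int = 11):
        self.k = k
        self.records = {rec.id: rec.residues for rec in genome}
        self._strands: list[tuple[str, str, np.ndarray, np.ndarray]] = []
        for rec in genome:
            for strand, seq in (("+", rec.residues), ("-", revcomp(rec.residues))):
                codes = _kmer_codes(encode(seq), k)
                order = np.argsort(codes, kind="stable")
                self._strands.append((rec.id, strand, codes[order], order))

    def seed_positions(self, code: np.uint64, strand_idx: int) -> np.ndarray:
        _, _, sorted_codes, order = self._strands[strand_idx]
        lo = np.searchsorted(sorted_codes, code, side="left")
        hi = np.searchsorted(sorted_codes, code, side="right")
        return order[lo:hi]


def _candidate_starts(proj: np.ndarray, tol: int = 50) -> list[tuple[int, int, int]]:
    """Group sorted projected element starts into candidate loci (lo, hi, count)."""
    groups = []
    proj = np.sort(proj)
    lo = prev = int(proj[0])
    count = 1
    for p in proj[1:]:
        p = int(p)
        if p - prev > tol:
            groups.append((lo, prev, count))
            lo, count = p, 0
        prev = p
        count += 1
    groups.append((lo, prev, count))
    return groups


def scan_genome(
    genome: Union[Sequence[SeqRecord], GenomeIndex],
    family,
    min_identity: float = 0.6,
    min_length: int = 30,
    seed_k: int = 11,
    scoring: ScoringScheme = DEFAULT_SCORING,
    min_seeds: int = 3,
) -> list[Hit]:
    """Find copies of a family consensus in a genome on both strands.

    Candidate loci are groups of co-diagonal k-mer seed matches; groups with
    fewer than ``min_seeds`` seeds are discarded before alignment (isolated
    random k-mer collisions in megabase genomes).  Hits of the same family
    overlapping more than 50% reciprocally are merged (the higher-scoring
    hit is kept); hits are sorted by sequence id and position.
    """
    consensus = family.consensus if hasattr(family, "consensus") else str(family)
    family_id = getattr(family, "family_id", "query")
    if seed_k > len(consensus):
        raise ValueError(
            f"seed_k={seed_k} exceeds consensus length {len(consensus)}"
        )
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, seed_k)
    if index.k != seed_k:
        index = GenomeIndex(list_records(index), seed_k)

    qcodes = _kmer_codes(encode(consensus), seed_k)
    valid = qcodes != (np.uint64(1) << np.uint64(63))
    qpos_all = np.nonzero(valid)[0]
    hits: list[Hit] = []
    for sidx, (seq_id, strand, _, _) in enumerate(index._strands):
        src = index.records[seq_id]
        oriented = src if strand == "+" else revcomp(src)
        proj = []
        for qp in qpos_all:
            gps = index.seed_positions(qcodes[qp], sidx)
            for gp in gps:
                proj.append(int(gp) - int(qp))
        if not proj:
            continue
        for lo, hi, count in _candidate_starts(np.asarray(proj)):
            if count < min_seeds:
                continue
            wlo = max(0, lo - 50)
            whi = min(len(oriented), hi + len(consensus) + 50)
            window = oriented[wlo:whi]
            if len(window) < min_length:
                continue
            aln = local_align(consensus, window, scoring)
            if aln.is_empty or aln.n_columns < min_length:
                continue
            if aln.identity < min_identity:
                continue
            gstart, gend = wlo + aln.b_start, wlo + aln.b_end
            if strand == "-":
                L = len(src)
                gstart, gend = L - gend, L - gstart
            hits.append(
                Hit(
                    family_id,
                    seq_id,
                    gstart,
                    gend,
                    strand,
                    aln.identity,
                    (aln.a_end - aln.a_start) / len(consensus),
                    aln.score,
                    aln.a_start,
                    aln.a_end,
                )
            )
    hits = _merge_hits(hits)
    hits.sort(key=lambda h: (h.seq_id, h.start, h.end, h.strand))
    return hits


def list_records(index: GenomeIndex) -> list[SeqRecord]:
    return [SeqRecord(i, s) for i, s in index.records.items()]


def _merge_hits(hits: list[Hit]) -> list[Hit]:
    """Merge same-family, same-strand hits overlapping >50% reciprocally.

    A hit nearly contained (>=90%) in a higher-scoring hit is also merged:
    a query with internal repeat structure (two LTRs) produces partial
    self-hits inside each full-length hit that would otherwise survive the
    reciprocal rule.
    """
    hits = sorted(hits, key=lambda h: (-h.score, h.seq_id, h.start, h.end))
    kept: list[Hit] = []
    for h in hits:
        merged = False
        for k in kept:
            if k.seq_id != h.seq_id or k.strand != h.strand:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov > 0.5 * len(h) and ov > 0.5 * len(k):
                merged = True
                break
            if ov >= 0.9 * min(len(h), len(k)):
                merged = True
                break
        if not merged:
            kept.append(h)
    return kept


# --- clustering ---------------------------------------------------------


def _shared_kmers(a: str, b: str, k: int = 8) -> int:
    ca = _kmer_codes(encode(a), k)
    cb = _kmer_codes(encode(b), k)
    return np.intersect1d(ca, cb).size


def sequences_linked(
    a: str,
    b: str,
    min_coverage: float = 0.75,
    min_identity: float = 0.75,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> bool:
    """BLASTCLUST-style predicate: alignment covers ``min_coverage`` of the
    shorter sequence at ``min_identity`` or better."""
    aln = local_align(a, b, scoring)
    if aln.is_empty:
        return False
    shorter = min(len(a), len(b))
    cov = min(aln.a_end - aln.a_start, aln.b_end - aln.b_start) / shorter
    return cov >= min_coverage and aln.identity >= min_identity


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_hits(
    sequences: Sequence[SeqRecord],
    min_coverage: float = 0.75,
    min_identity: float = 0.75,
    scoring: ScoringScheme = DEFAULT_SCORING,
    kmer_prefilter: bool = True,
) -> list[list[SeqRecord]]:
    """Single-linkage clustering of sequences under the 75/75 predicate.

    The partition is independent of input order; clusters are sorted by
    size, then by the length of their longest member, then by their
    lexicographically smallest id.  A shared-k-mer prefilter skips the
    alignment for pairs of long sequences that cannot plausibly reach the
    identity threshold; it is conservative and does not change partitions
    on realistic inputs.
    """
    if not sequences:
        raise ValueError("need at least one sequence to cluster")
    order = sorted(range(len(sequences)), key=lambda i: sequences[i].id)
    uf = _UnionFind(len(sequences))
    for oi in range(len(order)):
        for oj in range(oi + 1, len(order)):
            i, j = order[oi], order[oj]
            if uf.find(i) == uf.find(j):
                continue
            a, b = sequences[i].residues, sequences[j].residues
            if (
                kmer_prefilter
                and min(len(a), len(b)) >= 200
                and _shared_kmers(a, b) < 8
            ):
                continue
            if sequences_linked(a, b, min_coverage, min_identity, scoring):
                uf.union(i, j)
    groups: dict[int, list[SeqRecord]] = {}
    for i, rec in enumerate(sequences):
        groups.setdefault(uf.find(i), []).append(rec)
    clusters = [sorted(g, key=lambda r: r.id) for g in groups.values()]
    clusters.sort(
        key=lambda g: (-len(g), -max(len(r) for r in g), min(r.id for r in g))
    )
    return clusters


def write_hits_tsv(hits: Sequence[Hit], path) -> None:
    """Write hits as TSV: family, seq, start, end, strand, identity, coverage, score."""
    with open(path, "w") as fh:
        fh.write(
            "family_id\tseq_id\tstart\tend\tstrand\tidentity\tcoverage\tscore\n"
        )
        for h in hits:
            fh.write(
                f"{h.family_id}\t{h.seq_id}\t{h.start}\t{h.end}\t{h.strand}"
                f"\t{h.identity:.4f}\t{h.query_coverage:.4f}\t{h.score}\n"
            )
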