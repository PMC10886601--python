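"""End-to-end discovery workflow: scan, cluster, extend, annotate, classify, count.

``run_discover`` wires the stages together the way a repeat-library curator
works: seed sequences are searched against the genome, hits are clustered
at 75% coverage / 75% identity, each cluster's consensus is iteratively
extended until the element termini (LTR pair + TSD) are found, the internal
region is annotated (PBS, PPT), the LTRs are scanned for pol III promoter
motifs to classify the family (TRIMp2 / TRIMp3_tRNA / TRIMp3_5S), and
full-length LTR/internal copies and solo LTRs are counted.  All stages are
deterministic: rerunning with the same inputs and config writes
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .consensus import FamilyModel, build_msa, extend_to_termini
from .copynum import CopyCount, count_full_length, write_counts_tsv
from .phylo import bootstrap_support, write_newick
from .promoter import classify_family, load_5s_motifs
from .scan import GenomeIndex, Hit, cluster_hits, hit_sequence, scan_genome, write_hits_tsv
from .seqio import (
    GenomeInterval,
    GffFeature,
    SeqRecord,
    TrnaRecord,
    write_fasta,
    write_gff3,
    GFF_LTR,
    GFF_ELEMENT,
)
from .structure import (
    PbsCall,
    TrimAnnotation,
    detect_pbs,
    detect_ppt,
    find_solo_ltrs,
)

logger = logging.getLogger("trimp3")


def setup_logging(level: int = logging.INFO) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """All tunables of the discovery workflow (defaults follow the
    conventional repeat-library thresholds)."""

    cluster_min_coverage: float = 0.75
    cluster_min_identity: float = 0.75
    flank: int = 500
    max_rounds: int = 10
    max_copies_per_round: int = 10
    min_ltr: int = 80
    max_ltr: int = 400
    min_ltr_identity: float = 0.8
    scan_min_identity: float = 0.6
    scan_min_length: int = 30
    seed_k: int = 11
    full_length_frac: float = 0.9
    full_identity_min: float = 0.9
    min_cluster_size: int = 2
    bootstrap_n: int = 100
    seed: int = 0
    motifs_path: Optional[str] = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class FamilyResult:
    family: FamilyModel
    cluster_size: int
    annotation: Optional[TrimAnnotation] = None
    counts: Optional[CopyCount] = None
    solo_calls: list = field(default_factory=list)
    ltr_hits: list[Hit] = field(default_factory=list)
    internal_hits: list[Hit] = field(default_factory=list)


@dataclass
class DiscoverResult:
    families: list[FamilyResult]
    seed_hits: list[Hit]
    tree: Optional[object] = None


def run_discover(
    genome: Sequence[SeqRecord],
    seeds: Sequence[SeqRecord],
    trna_library: Optional[Sequence[TrnaRecord]],
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
) -> DiscoverResult:
    """Run the full discovery workflow; see the module docstring.

    When ``trna_library`` is None the PBS stage is skipped with a warning
    and every other output is produced.  With ``out_dir`` set, FASTA / GFF3
    / TSV / Newick outputs plus the provenance config are written there.
    """
    cfg = config
    motifs = load_5s_motifs(cfg.motifs_path) if cfg.motifs_path else None
    index = GenomeIndex(genome, cfg.seed_k)
    genome_list = list(genome)

    logger.info("scanning %d seed(s) against %d sequence(s)", len(seeds), len(genome_list))
    hit_seqs: list[SeqRecord] = []
    hit_by_id: dict[str, Hit] = {}
    all_hits: list[Hit] = []
    for seed in seeds:
        hits = scan_genome(
            index,
            FamilyModel(seed.id, seed.residues),
            min_identity=cfg.scan_min_identity,
            min_length=cfg.scan_min_length,
            seed_k=cfg.seed_k,
        )
        all_hits.extend(hits)
        for i, h in enumerate(hits):
            hid = f"{seed.id}|h{i}"
            hit_seqs.append(SeqRecord(hid, hit_sequence(index.records, h)[0]))
            hit_by_id[hid] = h
    if not hit_seqs:
        logger.warning("no hits found for any seed")
        return DiscoverResult([], [])

    logger.info("clustering %d hit sequences", len(hit_seqs))
    clusters = cluster_hits(
        hit_seqs, cfg.cluster_min_coverage, cfg.cluster_min_identity
    )
    results: list[FamilyResult] = []
    fam_no = 0
    for cluster in clusters:
        if len(cluster) < cfg.min_cluster_size:
            continue
        fam_no += 1
        fid = f"family-{fam_no}"
        chits = [hit_by_id[r.id] for r in cluster]
        logger.info("extending %s (%d members)", fid, len(cluster))
        fam = extend_to_termini(
            chits,
            index,
            flank=cfg.flank,
            max_rounds=cfg.max_rounds,
            max_copies=cfg.max_copies_per_round,
            family_id=fid,
            min_ltr=cfg.min_ltr,
            max_ltr=cfg.max_ltr,
            min_ltr_identity=cfg.min_ltr_identity,
            min_identity=cfg.scan_min_identity,
        )
        res = FamilyResult(fam, len(cluster))
        if fam.partition is None:
            logger.warning("%s: no termini found; left unpartitioned", fid)
            results.append(res)
            continue
        internal = fam.internal_consensus
        pbs: Optional[PbsCall] = None
        if trna_library:
            pbs = detect_pbs(internal, trna_library)
        else:
            logger.warning("%s: no tRNA library; PBS stage skipped", fid)
            fam.flags.append("pbs_skipped")
        ppt = detect_ppt(internal)
        classify_family(fam, motifs=motifs)
        from .promoter import scan_5s_promoter, scan_trna_promoter

        boxes = None
        if fam.family_class == "TRIMp3_tRNA":
            boxes = scan_trna_promoter(fam.ltr_consensus)
        elif fam.family_class == "TRIMp3_5S":
            boxes = scan_5s_promoter(fam.ltr_consensus, motifs=motifs)
        p = fam.partition
        res.annotation = TrimAnnotation(
            ltr5=p.ltr5,
            internal=p.internal,
            ltr3=p.ltr3,
            ltr_identity=1.0,
            pbs=pbs,
            ppt=ppt,
            boxes=boxes,
        )
        ltr_hits = scan_genome(
            index,
            FamilyModel(f"{fid}_LTR", fam.ltr_consensus),
            min_identity=cfg.scan_min_identity,
            min_length=cfg.scan_min_length,
            seed_k=cfg.seed_k,
        )
        internal_hits = scan_genome(
            index,
            FamilyModel(f"{fid}_I", internal),
            min_identity=cfg.scan_min_identity,
            min_length=cfg.scan_min_length,
            seed_k=cfg.seed_k,
        )
        solos = find_solo_ltrs(ltr_hits, internal_hits, fam, genome_list)
        res.ltr_hits, res.internal_hits, res.solo_calls = ltr_hits, internal_hits, solos
        res.counts = count_full_length(
            ltr_hits,
            internal_hits,
            fam,
            length_frac=cfg.full_length_frac,
            identity_min=cfg.full_identity_min,
            solo_calls=solos,
        )
        results.append(res)

    out = DiscoverResult(results, all_hits)
    partitioned = [r for r in results if r.family.partition is not None]
    if len(partitioned) >= 4:
        rows_msa = build_msa(
            [SeqRecord(r.family.family_id, r.family.ltr_consensus) for r in partitioned]
        )
        out.tree = bootstrap_support(
            rows_msa.rows, n=cfg.bootstrap_n, seed=cfg.seed
        )
    if out_dir is not None:
        _write_outputs(out, cfg, Path(out_dir))
    return out


def _write_outputs(result: DiscoverResult, cfg: PipelineConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    full, split, manifest, classif = [], [], [], []
    features: list[GffFeature] = []
    counts = []
    for r in result.families:
        fam = r.family
        full.append(SeqRecord(fam.family_id, fam.consensus))
        if fam.partition is not None:
            split.append(SeqRecord(fam.family_id, fam.ltr_consensus))
            split.append(SeqRecord(fam.family_id + "-I", fam.internal_consensus))
            p = fam.partition
            manifest.append(
                (
                    fam.family_id,
                    len(fam.consensus),
                    p.ltr_length,
                    p.internal_length,
                    fam.family_class,
                    fam.tsd_length if fam.tsd_length is not None else "NA",
                    ",".join(fam.flags) or "-",
                )
            )
            ann = r.annotation
            classif.append(
                (
                    fam.family_id,
                    fam.family_class,
                    ann.boxes.promoter_type if ann and ann.boxes else "none",
                    ann.pbs.trna_id if ann and ann.pbs else "NA",
                    ann.pbs.mode if ann and ann.pbs else "NA",
                )
            )
            for h in r.ltr_hits:
                features.append(
                    GffFeature(
                        GenomeInterval(h.seq_id, h.start, h.end, h.strand),
                        GFF_LTR,
                        {"ID": f"{fam.family_id}_LTR_{h.start}", "family": fam.family_id},
                        score=h.score,
                    )
                )
            for h in r.internal_hits:
                features.append(
                    GffFeature(
                        GenomeInterval(h.seq_id, h.start, h.end, h.strand),
                        GFF_ELEMENT,
                        {"ID": f"{fam.family_id}_I_{h.start}", "family": fam.family_id},
                        score=h.score,
                    )
                )
        else:
            manifest.append(
                (fam.family_id, len(fam.consensus), "NA", "NA", fam.family_class,
                 "NA", ",".join(fam.flags) or "-")
            )
        if r.counts:
            counts.append(r.counts)
    if full:
        write_fasta(full, out_dir / "families.fa")
    if split:
        write_fasta(split, out_dir / "families_split.fa")
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("family_id\ttotal_len\tltr_len\tinternal_len\tclass\ttsd_len\tflags\n")
        for row in manifest:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out_dir / "classification.tsv", "w") as fh:
        fh.write("family_id\tclass\tpromoter_type\tpbs_trna\tpbs_mode\n")
        for row in classif:
            fh.write("\t".join(str(x) for x in row) + "\n")
    write_counts_tsv(counts, out_dir / "counts.tsv")
    write_hits_tsv(result.seed_hits, out_dir / "seed_hits.tsv")
    write_gff3(features, out_dir / "annotations.gff3")
    if result.tree is not None:
        write_newick(result.tree, out_dir / "promoter_tree.nwk")
    cfg.to_yaml(out_dir / "config.yaml")
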