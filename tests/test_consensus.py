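"""Majority-rule consensus, center-star MSA, and terminus extension."""

import numpy as np
import pytest

from oracles import consensus_oracle
from trimp3.align import local_align
from trimp3.consensus import (
    FamilyModel,
    Msa,
    Partition,
    build_msa,
    extend_to_termini,
    majority_consensus,
)
from trimp3.scan import GenomeIndex, scan_genome
from trimp3.seqio import SeqRecord
from trimp3.simulate import FamilySpec, plant_elements


def _msa(*rows):
    return Msa([(f"r{i}", r) for i, r in enumerate(rows)])


def test_majority_rule_forced_columns():
    # column {A,A,A,C,C} -> A (3/5 >= 0.5)
    assert majority_consensus(_msa("A", "A", "A", "C", "C")) == "A"
    # column {A,A,C,C}: tie broken by fixed base order A<C<G<T
    assert majority_consensus(_msa("A", "A", "C", "C")) == "A"
    # gap-majority column dropped
    assert majority_consensus(_msa("-", "-", "-", "A", "A")) == ""
    # sub-threshold plurality -> N
    assert majority_consensus(_msa("A", "A", "C", "G", "T")) == "N"


def test_majority_matches_counting_oracle_on_random_msas():
    rng = np.random.default_rng(21)
    alphabet = list("ACGT-")
    for _ in range(40):
        rows = [
            "".join(rng.choice(alphabet, size=50, p=[0.2, 0.2, 0.2, 0.2, 0.2]))
            for _ in range(10)
        ]
        assert majority_consensus(Msa([(f"r{i}", r) for i, r in enumerate(rows)])) == \
            consensus_oracle(rows)


def test_identical_members_give_gapless_msa_and_exact_consensus(rng):
    s = "".join(rng.choice(list("ACGT"), size=120))
    for n in (1, 2, 5):
        msa = build_msa([SeqRecord(f"m{i}", s) for i in range(n)])
        assert all("-" not in row for _, row in msa.rows)
        assert majority_consensus(msa) == s


def test_substitution_only_members_recover_ancestor(rng):
    anc = "".join(rng.choice(list("ACGT"), size=200))
    members = []
    for i in range(5):
        s = list(anc)
        for p in rng.choice(200, size=3, replace=False):
            s[p] = "ACGT"["ACGT".index(s[p]) - 1]
        members.append(SeqRecord(f"m{i}", "".join(s)))
    msa = build_msa(members)
    # every aligned column holds homologous positions: the consensus equals
    # the ancestor and every row ungaps to its member
    assert majority_consensus(msa) == anc
    for (mid, row), m in zip(msa.rows, members):
        assert row.replace("-", "") == m.residues


def test_consensus_never_longer_than_columns(rng):
    rows = ["ACGT-ACGT", "AC-TTACGT", "ACGTTAC-T"]
    msa = _msa(*rows)
    assert len(majority_consensus(msa)) <= msa.column_count


@pytest.fixture(scope="module")
def noiseless_family():
    spec = FamilySpec("fam", ltr_len=110, internal_len=150, promoter="none",
                      tsd_len=5, copy_count=10, divergence=0.0)
    genome, truth = plant_elements(800_000, [spec], seed=31)
    return genome, truth


def test_extension_recovers_ancestor_exactly_without_noise(noiseless_family):
    genome, truth = noiseless_family
    anc = truth.ancestors["fam"]
    index = GenomeIndex([genome])
    seed = FamilyModel("fam", anc[80 : len(anc) - 80])
    hits = scan_genome(index, seed)
    fam = extend_to_termini(hits, index, family_id="fam")
    assert fam.partition is not None
    assert fam.consensus == anc
    assert fam.partition.ltr_length == 110
    assert fam.tsd_length == 5


def test_extension_is_idempotent(noiseless_family):
    genome, truth = noiseless_family
    anc = truth.ancestors["fam"]
    index = GenomeIndex([genome])
    hits = scan_genome(index, FamilyModel("fam", anc))
    fam1 = extend_to_termini(hits, index, family_id="fam")
    hits2 = scan_genome(index, FamilyModel("fam", fam1.consensus))
    fam2 = extend_to_termini(hits2, index, family_id="fam")
    assert fam2.consensus == fam1.consensus
    assert fam2.partition == fam1.partition


def test_fragment_cluster_returns_unpartitioned_with_warning(rng):
    # genome copies consist of the internal region only: no LTR pair exists
    internal = "".join(rng.choice(list("ACGT"), size=160))
    background = "".join(rng.choice(list("ACGT"), size=40_000))
    pieces, pos = [], 0
    for start in (5_000, 12_000, 20_000, 28_000, 35_000):
        pieces.append(background[pos:start])
        pieces.append(internal)
        pos = start
    pieces.append(background[pos:])
    genome = SeqRecord("chr1", "".join(pieces))
    index = GenomeIndex([genome])
    hits = scan_genome(index, FamilyModel("frag", internal))
    assert len(hits) == 5
    fam = extend_to_termini(hits, index, family_id="frag", min_ltr=80)
    assert fam.partition is None
    assert "no_termini" in fam.flags


def test_divergent_family_parameter_recovery():
    """10 copies at 2% divergence: consensus ~ ancestor, exact TSD length."""
    spec = FamilySpec("fam", ltr_len=130, internal_len=180, promoter="none",
                      tsd_len=4, copy_count=10, divergence=0.02)
    genome, truth = plant_elements(900_000, [spec], seed=77)
    anc = truth.ancestors["fam"]
    index = GenomeIndex([genome])
    hits = scan_genome(index, FamilyModel("fam", anc[70 : len(anc) - 70]))
    fam = extend_to_termini(hits, index, family_id="fam")
    assert fam.partition is not None
    aln = local_align(fam.consensus, anc)
    assert aln.identity >= 0.99
    assert abs(fam.partition.ltr_length - 130) <= 2
    assert fam.tsd_length == 4


def test_partition_validation():
    with pytest.raises(ValueError):
        Partition(ltr5=(1, 100), internal=(100, 200), ltr3=(200, 300))
    with pytest.raises(ValueError):
        Partition(ltr5=(0, 100), internal=(120, 200), ltr3=(200, 300))
    with pytest.raises(ValueError):
        FamilyModel("f", "A" * 250,
                    Partition(ltr5=(0, 100), internal=(100, 200), ltr3=(200, 300)))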