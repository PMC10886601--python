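"""LTR pair, TSD, PBS, PPT and solo-LTR detection."""

import numpy as np
import pytest

from oracles import ppt_oracle
from trimp3.seqio import SeqRecord, TrnaRecord, revcomp
from trimp3.simulate import FamilySpec, make_family, make_trna_library, plant_elements
from trimp3.structure import (
    ANTICODON_LOOP,
    annotate_element,
    detect_ltr_pair,
    detect_pbs,
    detect_ppt,
    detect_tsd,
    find_solo_ltrs,
)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLtrPair:
    def test_constructed_element_recovered_exactly(self, rng):
        ltr = _random_dna(rng, 150)
        internal = _random_dna(rng, 300)
        pair = detect_ltr_pair(ltr + internal + ltr, anchored=True)
        assert pair is not None
        assert pair.ltr5 == (0, 150)
        assert pair.internal == (150, 450)
        assert pair.ltr3 == (450, 600)
        assert pair.identity == 1.0

    def test_random_sequence_has_no_pair(self, rng):
        assert detect_ltr_pair(_random_dna(rng, 500)) is None

    @pytest.mark.parametrize("ltr_len,internal_len", [
        (80, 50), (80, 700), (120, 85), (200, 300), (330, 650), (400, 50),
    ])
    def test_boundary_recovery_across_size_range(self, rng, ltr_len, internal_len):
        ltr = _random_dna(rng, ltr_len)
        internal = _random_dna(rng, internal_len)
        pair = detect_ltr_pair(ltr + internal + ltr, anchored=True)
        assert pair is not None
        assert pair.ltr5 == (0, ltr_len)
        assert pair.ltr3 == (ltr_len + internal_len, 2 * ltr_len + internal_len)

    def test_reported_element_dimensions_reproduced(self, trna_library, rng):
        """An element with the archetypal compact anatomy (120 bp LTRs, 85 bp
        internal) annotates back to exactly those dimensions."""
        spec = FamilySpec("smo-like", ltr_len=120, internal_len=85,
                          promoter="tRNA_type2", pbs_trna_id="tRNA-Lys-CTT",
                          tsd_len=5)
        elem, _ = make_family(spec, trna_library, rng)
        assert len(elem) == 325
        pair = detect_ltr_pair(elem, anchored=True)
        assert pair.ltr5 == (0, 120)
        assert pair.internal == (120, 205)


class TestTsd:
    def test_planted_tsd_recovered(self, rng):
        elem = _random_dna(rng, 200)
        tsd = "ACGTA"
        seq = _random_dna(rng, 50) + tsd + elem + tsd + _random_dna(rng, 50)
        assert detect_tsd(seq, 55, 255) == "ACGTA"

    def test_disagreeing_flanks_give_none(self):
        seq = "G" * 20 + "TTTT" + "A" * 100 + "GGGG" + "C" * 20
        assert detect_tsd(seq, 24, 124) is None

    def test_longest_duplication_wins(self, rng):
        elem = _random_dna(rng, 100)
        seq = "T" * 20 + "CACGTA" + elem + "CACGTA" + "G" * 20
        assert detect_tsd(seq, 26, 126) == "CACGTA"  # 6 beats nested 4/5

    def test_insufficient_flank_returns_none(self, rng):
        seq = "ACG" + _random_dna(rng, 100)
        assert detect_tsd(seq, 3, 103) is None


class TestPbs:
    def test_three_prime_mode_with_cca(self, trna_library, rng):
        trna = next(t for t in trna_library if t.id == "tRNA-Lys-CTT")
        pbs = revcomp(trna.mature[-12:])
        internal = pbs + _random_dna(rng, 80)
        call = detect_pbs(internal, trna_library)
        assert call is not None
        assert call.trna_id == "tRNA-Lys-CTT"
        assert call.mode == "three_prime_end"
        assert call.complementary_length == 12
        assert call.mismatches == 0
        assert call.pbs_interval == (0, 12)

    def test_anticodon_loop_mode_is_splice_aware(self, trna_library, rng):
        trna = next(t for t in trna_library if t.intron is not None)
        lo = ANTICODON_LOOP[1] - 16
        pbs = revcomp(trna.spliced[lo : ANTICODON_LOOP[1]])
        internal = "AC" + pbs + _random_dna(rng, 60)
        call = detect_pbs(internal, trna_library)
        assert call is not None
        assert call.trna_id == trna.id
        assert call.mode == "anticodon_loop"
        assert call.complementary_length >= 16
        # the match region is contiguous only on the spliced tRNA: the
        # unspliced gene is interrupted by the intron inside that window
        assert revcomp(internal[2 : 2 + 16]) not in trna.residues
        assert revcomp(internal[2 : 2 + 16]) in trna.spliced

    def test_random_internals_rarely_call(self, trna_library):
        rng = np.random.default_rng(555)
        false_calls = 0
        for _ in range(1000):
            internal = _random_dna(rng, 50)
            if detect_pbs(internal, trna_library) is not None:
                false_calls += 1
        assert false_calls / 1000 < 0.05

    def test_short_internal_returns_none(self, trna_library):
        assert detect_pbs("ACGT", trna_library) is None


class TestPpt:
    def test_purine_run_at_junction_detected(self):
        internal = "CTCTCTCTCT" * 5 + "GAAAAGGGGA"
        ppt = detect_ppt(internal)
        assert ppt is not None
        assert ppt[1] == len(internal)

    def test_pyrimidine_tail_gives_none(self, rng):
        internal = _random_dna(rng, 50) + "CTCTCTCTCTCT"
        # last 12 are pyrimidines: no window within 5 nt of the junction
        assert detect_ppt(internal) is None or detect_ppt(internal)[1] <= len(internal)
        assert detect_ppt("CT" * 30) is None

    def test_matches_sliding_window_oracle(self):
        rng = np.random.default_rng(777)
        for _ in range(300):
            internal = "".join(
                rng.choice(list("ACGT"), size=rng.integers(15, 80),
                           p=[0.35, 0.15, 0.35, 0.15])
            )
            assert detect_ppt(internal) == ppt_oracle(internal)


class TestSoloLtr:
    def test_generator_solos_called_exactly(self):
        from trimp3.consensus import FamilyModel, Partition
        from trimp3.scan import GenomeIndex, scan_genome

        spec = FamilySpec("fam", ltr_len=120, internal_len=150, promoter="none",
                          tsd_len=5, copy_count=10, divergence=0.0,
                          solo_fraction=0.3)
        genome, truth = plant_elements(800_000, [spec], seed=41)
        anc = truth.ancestors["fam"]
        fam = FamilyModel(
            "fam", anc,
            Partition(ltr5=(0, 120), internal=(120, 270), ltr3=(270, 390)),
        )
        index = GenomeIndex([genome])
        lh = scan_genome(index, FamilyModel("fam_LTR", fam.ltr_consensus))
        ih = scan_genome(index, FamilyModel("fam_I", fam.internal_consensus))
        solos = find_solo_ltrs(lh, ih, fam, [genome])
        truth_solos = truth.copies[truth.copies.is_solo]
        assert len(solos) == len(truth_solos) == 3
        truth_by_start = dict(zip(truth_solos.start, truth_solos.tsd))
        for s in solos:
            assert truth_by_start[s.hit.start] == s.tsd

    def test_unpartitioned_family_rejected(self):
        from trimp3.consensus import FamilyModel

        with pytest.raises(ValueError):
            find_solo_ltrs([], [], FamilyModel("f", "ACGT" * 30), [])


def test_full_annotation_of_generated_element(trna_library, rng):
    spec = FamilySpec("fam", ltr_len=150, internal_len=200,
                      promoter="tRNA_type2", pbs_mode="anticodon_loop",
                      pbs_trna_id="tRNA-iMet-CAT", tsd_len=5)
    elem, meta = make_family(spec, trna_library, rng)
    ann = annotate_element(elem, trna_library)
    assert ann is not None
    assert ann.ltr5 == (0, 150) and ann.ltr3 == (350, 500)
    assert ann.pbs.trna_id == "tRNA-iMet-CAT"
    assert ann.pbs.mode == "anticodon_loop"
    assert ann.ppt is not None
    assert ann.boxes is not None and ann.boxes.promoter_type == "tRNA_type2"
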