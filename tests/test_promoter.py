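"""RNA polymerase III promoter motif scanning and family classification."""

import numpy as np
import pytest

from trimp3.consensus import FamilyModel, Partition
from trimp3.promoter import (
    classify_family,
    default_5s_motifs,
    iupac_mismatches,
    scan_5s_promoter,
    scan_trna_promoter,
)
from trimp3.simulate import FamilySpec, make_family, make_trna_library, mutate


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def test_iupac_matching():
    assert iupac_mismatches("TRGCY", "TAGCT") == 0
    assert iupac_mismatches("TRGCY", "TGGCC") == 0
    assert iupac_mismatches("TRGCY", "TCGCC") == 1
    with pytest.raises(ValueError):
        iupac_mismatches("TRGCY", "TAGC")


def test_constructed_trna_promoter_found(rng):
    ltr = (
        _random_dna(rng, 10)
        + "TAGCT" + _random_dna(rng, 6) + "TGG"
        + _random_dna(rng, 16) + "GGTTC"
        + _random_dna(rng, 60)
    )
    ann = scan_trna_promoter(ltr)
    assert ann.promoter_type == "tRNA_type2"
    assert ann.box_a.interval[0] == 10
    assert ltr[slice(*ann.box_b.interval)] == "GGTTC"
    # box B downstream of box A start by 20-80 nt
    assert 20 <= ann.box_b.interval[0] - ann.box_a.interval[0] <= 80


def test_trna_promoter_spacing_enforced(rng):
    # GGTTC too close to box A (within 20 nt): no call
    ltr = "TAGCT" + "AA" + "TGG" + "GGTTC" + _random_dna(rng, 100)
    ann = scan_trna_promoter(ltr)
    assert ann.promoter_type == "none" or ann.box_b.interval[0] >= 20


def test_5s_positive_control_is_the_reference_itself():
    m = default_5s_motifs()
    ann = scan_5s_promoter(m.reference, motifs=m)
    assert ann.promoter_type == "fiveS_type1"
    assert ann.box_a.matched == m.box_a
    assert ann.ie.matched == m.ie
    assert ann.box_c.matched == m.box_c


def test_cross_specificity_between_promoter_types(trna_library, rng):
    spec_t = FamilySpec("t", ltr_len=150, internal_len=120,
                        promoter="tRNA_type2", pbs_trna_id="tRNA-Lys-CTT")
    elem_t, _ = make_family(spec_t, trna_library, rng)
    ltr_t = elem_t[:150]
    assert scan_trna_promoter(ltr_t).promoter_type == "tRNA_type2"
    assert scan_5s_promoter(ltr_t).promoter_type == "none"

    spec_5 = FamilySpec("f", ltr_len=150, internal_len=120,
                        promoter="fiveS_type1", pbs_trna_id="tRNA-Leu-CAA")
    elem_5, _ = make_family(spec_5, trna_library, rng)
    assert scan_5s_promoter(elem_5[:150]).promoter_type == "fiveS_type1"


def test_random_ltrs_rarely_scan_positive():
    """Monte-Carlo null rates of both scanners on random 300-mers.

    The long 5S internal-control-region motifs essentially never fire by
    chance.  The tRNA-type promoter is a short bipartite pattern with one
    tolerated mismatch and 60 admissible box B placements, so its analytic
    chance rate is ~0.14 per 300-mer; the bound below brackets that rate
    (detection therefore relies on the promoter appearing in *both* LTRs
    of a real family, not on single-window specificity).
    """
    rng = np.random.default_rng(404)
    fp_trna = fp_5s = 0
    n = 1000
    for _ in range(n):
        ltr = _random_dna(rng, 300)
        if scan_trna_promoter(ltr).promoter_type != "none":
            fp_trna += 1
        if scan_5s_promoter(ltr).promoter_type != "none":
            fp_5s += 1
    assert fp_trna / n < 0.18
    assert fp_5s / n < 0.02


def test_scan_is_deterministic(rng):
    ltr = _random_dna(rng, 300)
    assert scan_trna_promoter(ltr) == scan_trna_promoter(ltr)


def _family_from_element(elem, ltr_len):
    internal_end = len(elem) - ltr_len
    return FamilyModel(
        "fam", elem,
        Partition((0, ltr_len), (ltr_len, internal_end), (internal_end, len(elem))),
    )


def test_classification_of_planted_families(trna_library, rng):
    for promoter, expected in [
        ("tRNA_type2", "TRIMp3_tRNA"),
        ("fiveS_type1", "TRIMp3_5S"),
        ("none", "TRIMp2"),
    ]:
        spec = FamilySpec("fam", ltr_len=150, internal_len=200,
                          promoter=promoter, pbs_trna_id="tRNA-Leu-CAA")
        elem, _ = make_family(spec, trna_library, rng)
        fam = _family_from_element(elem, 150)
        assert classify_family(fam) == expected
        assert fam.family_class == expected


def test_long_trim_flagging(trna_library, rng):
    # 1263 bp: classification kept but flagged as a long TRIM
    spec = FamilySpec("long", ltr_len=321, internal_len=621,
                      promoter="tRNA_type2", pbs_trna_id="tRNA-Lys-CTT")
    elem, _ = make_family(spec, trna_library, rng)
    fam = _family_from_element(elem, 321)
    assert len(elem) == 1263
    assert classify_family(fam) == "TRIMp3_tRNA"
    assert "long_trim" in fam.flags

    # beyond 1300 bp the TRIM label is withheld
    spec2 = FamilySpec("toolong", ltr_len=400, internal_len=700,
                       promoter="tRNA_type2", pbs_trna_id="tRNA-Lys-CTT")
    elem2, _ = make_family(spec2, trna_library, rng)
    fam2 = _family_from_element(elem2, 400)
    assert classify_family(fam2) == "unclassified"
    assert "not_trim_length" in fam2.flags


def test_unpartitioned_family_rejected():
    with pytest.raises(ValueError):
        classify_family(FamilyModel("f", "ACGT" * 100))


def test_sensitivity_on_diverged_ltrs(trna_library):
    """Family-level detection (either LTR) of planted promoters at 5% divergence."""
    rng = np.random.default_rng(2024)
    detected = {"tRNA_type2": 0, "fiveS_type1": 0}
    n_per_type = 100
    for promoter in detected:
        for i in range(n_per_type):
            spec = FamilySpec("fam", ltr_len=160, internal_len=120,
                              promoter=promoter, pbs_trna_id="tRNA-Leu-CAA")
            elem, _ = make_family(spec, trna_library, rng)
            ltr = elem[:160]
            hit = False
            for _ltr_copy in range(2):  # both LTRs diverge independently
                mut, _, _ = mutate(ltr, 0.05, 0.0, rng)
                if promoter == "tRNA_type2":
                    hit = hit or scan_trna_promoter(mut).promoter_type != "none"
                else:
                    hit = hit or scan_5s_promoter(mut).promoter_type != "none"
            detected[promoter] += hit
    assert detected["tRNA_type2"] / n_per_type >= 0.9
    assert detected["fiveS_type1"] / n_per_type >= 0.9


def test_zero_divergence_promoters_always_detected(trna_library):
    rng = np.random.default_rng(31337)
    for _ in range(25):
        for promoter, scanner in (
            ("tRNA_type2", scan_trna_promoter),
            ("fiveS_type1", scan_5s_promoter),
        ):
            spec = FamilySpec("fam", ltr_len=170, internal_len=100,
                              promoter=promoter, pbs_trna_id="tRNA-Lys-CTT")
            elem, _ = make_family(spec, trna_library, rng)
            assert scanner(elem[:170]).promoter_type == promoter
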