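"""Jukes-Cantor distances, BioNJ reconstruction, bootstrap supports."""

import math

import dendropy
import numpy as np
import pytest
from scipy.stats import binom

from trimp3.phylo import (
    DistanceMatrix,
    bionj_tree,
    bootstrap_support,
    jc_distance,
    jc_matrix,
    patristic_matrix,
    tree_bipartitions,
    write_newick,
)


class TestJcDistance:
    def test_identical_rows_give_zero(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # p = 0.1
        assert abs(jc_distance(a, b) - 0.10732) < 1e-5

    def test_saturation_capped(self):
        a = "A" * 80
        b = "C" * 60 + "A" * 20  # p = 0.75: formula singular
        assert jc_distance(a, b) == 5.0

    def test_pairwise_deletion_of_gaps_and_n(self):
        a = "AC-TNACGT"
        b = "ACGT-ACGA"
        # 7 shared unambiguous columns, 1 mismatch -> p = 1/7
        expect = -0.75 * math.log(1 - 4 * (1 / 7) / 3)
        assert abs(jc_distance(a, b) - expect) < 1e-12

    def test_no_shared_columns_is_an_error(self):
        with pytest.raises(ValueError):
            jc_distance("AC--", "--GT")

    def test_monotone_in_mismatch_proportion(self):
        prev = -1.0
        for k in range(0, 74):
            b = "C" * k + "A" * (100 - k)
            d = jc_distance("A" * 100, b)
            assert d > prev
            prev = d


def _dm(taxa, rows):
    d = np.array(rows, dtype=float)
    return DistanceMatrix(list(taxa), d, np.zeros_like(d))


class TestBionj:
    def test_three_taxa_closed_form(self):
        dm = _dm("ABC", [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]])
        tree = bionj_tree(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert abs(lengths["A"] - 0.2) < 1e-12  # (dAB + dAC - dBC)/2
        assert abs(lengths["B"] - 0.1) < 1e-12
        assert abs(lengths["C"] - 0.3) < 1e-12

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            bionj_tree(_dm("AB", [[0, 1], [1, 0]]))

    def test_five_taxon_tree_matches_independent_implementation(self):
        """Frozen output of ape::bionj (R) on the same matrix."""
        dm = _dm(
            "ABCDE",
            [
                [0.00, 0.30, 0.45, 0.55, 0.70],
                [0.30, 0.00, 0.40, 0.50, 0.62],
                [0.45, 0.40, 0.00, 0.33, 0.41],
                [0.55, 0.50, 0.33, 0.00, 0.28],
                [0.70, 0.62, 0.41, 0.28, 0.00],
            ],
        )
        tree = bionj_tree(dm)
        # ape: (E:0.1876207,D:0.0923793,(C:0.1020000,(B:0.1200000,
        #       A:0.1800000):0.1740000):0.1280000);
        expected_leaf = {
            "A": 0.1799999923,
            "B": 0.1200000122,
            "C": 0.102000013,
            "D": 0.09237930924,
            "E": 0.187620692,
        }
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        for t, v in expected_leaf.items():
            assert abs(lengths[t] - v) < 1e-6
        # bipartitions are normalized to the side not containing taxon A
        bps = tree_bipartitions(tree)
        assert frozenset({"D", "E"}) in bps
        assert frozenset({"C", "D", "E"}) in bps
        internal = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            internal[below] = node.edge.length
        assert abs(internal[frozenset({"A", "B"})] - 0.1739999801) < 1e-6
        assert abs(internal[frozenset({"A", "B", "C"})] - 0.1279999986) < 1e-6


def _random_tree_newick(rng, n):
    nodes = [f"T{i}:{rng.uniform(0.05, 1.0):.6f}" for i in range(n)]
    while len(nodes) > 3:
        j = int(rng.integers(1, len(nodes)))
        i = int(rng.integers(0, j))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.05, 1.0):.6f}")
    return "(" + ",".join(nodes) + ");"


@pytest.mark.parametrize("trial", range(30))
def test_additive_matrix_recovers_generating_tree(trial):
    rng = np.random.default_rng(1000 + trial)
    n = int(rng.integers(4, 13))
    src = dendropy.Tree.get(data=_random_tree_newick(rng, n), schema="newick")
    dm = patristic_matrix(src)
    rebuilt = bionj_tree(dm)
    assert tree_bipartitions(rebuilt) == tree_bipartitions(src)
    back = patristic_matrix(rebuilt)
    assert np.allclose(back.d, dm.d, atol=1e-9)


class TestBootstrap:
    def _rows_single_split(self):
        return [
            ("A", "A" * 60),
            ("B", "A" * 60),
            ("C", "T" * 60),
            ("D", "T" * 60),
        ]

    def test_unanimous_alignment_gives_full_support(self):
        tree = bootstrap_support(self._rows_single_split(), n=50, seed=3)
        labels = [
            node.label
            for node in tree.preorder_node_iter()
            if node.label and not node.is_leaf()
        ]
        assert "100" in labels

    def test_seed_determinism(self):
        rows = self._rows_single_split()
        t1 = bootstrap_support(rows, n=30, seed=9)
        t2 = bootstrap_support(rows, n=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_conflicting_patterns_hit_binomial_expectation(self):
        """Support equals the probability that the majority pattern wins a
        resample, computed exactly from the binomial distribution."""
        n1, ncol = 52, 100
        cols = [("A", "A", "T", "T")] * n1 + [("A", "T", "A", "T")] * (ncol - n1)
        rows = [
            (t, "".join(c[i] for c in cols)) for i, t in enumerate("ABCD")
        ]
        n_rep = 1000
        tree = bootstrap_support(rows, n=n_rep, seed=12345)
        support = None
        all_taxa = frozenset("ABCD")
        for node in tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf() or not node.label:
                continue
            below = frozenset(l.taxon.label for l in node.leaf_iter())
            key = all_taxa - below if "A" in below else below
            if key in (frozenset({"C", "D"}), frozenset({"A", "B"})):
                support = float(node.label)
        assert support is not None
        # replicate recovers AB|CD iff >= 50 of its columns are majority-type
        # (the NJ tie-break at 50/50 also joins the first pair)
        p_win = 1 - binom.cdf(49, ncol, n1 / ncol)
        se = math.sqrt(p_win * (1 - p_win) / n_rep)
        assert abs(support / 100 - p_win) <= 3 * se

    def test_newick_roundtrip(self, tmp_path):
        tree = bootstrap_support(self._rows_single_split(), n=20, seed=5)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = dendropy.Tree.get(path=str(p), schema="newick")
        assert {l.taxon.label for l in back.leaf_node_iter()} == set("ABCD")


def test_jc_matrix_consistency():
    rows = [("A", "ACGTACGT"), ("B", "ACGTACGA"), ("C", "TCGTACGA")]
    dm = jc_matrix(rows)
    assert dm.d[0, 0] == 0.0
    assert np.allclose(dm.d, dm.d.T)
    assert abs(dm.p_raw[0, 1] - 1 / 8) < 1e-12
    assert dm.d[0, 1] == jc_distance(rows[0][1], rows[1][1])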