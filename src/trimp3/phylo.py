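"""Distance phylogenetics for promoter/tRNA-like sequence alignments.

Pairwise evolutionary distances use the Jukes-Cantor correction
``d = -(3/4) ln(1 - 4p/3)`` of the site mismatch proportion ``p`` computed
under pairwise deletion (only columns where both rows carry an unambiguous
base).  Saturated pairs (``p >= 3/4``, where the correction diverges) are
capped at a configurable maximum.  Trees are reconstructed with BioNJ, the
variance-weighted neighbor-joining variant, and internal-branch support is
estimated by bootstrap resampling of alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import dendropy
import numpy as np

#: default cap (substitutions/site) for saturated distances
MAX_DISTANCE = 5.0

Row = tuple[str, str]  # (taxon, gapped aligned sequence)


def _shared_columns(a: str, b: str) -> tuple[int, int]:
    """(shared unambiguous columns, mismatches) under pairwise deletion."""
    shared = mism = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        shared += 1
        if ca != cb:
            mism += 1
    return shared, mism


def jc_distance(
    row_a: str, row_b: str, max_distance: float = MAX_DISTANCE
) -> float:
    """Jukes-Cantor distance between two equal-length gapped rows.

    Raises on rows of unequal length or with no shared unambiguous column;
    returns ``max_distance`` when the mismatch proportion reaches the
    saturation point p = 3/4.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    shared, mism = _shared_columns(row_a, row_b)
    if shared == 0:
        raise ValueError("no shared non-gap columns between rows")
    p = mism / shared
    if p >= 0.75:
        return max_distance
    return min(-0.75 * math.log1p(-4.0 * p / 3.0), max_distance)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with the raw mismatch proportions kept."""

    taxa: list[str]
    d: np.ndarray
    p_raw: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n) or not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric over the taxa")


def jc_matrix(rows: Sequence[Row], max_distance: float = MAX_DISTANCE) -> DistanceMatrix:
    """All-pairs Jukes-Cantor distances for an alignment."""
    taxa = [t for t, _ in rows]
    n = len(rows)
    d = np.zeros((n, n))
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared, mism = _shared_columns(rows[i][1], rows[j][1])
            if shared == 0:
                pij, dij = 1.0, max_distance
            else:
                pij = mism / shared
                dij = (
                    max_distance
                    if pij >= 0.75
                    else min(-0.75 * math.log1p(-4.0 * pij / 3.0), max_distance)
                )
            d[i, j] = d[j, i] = dij
            p[i, j] = p[j, i] = pij
    return DistanceMatrix(taxa, d, p)


def bionj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """BioNJ tree reconstruction.

    Standard neighbor joining agglomeration with BioNJ's variance-weighted
    distance reduction; ties in the Q criterion break toward the earliest
    pair in taxon order, and negative branch lengths are clamped to zero.
    The returned tree is unrooted (trifurcating seed node).
    """
    taxa = list(dm.taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("BioNJ needs at least 3 taxa")
    ns = dendropy.TaxonNamespace(taxa)
    nodes: list[dendropy.Node] = []
    for t in taxa:
        node = dendropy.Node(taxon=ns.get_taxon(t))
        nodes.append(node)
    D = dm.d.astype(float).copy()
    V = D.copy()
    active = list(range(n))

    def _attach(parent_child: dendropy.Node, length: float) -> None:
        parent_child.edge.length = max(0.0, float(length))

    while len(active) > 3:
        r = len(active)
        S = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                i, j = active[ii], active[jj]
                q = (r - 2) * D[i, j] - S[i] - S[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        bi = 0.5 * D[i, j] + (S[i] - S[j]) / (2.0 * (r - 2))
        bj = D[i, j] - bi
        new = dendropy.Node()
        new.add_child(nodes[i])
        new.add_child(nodes[j])
        _attach(nodes[i], bi)
        _attach(nodes[j], bj)
        vij = V[i, j]
        if vij > 1e-12:
            others = [k for k in active if k not in (i, j)]
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (
                2.0 * (r - 2) * vij
            )
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        # reuse slot i for the new node, deactivate j
        for k in active:
            if k in (i, j):
                continue
            D_uk = lam * (D[i, k] - bi) + (1.0 - lam) * (D[j, k] - bj)
            V_uk = lam * V[i, k] + (1.0 - lam) * V[j, k] - lam * (1.0 - lam) * vij
            D[i, k] = D[k, i] = D_uk
            V[i, k] = V[k, i] = max(0.0, V_uk)
        nodes[i] = new
        active.remove(j)

    x, y, z = active
    root = dendropy.Node()
    for a, b, c in ((x, y, z), (y, x, z), (z, x, y)):
        length = 0.5 * (D[a, b] + D[a, c] - D[b, c])
        root.add_child(nodes[a])
        _attach(nodes[a], length)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Internal-edge bipartitions as normalized leaf-label sets.

    Each internal edge splits the taxa in two; the side not containing the
    first taxon (in namespace order) represents the bipartition.
    """
    all_taxa = frozenset(t.label for t in tree.taxon_namespace)
    first = min(all_taxa)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) <= 1 or len(below) >= len(all_taxa) - 1:
            continue
        if first in below:
            below = all_taxa - below
        out.add(below)
    return out


def bootstrap_support(
    rows: Sequence[Row],
    tree_builder: Optional[Callable[[Sequence[Row]], dendropy.Tree]] = None,
    n: int = 100,
    seed: int = 0,
    max_distance: float = MAX_DISTANCE,
) -> dendropy.Tree:
    """Column bootstrap supports for the BioNJ tree of an alignment.

    ``n`` resamples of alignment columns (with replacement, seeded) are
    drawn; a tree is built per replicate and the support of each internal
    bipartition of the reference tree is the percentage of replicates
    containing it, attached as the internal node label.
    """
    if len(rows) < 4:
        raise ValueError("bootstrap needs at least 4 taxa")
    builder = tree_builder or (lambda rs: bionj_tree(jc_matrix(rs, max_distance)))
    ref = builder(rows)
    width = len(rows[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree_bipartitions(ref)}
    for _ in range(n):
        cols = rng.integers(0, width, size=width)
        sample = [(t, "".join(s[c] for c in cols)) for t, s in rows]
        rep_bps = tree_bipartitions(builder(sample))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_taxa = frozenset(t for t, _ in rows)
    first = min(all_taxa)
    for node in ref.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        key = all_taxa - below if first in below else below
        if key in counts:
            node.label = f"{100.0 * counts[key] / n:g}"
    return ref


def write_newick(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
        )


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((t.label for t in tree.taxon_namespace))
    lookup = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(lookup[taxa[i]], lookup[taxa[j]])
    return DistanceMatrix(taxa, d, np.zeros((n, n)))
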