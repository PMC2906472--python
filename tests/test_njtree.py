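"""Neighbor joining: closed forms, additivity, brute-force topology
search, bootstrap supports, newick round trips."""

import itertools

import numpy as np
import pytest

from srcrpipe.distance import DistanceMatrix
from srcrpipe.msa import DomainAlignment
from srcrpipe.njtree import (TreeError, bipartitions, bootstrap_tree,
                             neighbor_joining, node_support, read_newick,
                             rf_distance, write_newick)


def _dm(labels, values):
    return DistanceMatrix(labels=list(labels),
                          values=np.array(values, dtype=float))


def _leaf_branch(tree, label):
    leaf = [l for l in tree.leaf_node_iter() if l.taxon.label == label][0]
    return leaf.edge.length


def test_three_taxa_closed_form():
    t = neighbor_joining(_dm("xyz", [[0, 4, 6], [4, 0, 8], [6, 8, 0]]))
    assert _leaf_branch(t, "x") == pytest.approx((4 + 6 - 8) / 2)
    assert _leaf_branch(t, "y") == pytest.approx((4 + 8 - 6) / 2)
    assert _leaf_branch(t, "z") == pytest.approx((6 + 8 - 4) / 2)
    assert len(t.seed_node.child_nodes()) == 3


def test_additive_five_taxon_matrix_recovered_exactly():
    # tree ((a:2,b:3):1,(c:1,d:4):2,e:6) -> its path-length matrix
    labels = list("abcde")
    paths = {("a", "b"): 5, ("a", "c"): 6, ("a", "d"): 9, ("a", "e"): 11,
             ("b", "c"): 7, ("b", "d"): 10, ("b", "e"): 12,
             ("c", "d"): 5, ("c", "e"): 9, ("d", "e"): 12}
    D = np.zeros((5, 5))
    for (x, y), v in paths.items():
        i, j = labels.index(x), labels.index(y)
        D[i, j] = D[j, i] = v
    t = neighbor_joining(_dm(labels, D))
    # canonical sides exclude the anchor leaf 'a': ab|cde and cd|abe
    assert bipartitions(t) == {frozenset({"c", "d", "e"}),
                               frozenset({"c", "d"})}
    pdm = t.phylogenetic_distance_matrix()
    tx = {x.label: x for x in t.taxon_namespace}
    for (x, y), v in paths.items():
        assert pdm.distance(tx[x], tx[y]) == pytest.approx(v, abs=1e-9)


def _ls_error(D, labels, split):
    """Least-squares branch fit error for a 4-taxon topology given as the
    pair grouped together; brute-force oracle over edge lengths."""
    from scipy.optimize import nnls

    pairs = list(itertools.combinations(range(4), 2))
    (g1, g2) = split
    other = [k for k in range(4) if k not in split]
    # params: 4 pendant edges + 1 internal
    A = np.zeros((len(pairs), 5))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        A[r, i] = A[r, j] = 1
        same_side = {i, j} == set(split) or {i, j} == set(other)
        if not same_side:
            A[r, 4] = 1
        y[r] = D[i, j]
    coef, _ = nnls(A, y)
    return np.linalg.norm(A @ coef - y)


def test_four_taxa_matches_brute_force_topology_search():
    rng = np.random.default_rng(0)
    for _ in range(10):
        pts = rng.random((4, 6))
        D = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                D[i, j] = np.abs(pts[i] - pts[j]).sum()
        labels = [f"t{i}" for i in range(4)]
        t = neighbor_joining(_dm(labels, D))
        bp = bipartitions(t)
        assert len(bp) == 1
        got_pair = tuple(sorted(int(x[1]) for x in next(iter(bp))))
        errors = {split: _ls_error(D, labels, split)
                  for split in [(0, 1), (0, 2), (0, 3)]}
        best = min(errors, key=errors.get)
        best_pair = tuple(sorted(best))
        complement = tuple(sorted(set(range(4)) - set(best)))
        assert got_pair in (best_pair, complement)


def test_nj_matches_scikit_bio_on_random_matrices():
    pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sknj

    rng = np.random.default_rng(1)
    for _ in range(3):
        n = 7
        pts = rng.random((n, 4))
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                D[i, j] = np.abs(pts[i] - pts[j]).sum()
        labels = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(_dm(labels, D))
        sk = sknj(SkDM(D, labels))
        # compare via canonical bipartitions
        all_labels = set(labels)
        anchor = min(labels)
        canon = set()
        for sub in sk.traverse():
            if sub.is_tip() or sub.is_root():
                continue
            side = {l.name for l in sub.tips()}
            if 1 < len(side) < n - 1:
                canon.add(frozenset(all_labels - side
                                    if anchor in side else side))
        assert bipartitions(mine) == canon


def test_nj_input_validation():
    with pytest.raises(TreeError):
        neighbor_joining(_dm("ab", [[0, 1], [1, 0]]))
    bad = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
    with pytest.raises(TreeError, match="missing"):
        neighbor_joining(_dm("abc", bad))


def test_bipartitions_invariant_under_leaf_permutation():
    rng = np.random.default_rng(4)
    n = 8
    pts = rng.random((n, 4))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.abs(pts[i] - pts[j]).sum()
    labels = [f"t{i}" for i in range(n)]
    t1 = neighbor_joining(_dm(labels, D))
    perm = rng.permutation(n)
    t2 = neighbor_joining(_dm([labels[k] for k in perm],
                              D[np.ix_(perm, perm)]))
    assert bipartitions(t1) == bipartitions(t2)


def test_negative_branch_lengths_flagged_and_clampable():
    D = np.array([[0, 5, 9, 9],
                  [5, 0, 9, 9],
                  [9, 9, 0, 1],
                  [9, 9, 1, 0]], dtype=float)
    # distort to force a negative estimate
    D[0, 1] = D[1, 0] = 0.01
    D[0, 2] = D[2, 0] = 12
    with pytest.warns(UserWarning, match="negative"):
        t = neighbor_joining(_dm("abcd", D))
    assert any(l.edge.length < 0 for l in t.leaf_node_iter())
    t2 = neighbor_joining(_dm("abcd", D), clamp_negative=True)
    assert all(l.edge.length >= 0 for l in t2.leaf_node_iter())


def test_bootstrap_identical_sequences_no_supported_splits():
    aln = DomainAlignment([(f"s{i}", "ACDEFGHIKL" * 6) for i in range(5)])
    t = bootstrap_tree(aln, B=100, seed=1)
    sups = [node_support(n) for n in t.preorder_node_iter()
            if not n.is_leaf() and n is not t.seed_node]
    # every bipartition of identical data is arbitrary: none should be firm
    assert all(s is None or s <= 0.9 for s in sups)


def test_bootstrap_supports_true_splits_at_low_divergence(default_family):
    from srcrpipe.synthetic_data import evolve_domain

    rng = np.random.default_rng(2)
    rows = []
    for letter in ("a", "b", "c", "d"):
        proto = default_family.prototypes[letter]
        for k in range(2):
            rows.append((f"{letter}{k}", evolve_domain(proto, 0.03, rng)[0]))
    aln = DomainAlignment(rows)
    t = bootstrap_tree(aln, B=150, seed=9)
    truth = {frozenset({f"{l}0", f"{l}1"}) for l in "bcd"}  # canonical sides
    found = {}
    all_labels = {lab for lab, _ in rows}
    for node in t.preorder_node_iter():
        if node.is_leaf() or node is t.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if "a0" in side:
            side = frozenset(all_labels - side)
        found[side] = node_support(node)
    for bp in truth:
        assert bp in found and found[bp] >= 0.9


def test_bootstrap_supports_stable_across_seeds(core_alignment):
    sub = DomainAlignment(core_alignment.rows[:10])
    t1 = bootstrap_tree(sub, B=1000, seed=1)
    t2 = bootstrap_tree(sub, B=1000, seed=2)

    def sups(t):
        out = {}
        labels = {l.taxon.label for l in t.leaf_node_iter()}
        anchor = min(labels)
        for n in t.preorder_node_iter():
            if n.is_leaf() or n is t.seed_node:
                continue
            side = frozenset(l.taxon.label for l in n.leaf_iter())
            if anchor in side:
                side = frozenset(labels - side)
            out[side] = node_support(n)
        return out

    s1, s2 = sups(t1), sups(t2)
    for bp in set(s1) & set(s2):
        assert abs(s1[bp] - s2[bp]) <= 0.03


def test_newick_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(a:1,b:2,(c:1,d:1):0.5);\n")
    t = read_newick(p)
    out = tmp_path / "o.nwk"
    write_newick(t, out)
    t2 = read_newick(out)
    assert rf_distance(t, t2) == 0
    pdm1 = t.phylogenetic_distance_matrix()
    tx1 = {x.label: x for x in t.taxon_namespace}
    assert pdm1.distance(tx1["a"], tx1["b"]) == pytest.approx(3.0)


def test_newick_support_as_internal_label(tmp_path):
    p = tmp_path / "s.nwk"
    p.write_text("(a:1,b:2,(c:1,d:1)0.97:0.5);\n")
    t = read_newick(p)
    internal = [n for n in t.preorder_node_iter()
                if not n.is_leaf() and n is not t.seed_node]
    assert node_support(internal[0]) == pytest.approx(0.97)
    out = tmp_path / "o.nwk"
    write_newick(t, out)
    assert "0.97" in out.read_text()


def test_newick_errors(tmp_path):
    bad = tmp_path / "bad.nwk"
    bad.write_text("((a,b);\n")
    with pytest.raises(TreeError, match="parse"):
        read_newick(bad)
    dup = tmp_path / "dup.nwk"
    dup.write_text("(a:1,a:1,b:1);\n")
    with pytest.raises(TreeError, match="duplicate"):
        read_newick(dup)
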