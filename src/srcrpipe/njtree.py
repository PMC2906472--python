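"""Neighbor-joining trees with column-bootstrap support, plus newick I/O.

The agglomeration is the standard Saitou–Nei Q-criterion; ties are broken
by the smallest (row, column) index pair so results are platform-stable.
Trees are stored rooted at the final trifurcation (dendropy ``Tree``
objects); bootstrap supports live on internal nodes as labels in
``[0, 1]``.  On an additive distance matrix NJ recovers the generating
topology and exact branch lengths, which is the main correctness oracle.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import dendropy
import numpy as np

from .distance import DistanceMatrix, correct_distance
from .msa import DomainAlignment


class TreeError(ValueError):
    pass


def neighbor_joining(D: DistanceMatrix, clamp_negative: bool = False):
    """Build an NJ tree from a distance matrix.

    Negative branch lengths are retained and reported with a warning
    unless ``clamp_negative`` is set, in which case a negative pendant
    length is clamped to 0 and the deficit moved to its sister edge.
    """
    labels = list(D.labels)
    n = len(labels)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    d = np.array(D.values, dtype=float)
    if np.isnan(d).any():
        raise TreeError(
            "distance matrix has missing cells; impute or prune first")

    taxa = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxa.get_taxon(l)) for l in labels]
    idx = list(range(n))            # positions into d of active clusters
    negative = False

    while len(idx) > 3:
        m = len(idx)
        sub = d[np.ix_(idx, idx)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        # smallest Q; ties -> smallest (row, col)
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        i_, j_ = min((min(a, b), max(a, b)) for a, b in ties)
        dij = sub[i_, j_]
        bi = 0.5 * dij + (R[i_] - R[j_]) / (2 * (m - 2))
        bj = dij - bi
        if bi < 0 or bj < 0:
            negative = True
            if clamp_negative:
                if bi < 0:
                    bj, bi = bj + bi, 0.0
                elif bj < 0:
                    bi, bj = bi + bj, 0.0
        parent = dendropy.Node()
        ni, nj = nodes[idx[i_]], nodes[idx[j_]]
        parent.add_child(ni)
        parent.add_child(nj)
        ni.edge.length = bi
        nj.edge.length = bj
        # distances from the new node u to every other active cluster
        gi, gj = idx[i_], idx[j_]
        new_row = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.vstack([d, new_row])
        d = np.hstack([d, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        for k in sorted((i_, j_), reverse=True):
            idx.pop(k)
        idx.append(d.shape[0] - 1)

    # final trifurcation
    a, b, c = idx
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    root = dendropy.Node()
    for node, bl in ((nodes[a], 0.5 * (dab + dac - dbc)),
                     (nodes[b], 0.5 * (dab + dbc - dac)),
                     (nodes[c], 0.5 * (dac + dbc - dab))):
        if bl < 0:
            negative = True
            if clamp_negative:
                bl = 0.0
        root.add_child(node)
        node.edge.length = bl

    if negative and not clamp_negative:
        warnings.warn("NJ produced negative branch lengths (retained)",
                      stacklevel=2)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and support

def bipartitions(tree, canonical_label: str | None = None) -> set[frozenset]:
    """Non-trivial bipartitions of an (unrooted) tree, each canonicalized
    as the side not containing the lexicographically smallest leaf.
    Zero-length internal edges are treated as soft polytomies and
    contribute no bipartition."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    anchor = canonical_label or leaves[0]
    total = set(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        if node.edge.length is not None and abs(node.edge.length) <= 1e-12:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if len(side) <= 1 or len(side) >= len(total) - 1:
            continue
        if anchor in side:
            side = total - side
        out.add(frozenset(side))
    return out


def rf_distance(t1, t2) -> int:
    """Unweighted Robinson–Foulds distance (bipartition symmetric
    difference)."""
    l1 = {l.taxon.label for l in t1.leaf_node_iter()}
    l2 = {l.taxon.label for l in t2.leaf_node_iter()}
    if l1 != l2:
        raise TreeError("trees are over different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


def _pairwise_p_matrix(codes: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """All-pairs p-distances for integer-coded alignment rows (vectorized;
    invalid positions are gaps/X)."""
    both = valid[:, None, :] & valid[None, :, :]
    diff = (codes[:, None, :] != codes[None, :, :]) & both
    n_ok = both.sum(axis=2)
    with np.errstate(invalid="ignore"):
        p = np.where(n_ok > 0, diff.sum(axis=2) / np.maximum(n_ok, 1), np.nan)
    np.fill_diagonal(p, 0.0)
    return p


def _encode(alignment: DomainAlignment):
    arr = np.array([list(s) for _, s in alignment.rows])
    valid = ~np.isin(arr, list("-X."))
    codes = np.frombuffer("".join("".join(r) for r in arr).encode("latin1"),
                          dtype=np.uint8).reshape(arr.shape)
    return codes, valid


def bootstrap_tree(alignment: DomainAlignment, model_tag: str = "p",
                   B: int = 100, seed: int | None = None,
                   support_on: "dendropy.Tree | None" = None):
    """NJ tree with bootstrap supports.

    Builds the NJ tree from the full alignment (or annotates
    ``support_on`` if given), then resamples alignment columns ``B``
    times; the support of an internal edge is the fraction of replicate
    NJ trees containing the same bipartition, stored as the child node's
    label.
    """
    if B < 100:
        raise TreeError("B must be >= 100")
    if seed is None:
        raise TreeError("bootstrap requires an explicit seed")
    codes, valid = _encode(alignment)
    labels = alignment.labels

    def tree_from(p):
        vals = p.copy()
        if model_tag != "p":
            it = np.nditer(vals, flags=["multi_index"], op_flags=["readwrite"])
            for v in it:
                v[...] = correct_distance(float(v), model_tag)
        return neighbor_joining(DistanceMatrix(labels=labels, values=vals,
                                               model_tag=model_tag))

    base = support_on if support_on is not None else tree_from(
        _pairwise_p_matrix(codes, valid))
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = codes.shape[1]
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        p = _pairwise_p_matrix(codes[:, cols], valid[:, cols])
        if np.isnan(p).any():
            continue
        for bp in bipartitions(tree_from(p)):
            counts[bp] = counts.get(bp, 0) + 1
    anchor = sorted(l.taxon.label for l in base.leaf_node_iter())[0]
    total = {l.taxon.label for l in base.leaf_node_iter()}
    for node in base.preorder_node_iter():
        if node.is_leaf() or node is base.seed_node:
            continue
        side = {l.taxon.label for l in node.leaf_iter()}
        if anchor in side:
            side = total - side
        node.label = f"{counts.get(frozenset(side), 0) / B:.3f}"
    return base


def node_support(node) -> float | None:
    try:
        return float(node.label)
    except (TypeError, ValueError):
        return None


# ---------------------------------------------------------------------------
# Newick I/O (supports as internal node labels)

def write_newick(tree, path: str | Path) -> None:
    s = tree.as_string(schema="newick", suppress_rooting=True,
                       unquoted_underscores=True)
    Path(path).write_text(s)


def read_newick(path: str | Path):
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:           # dendropy raises several parse types
        raise TreeError(f"newick parse error in {path}: {exc}") from exc
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    dups = {l for l in labels if labels.count(l) > 1}
    if dups:
        raise TreeError(f"duplicate leaf labels: {sorted(dups)}")
    return tree
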