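"""Pairwise and progressive multiple alignment of SRCR domains.

Pairwise alignment is global Needleman–Wunsch with affine gap costs and a
Gonnet-250 substitution matrix (gap open 10.0, gap extension 0.10 — the
classic Clustal protein defaults), delegated to Biopython's
``PairwiseAligner``.  Multiple alignment is progressive: a UPGMA guide tree
over pairwise p-distances orders profile–profile merges scored by
frequency-weighted sum-of-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .srcr_scan import AA, AA_INDEX, DomainModel, _GONNET_ARR


class AlignmentError(ValueError):
    pass


@dataclass
class AlignParams:
    """Alignment parameters.  ``gap_open``/``gap_extend`` are positive
    costs; ``matrix`` names a Biopython substitution matrix.  Terminal gaps
    are penalized by default (``penalize_terminal_gaps=False`` gives
    end-free semi-global alignment)."""

    gap_open: float = 10.0
    gap_extend: float = 0.10
    matrix: str = "GONNET1992"
    penalize_terminal_gaps: bool = True

    def __post_init__(self) -> None:
        if not self.gap_open > self.gap_extend > 0:
            raise AlignmentError("require gap_open > gap_extend > 0")


@dataclass
class DomainAlignment:
    """An alignment: ordered ``(label, aligned_string)`` rows of equal
    length, gaps as ``'-'``."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.rows:
            n = len(self.rows[0][1])
            if any(len(s) != n for _, s in self.rows):
                raise AlignmentError("ragged alignment")

    @property
    def column_count(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.rows]

    def ungapped(self, label: str) -> str:
        for lab, s in self.rows:
            if lab == label:
                return s.replace("-", "")
        raise KeyError(label)

    def row(self, label: str) -> str:
        for lab, s in self.rows:
            if lab == label:
                return s
        raise KeyError(label)

    def subset(self, labels) -> "DomainAlignment":
        want = set(labels)
        return DomainAlignment([(l, s) for l, s in self.rows if l in want])


def read_alignment_fasta(path: str | Path) -> DomainAlignment:
    rows = [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise AlignmentError(f"no rows in {path}")
    return DomainAlignment(rows)


def write_alignment_fasta(alignment: DomainAlignment, path: str | Path,
                          width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for label, s in alignment.rows:
            fh.write(f">{label}\n")
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Pairwise

def _extended_matrix(name: str):
    """Substitution matrix extended with an 'X' row/column scoring 0
    (missing data is alignment-neutral)."""
    base = substitution_matrices.load(name)
    alpha = base.alphabet + "X"
    ext = substitution_matrices.Array(alphabet=alpha, dims=2)
    for a in base.alphabet:
        for b in base.alphabet:
            ext[a, b] = base[a, b]
    return ext


_MATRIX_CACHE: dict[str, object] = {}


def _make_aligner(params: AlignParams) -> PairwiseAligner:
    if params.matrix not in _MATRIX_CACHE:
        _MATRIX_CACHE[params.matrix] = _extended_matrix(params.matrix)
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _MATRIX_CACHE[params.matrix]
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.penalize_terminal_gaps:
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def pairwise_global_align(a: str, b: str,
                          params: AlignParams | None = None,
                          labels: tuple[str, str] = ("a", "b")):
    """Globally align two sequences.

    Returns ``(DomainAlignment, score, percent_identity)``; the identity
    denominator counts only columns where neither row is a gap.  The first
    optimal alignment in the aligner's deterministic enumeration order is
    reported.
    """
    if not a or not b:
        raise AlignmentError("cannot align an empty sequence")
    params = params or AlignParams()
    aligner = _make_aligner(params)
    alns = aligner.align(a.upper(), b.upper())
    aln = alns[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    ident = same = 0
    for x, y in zip(row_a, row_b):
        if x != "-" and y != "-":
            ident += 1
            if x == y:
                same += 1
    pid = 100.0 * same / ident if ident else 0.0
    return (DomainAlignment([(labels[0], row_a), (labels[1], row_b)]),
            float(aln.score), pid)


def pairwise_p_distance(a: str, b: str,
                        params: AlignParams | None = None) -> float:
    """p-distance of the pairwise global alignment (gap/X columns
    excluded), used for guide-tree construction."""
    aln, _, _ = pairwise_global_align(a, b, params)
    ra, rb = aln.rows[0][1], aln.rows[1][1]
    diff = n = 0
    for x, y in zip(ra, rb):
        if x in "-X" or y in "-X":
            continue
        n += 1
        diff += x != y
    return diff / n if n else 1.0


# ---------------------------------------------------------------------------
# Guide tree (UPGMA) and progressive alignment

def _upgma_merges(dist: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic UPGMA agglomeration order on a condensed-style square
    distance matrix; ties resolved by smallest (i, j) index pair.  Returns
    merges as cluster-index pairs where new clusters take index n, n+1, ...
    """
    n = dist.shape[0]
    active = {i: [i] for i in range(n)}
    d = {(min(i, j), max(i, j)): float(dist[i, j])
         for i in range(n) for j in range(i + 1, n)}
    merges = []
    nxt = n
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), _ = best
        members = active[i] + active[j]
        others = [k for k in active if k not in (i, j)]
        for k in others:
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            w = (len(active[i]) * dik + len(active[j]) * djk) / len(members)
            d[(min(nxt, k), max(nxt, k))] = w
        for k in list(d):
            if i in k or j in k:
                del d[k]
        del active[i], active[j]
        active[nxt] = members
        merges.append((i, j))
        nxt += 1
    return merges


def build_guide_tree(seqs: list[tuple[str, str]],
                     params: AlignParams | None = None):
    """UPGMA tree (as a dendropy tree) over pairwise p-distances.

    ``seqs`` is a list of ``(label, sequence)``.
    """
    import dendropy

    if len(seqs) < 2:
        raise AlignmentError("guide tree needs at least 2 sequences")
    labels = [l for l, _ in seqs]
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pairwise_p_distance(
                seqs[i][1], seqs[j][1], params)
    merges = _upgma_merges(dist)

    taxa = dendropy.TaxonNamespace(labels)
    nodes = {i: dendropy.Node(taxon=taxa.get_taxon(labels[i]))
             for i in range(n)}
    nxt = n
    for (i, j) in merges:
        parent = dendropy.Node()
        parent.add_child(nodes.pop(i))
        parent.add_child(nodes.pop(j))
        nodes[nxt] = parent
        nxt += 1
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[nxt - 1]
    tree.is_rooted = True
    return tree


class _Profile:
    """Gapped rows plus per-column residue counts for profile scoring."""

    def __init__(self, rows: list[tuple[str, str]]):
        self.rows = rows
        ncol = len(rows[0][1])
        counts = np.zeros((ncol, 20))
        for _, s in rows:
            for c, ch in enumerate(s):
                k = AA_INDEX.get(ch)
                if k is not None:
                    counts[c, k] += 1
        self.counts = counts

    @property
    def ncol(self) -> int:
        return self.counts.shape[0]

    def freqs(self) -> np.ndarray:
        tot = self.counts.sum(axis=1, keepdims=True)
        return self.counts / np.maximum(tot, 1.0)


def _align_profiles(p1: _Profile, p2: _Profile,
                    params: AlignParams) -> _Profile:
    """Global affine profile–profile alignment; sum-of-pairs scores with
    the Gonnet matrix; diagonal preferred on ties."""
    f1, f2 = p1.freqs(), p2.freqs()
    smat = f1 @ _GONNET_ARR @ f2.T          # (n1, n2)
    n1, n2 = smat.shape
    go, ge = params.gap_open, params.gap_extend
    NEG = -1e30

    M = np.full((n1 + 1, n2 + 1), NEG)
    Ix = np.full((n1 + 1, n2 + 1), NEG)     # gap in p2
    Iy = np.full((n1 + 1, n2 + 1), NEG)     # gap in p1
    M[0, 0] = 0.0
    if params.penalize_terminal_gaps:
        Ix[1:, 0] = -(go + ge * np.arange(n1))
        Iy[0, 1:] = -(go + ge * np.arange(n2))
    else:
        Ix[1:, 0] = 0.0
        Iy[0, 1:] = 0.0
    ptr = {}
    for i in range(1, n1 + 1):
        mprev = M[i - 1]
        xprev = Ix[i - 1]
        # Ix: consume p1 column
        openx = np.maximum(mprev, Iy[i - 1]) - go
        extx = xprev - ge
        Ix[i] = np.maximum(openx, extx)
        # vectorized along j for M; Iy needs a serial scan -> telescoped
        diag = np.maximum(np.maximum(mprev[:-1], xprev[:-1]), Iy[i - 1, :-1])
        M[i, 1:] = diag + smat[i - 1]
        M[i, 0] = NEG
        offs = np.arange(n2) * ge
        base = np.maximum(M[i, :-1], Ix[i, :-1]) + offs
        acc = np.maximum.accumulate(base)
        Iy[i, 1:] = acc - go - offs

    # traceback without explicit pointers: re-derive moves
    rows1 = [list(s) for _, s in p1.rows]
    rows2 = [list(s) for _, s in p2.rows]
    out1: list[list[str]] = [[] for _ in rows1]
    out2: list[list[str]] = [[] for _ in rows2]
    i, j = n1, n2
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            for r, o in zip(rows1, out1):
                o.append(r[i - 1])
            for r, o in zip(rows2, out2):
                o.append(r[j - 1])
            prevs = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            state = int(np.argmax(prevs))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            for r, o in zip(rows1, out1):
                o.append(r[i - 1])
            for o in out2:
                o.append("-")
            came_ext = abs(Ix[i, j] - (Ix[i - 1, j] - ge)) < eps
            i -= 1
            if came_ext:
                state = 1
            else:
                state = 0 if M[i, j] >= Iy[i, j] else 2
        elif state == 2 and j > 0:
            for o in out1:
                o.append("-")
            for r, o in zip(rows2, out2):
                o.append(r[j - 1])
            came_ext = abs(Iy[i, j] - (Iy[i, j - 1] - ge)) < eps
            j -= 1
            if came_ext:
                state = 2
            else:
                state = 0 if M[i, j] >= Ix[i, j] else 1
        elif i > 0:
            state = 1
        else:
            state = 2
    merged = (
        [(lab, "".join(reversed(o))) for (lab, _), o in zip(p1.rows, out1)]
        + [(lab, "".join(reversed(o))) for (lab, _), o in zip(p2.rows, out2)]
    )
    return _Profile(merged)


def progressive_align(seqs: list[tuple[str, str]],
                      params: AlignParams | None = None) -> DomainAlignment:
    """Progressively align sequences along a UPGMA guide order.

    Every output row ungaps to its input sequence; input row order is
    preserved in the output.
    """
    params = params or AlignParams()
    if len(seqs) < 2:
        raise AlignmentError("need at least 2 sequences")
    labels = [l for l, _ in seqs]
    if len(set(labels)) != len(labels):
        raise AlignmentError("duplicate sequence labels")
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = pairwise_p_distance(
                seqs[i][1], seqs[j][1], params)
    merges = _upgma_merges(dist)
    profiles: dict[int, _Profile] = {
        i: _Profile([(labels[i], seqs[i][1].upper())]) for i in range(n)
    }
    nxt = n
    for (i, j) in merges:
        profiles[nxt] = _align_profiles(profiles.pop(i), profiles.pop(j),
                                        params)
        nxt += 1
    final = profiles[nxt - 1]
    by_label = dict(final.rows)
    aln = DomainAlignment([(lab, by_label[lab]) for lab in labels])
    for lab, seq in seqs:
        assert aln.ungapped(lab) == seq.upper(), f"ungap identity lost: {lab}"
    return aln


def trim_to_core(alignment: DomainAlignment, model: DomainModel,
                 reference_label: str | None = None) -> DomainAlignment:
    """Project an alignment onto the model's core columns via a reference
    row whose ungapped sequence is a model core sequence (length
    ``core_length``).  Returns exactly ``core_length`` columns.
    """
    if reference_label is None:
        for lab, s in alignment.rows:
            if len(s.replace("-", "")) == model.core_length:
                reference_label = lab
                break
        else:
            raise AlignmentError("no reference row of core length present")
    try:
        ref_row = alignment.row(reference_label)
    except KeyError:
        raise AlignmentError(
            f"no reference row {reference_label!r} in alignment") from None
    if len(ref_row.replace("-", "")) != model.core_length:
        raise AlignmentError(
            f"reference row {reference_label} does not span the model core")
    keep = [c for c, ch in enumerate(ref_row) if ch != "-"]
    rows = [(lab, "".join(s[c] for c in keep)) for lab, s in alignment.rows]
    return DomainAlignment(rows)
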