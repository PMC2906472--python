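"""Detection of group-B SRCR domains in receptor proteins.

A :class:`DomainModel` is a positional score profile over a fixed number of
consensus core columns (default 78), built from a reference alignment of
letter-labelled group-B SRCR domains.  The group-B scaffold carries eight
cysteines forming the disulfide bonds (1,4), (2,7), (3,8) and (5,6);
individual domains may lose one or more of these (most commonly C2 and C7,
dropping one bond) and are still reported, with the loss catalogued.

Scanning aligns the entire profile to substrings of a protein
("glocal": free ends in the protein, the whole core consumed) with affine
gap costs, and tiles the protein greedily with non-overlapping hits whose
score clears a threshold expressed as a fraction of the model's self-match
score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .core_io import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

#: Disulfide pairing of the eight group-B cysteines, by cysteine ordinal.
DISULFIDE_PAIRS = frozenset({(1, 4), (2, 7), (3, 8), (5, 6)})

_GONNET = substitution_matrices.load("GONNET1992")
_GONNET_ARR = np.array(
    [[float(_GONNET[a, b]) for b in AA] for a in AA]
)


class ScanError(ValueError):
    pass


@dataclass
class DomainModel:
    """Positional profile for the group-B SRCR domain core.

    ``profile[c, r]`` is the score (Gonnet matrix units) for residue ``r``
    at core column ``c``: the reference-frequency-weighted substitution
    score, the classic profile/sequence scoring of progressive aligners.
    """

    profile: np.ndarray                  # (core_length, 20) scores
    frequencies: np.ndarray              # (core_length, 20) residue freqs
    cys_columns: dict[int, int]          # cysteine ordinal 1..8 -> core column (0-based)
    core_length: int = 78
    min_domain_span: int = 78
    max_domain_span: int = 110
    edge_slack: int = 6
    gap_open: float = 12.0
    gap_extend: float = 1.0
    disulfide_pairs: frozenset = DISULFIDE_PAIRS

    def __post_init__(self) -> None:
        if len(self.cys_columns) != 8:
            raise ScanError("group-B model requires exactly 8 cysteine columns")
        cols = [self.cys_columns[i] for i in range(1, 9)]
        if cols != sorted(cols) or len(set(cols)) != 8:
            raise ScanError("cysteine columns must be strictly increasing")
        if self.core_length <= max(cols):
            raise ScanError("core_length smaller than last cysteine column")

    @property
    def self_score(self) -> float:
        """Score of the best-matching residue at every core column."""
        return float(self.profile.max(axis=1).sum())


@dataclass
class DomainHit:
    """A located SRCR domain: 1-based inclusive protein coordinates, the
    per-core-column residue mapping, and the cysteine census."""

    protein_id: str
    domain_index: int
    start: int
    end: int
    score: float
    core_mapping: list[str]              # per core column: residue or '-'
    cys_present: frozenset = field(default_factory=frozenset)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def group_call(self) -> str:
        n_missing = 8 - len(self.cys_present)
        if n_missing == 0:
            return "B"
        if n_missing <= 4:
            return "B_atypical"
        return "A_like"


def build_domain_model(reference_alignment, pseudocount: float = 0.5,
                       **model_kwargs) -> DomainModel:
    """Build a :class:`DomainModel` from a reference domain alignment.

    Column residue frequencies get a uniform pseudocount; the eight
    cysteine columns are those where cysteine is the modal residue with
    frequency >= 0.5 (majority rule, so a single reference domain missing
    a cysteine does not delete the column).
    """
    rows = [aligned for _, aligned in reference_alignment.rows]
    if len(rows) < 2:
        raise ScanError("reference alignment needs at least 2 rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ScanError("ragged reference alignment")

    counts = np.zeros((ncol, 20))
    for row in rows:
        for c, ch in enumerate(row.upper()):
            if ch in AA_INDEX:
                counts[c, AA_INDEX[ch]] += 1
    # drop columns that are mostly gap: keep columns with >=50% residues
    occupancy = counts.sum(axis=1)
    keep = occupancy >= 0.5 * len(rows)
    counts = counts[keep]
    freqs = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True)
                                      + 20 * pseudocount)

    raw = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
    c_idx = AA_INDEX["C"]
    modal = raw.argmax(axis=1)
    cys_cand = [c for c in range(len(raw))
                if modal[c] == c_idx and raw[c, c_idx] >= 0.5]
    if len(cys_cand) < 8:
        raise ScanError(
            "not a group-B reference: fewer than 8 conserved-cysteine columns"
        )
    if len(cys_cand) > 8:
        cys_cand = sorted(sorted(cys_cand, key=lambda c: -raw[c, c_idx])[:8])
    cys_columns = {i + 1: col for i, col in enumerate(cys_cand)}

    profile = freqs @ _GONNET_ARR
    return DomainModel(profile=profile, frequencies=freqs,
                       cys_columns=cys_columns, core_length=len(profile),
                       **model_kwargs)


def _glocal_align(model: DomainModel, seq: str):
    """Align the full profile to the best-scoring substring of ``seq``.

    Returns ``(score, start0, end0, core_mapping)`` with 0-based inclusive
    substring coordinates, or ``None`` for an empty sequence.  Affine gap
    costs apply to unmatched core columns (deletions) and to protein
    residues inserted between core columns.  The best end position with the
    smallest start wins ties, so results are deterministic.
    """
    n, L = model.core_length, len(seq)
    if L == 0:
        return None
    sidx = np.array([AA_INDEX.get(ch, -1) for ch in seq])
    # residue scores; 'X' (missing data) scores 0 against every column
    smat = np.zeros((n, L))
    valid = sidx >= 0
    smat[:, valid] = model.profile[:, sidx[valid]]

    NEG = -1e30
    go, ge = model.gap_open, model.gap_extend
    M = np.full((n + 1, L + 1), NEG)
    Ix = np.full((n + 1, L + 1), NEG)   # gap in protein (core column deleted)
    Iy = np.full((n + 1, L + 1), NEG)   # insertion in protein
    M[0, :] = 0.0                       # free start anywhere in the protein
    ptrM = np.zeros((n + 1, L + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, L + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, L + 1), dtype=np.int8)

    for i in range(1, n + 1):
        # Ix: consume a core column without a protein residue
        fromM = M[i - 1, :] - go
        fromX = Ix[i - 1, :] - ge
        Ix[i, :] = np.maximum(fromM, fromX)
        ptrX[i, :] = (fromX > fromM).astype(np.int8)   # 0 from M, 1 from Ix

        prev = np.maximum(M[i - 1, :-1], Ix[i - 1, :-1])
        diag = np.where(M[i - 1, :-1] >= Ix[i - 1, :-1], 0, 1)
        prevY = Iy[i - 1, :-1]
        best = np.where(prevY > prev, prevY, prev)
        ptrM[i, 1:] = np.where(prevY > prev, 2, diag)
        M[i, 1:] = best + smat[i - 1, :]

        # Iy: consume protein residues between core columns.  The affine
        # row recurrence Iy[j] = max(M[j-1]-go, Iy[j-1]-ge) telescopes to a
        # running maximum of M[j]+j*ge, so one cumulative-max scan per row
        # replaces the serial loop.
        offs = np.arange(L) * ge
        base = M[i, :-1] + offs
        acc = np.maximum.accumulate(base)
        Iy[i, 1:] = acc - go - offs
        ptrY[i, 1:] = (acc > base).astype(np.int8)   # 1: extend, 0: open

    endrow = np.maximum(M[n, :], Ix[n, :])
    j_end = int(np.argmax(endrow))
    score = float(endrow[j_end])
    state = 0 if M[n, j_end] >= Ix[n, j_end] else 1

    # traceback
    mapping = ["-"] * n
    i, j = n, j_end
    end0 = j_end - 1
    while i > 0:
        if state == 0:      # M
            mapping[i - 1] = seq[j - 1]
            state = int(ptrM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:    # Ix: core column i unmatched
            came = ptrX[i, j]
            i = i - 1
            state = 1 if came == 1 else 0
        else:               # Iy: protein residue j inserted
            came = ptrY[i, j]
            j = j - 1
            state = 2 if came == 1 else 0
    start0 = j
    if end0 < start0:
        return None
    return score, start0, end0, mapping


def scan_protein(record: ProteinRecord, model: DomainModel,
                 score_threshold: float | None = None) -> list[DomainHit]:
    """Tile a protein with non-overlapping SRCR domain hits.

    Repeatedly aligns the profile to every not-yet-consumed interval,
    accepts the best-scoring candidate (ties: smaller start) whose score
    reaches the threshold (default 40% of the model self-match score) and
    whose span lies within the model's domain-length window, consumes it
    and recurses into the flanking intervals.  Hits come back sorted
    N-to-C with consecutive ``domain_index`` and the per-hit cysteine
    census read off the core mapping.
    """
    if score_threshold is None:
        score_threshold = 0.40 * model.self_score
    lo = model.min_domain_span - model.edge_slack
    hi = model.max_domain_span + model.edge_slack

    seq = record.sequence
    intervals = [(0, len(seq))]          # half-open [a, b)
    accepted: list[tuple[int, int, float, list[str]]] = []
    cache: dict[tuple[int, int], tuple | None] = {}

    while intervals:
        best = None
        for (a, b) in intervals:
            if b - a < lo:
                continue
            if (a, b) not in cache:
                res = _glocal_align(model, seq[a:b])
                cache[(a, b)] = res
            res = cache[(a, b)]
            if res is None:
                continue
            score, s0, e0, mapping = res
            cand = (score, -(a + s0), (a, b), a + s0, a + e0, mapping)
            if best is None or cand[:2] > best[:2]:
                best = cand
        if best is None:
            break
        score, _, (a, b), s0, e0, mapping = best
        intervals.remove((a, b))
        if score < score_threshold:
            continue                      # nothing acceptable in this interval
        span = e0 - s0 + 1
        if lo <= span <= hi:
            accepted.append((s0, e0, score, mapping))
            if s0 - a >= lo:
                intervals.append((a, s0))
            if b - (e0 + 1) >= lo:
                intervals.append((e0 + 1, b))
        # an out-of-window best hit exhausts its interval (never recursed:
        # real SRCR arrays do not nest domains inside spurious matches)

    accepted.sort(key=lambda h: h[0])
    hits = []
    for k, (s0, e0, score, mapping) in enumerate(accepted, start=1):
        cys = frozenset(
            ordinal for ordinal, col in model.cys_columns.items()
            if mapping[col] == "C"
        )
        hits.append(DomainHit(
            protein_id=record.id, domain_index=k,
            start=s0 + 1, end=e0 + 1, score=score,
            core_mapping=mapping, cys_present=cys,
        ))
    return hits


def cysteine_pattern(hit: DomainHit):
    """Return ``(missing, intact_disulfides, group_call)`` for a hit.

    A disulfide bond is counted intact only when both partner cysteines
    are present; losing C2 and C7 (the most frequent atypia) removes one
    of the four bonds.
    """
    missing = frozenset(range(1, 9)) - hit.cys_present
    intact = frozenset(
        (a, b) for (a, b) in DISULFIDE_PAIRS
        if a in hit.cys_present and b in hit.cys_present
    )
    return missing, intact, hit.group_call
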