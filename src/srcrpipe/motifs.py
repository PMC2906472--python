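"""Transmembrane/cytoplasmic partitioning and tyrosine-motif scanning.

Transmembrane segments are called from sliding-window Kyte–Doolittle
hydropathy (a transparent, scriptable rule; externally determined
coordinates can be supplied instead and are passed through untouched).
The cytoplasmic tail is everything C-terminal to the last TM segment.
The WC1-type signalling motif is the tyrosine tetramer
Y-(Q/E)-(D/C/E)-(I/L); near-misses with threonine in the fourth position
are reported separately and never counted as motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core_io import ProteinRecord

#: Kyte–Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

WC1_MOTIF_RE = re.compile(r"(?=(Y[QE][DCE][IL]))")
WC1_NEAR_MISS_RE = re.compile(r"(?=(Y[QE][DCE]T))")


class TopologyError(ValueError):
    pass


@dataclass
class TopologyCall:
    """Membrane topology of one protein: sorted non-overlapping TM
    segments (1-based inclusive) and the first cytoplasmic position."""

    protein_id: str
    tm_regions: list[tuple[int, int]]
    source: str = "predicted"          # predicted | user_supplied
    note: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for (s, e) in self.tm_regions:
            if s <= prev_end:
                raise TopologyError(
                    f"{self.protein_id}: TM regions overlap or unsorted")
            if not (s <= e):
                raise TopologyError(f"{self.protein_id}: bad TM {s}..{e}")
            prev_end = e

    @property
    def cytoplasmic_start(self) -> int | None:
        if not self.tm_regions:
            return None
        return self.tm_regions[-1][1] + 1


@dataclass
class MotifHit:
    """A tyrosine-motif occurrence: 1-based position of the tyrosine (or
    motif start for literal patterns) and its sequence context."""

    protein_id: str
    position: int
    tetramer: str
    pattern_id: str                    # "wc1_like" | "wc1_near_miss" | "literal:<motif>"
    region: str = "other"              # cytoplasmic | other


def predict_tm(record: ProteinRecord, window: int = 19,
               threshold: float = 1.6) -> TopologyCall:
    """Predict TM segments by mean Kyte–Doolittle hydropathy over a
    sliding window.

    Window centres whose mean hydropathy reaches ``threshold`` seed
    candidate cores; overlapping windows merge, and each merged segment is
    reported over the full extent of its contributing windows (so a
    single seed already spans ``window`` residues).  A protein shorter
    than the window gets an empty, flagged call.
    """
    seq = record.sequence
    if len(seq) < window:
        return TopologyCall(record.id, [], source="predicted",
                            note="sequence shorter than window; no TM call")
    h = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in seq])
    means = np.convolve(h, np.ones(window) / window, mode="valid")
    half = window // 2
    # hot[c]: the window centred on residue c+half (0-based) clears the cutoff
    hot = means >= threshold
    regions: list[tuple[int, int]] = []
    k = 0
    n = len(hot)
    while k < n:
        if hot[k]:
            j = k
            while j + 1 < n and hot[j + 1]:
                j += 1
            s, e = k + half + 1, j + half + 1     # 1-based hot-centre run
            if e - s + 1 < window:                # pad to the window minimum
                pad = window - (e - s + 1)
                s = max(1, s - (pad + 1) // 2)
                e = min(len(seq), s + window - 1)
                s = max(1, e - window + 1)
            if regions and s <= regions[-1][1]:
                regions[-1] = (regions[-1][0], max(regions[-1][1], e))
            else:
                regions.append((s, e))
            k = j + 1
        else:
            k += 1
    return TopologyCall(record.id, regions, source="predicted")


def user_topology(record: ProteinRecord,
                  tm_regions: list[tuple[int, int]]) -> TopologyCall:
    """Wrap externally determined TM coordinates (passthrough)."""
    return TopologyCall(record.id, sorted(tm_regions),
                        source="user_supplied")


def cytoplasmic_domain(record: ProteinRecord,
                       topology: TopologyCall) -> str:
    """Residues C-terminal to the last TM segment (may be empty)."""
    if not topology.tm_regions:
        raise TopologyError(
            f"{record.id}: no transmembrane region, no cytoplasmic domain")
    return record.sequence[topology.tm_regions[-1][1]:]


def scan_wc1_motif(seq: str, protein_id: str = "",
                   topology: TopologyCall | None = None) -> list[MotifHit]:
    """All (overlapping) WC1-type Y-(Q/E)-(D/C/E)-(I/L) tetramers, plus
    threonine near-misses tagged ``wc1_near_miss`` (informational only)."""
    seq = seq.upper()
    hits = []
    for pattern_id, rx in (("wc1_like", WC1_MOTIF_RE),
                           ("wc1_near_miss", WC1_NEAR_MISS_RE)):
        for m in rx.finditer(seq):
            pos = m.start() + 1
            hits.append(MotifHit(
                protein_id=protein_id, position=pos,
                tetramer=m.group(1), pattern_id=pattern_id,
                region=_region(pos, topology),
            ))
    hits.sort(key=lambda h: (h.position, h.pattern_id))
    return hits


def find_literal_motifs(seq: str, motifs, protein_id: str = "",
                        topology: TopologyCall | None = None
                        ) -> list[MotifHit]:
    """All exact occurrences of each literal motif (overlaps included)."""
    seq = seq.upper()
    hits = []
    for motif in motifs:
        if not motif or motif != motif.upper():
            raise ValueError(f"motifs must be non-empty uppercase: {motif!r}")
        start = 0
        while True:
            k = seq.find(motif, start)
            if k < 0:
                break
            pos = k + 1
            hits.append(MotifHit(
                protein_id=protein_id, position=pos, tetramer=motif,
                pattern_id=f"literal:{motif}",
                region=_region(pos, topology),
            ))
            start = k + 1
    hits.sort(key=lambda h: (h.position, h.pattern_id))
    return hits


def _region(position: int, topology: TopologyCall | None) -> str:
    if topology is None or topology.cytoplasmic_start is None:
        return "other"
    return ("cytoplasmic" if position >= topology.cytoplasmic_start
            else "other")
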