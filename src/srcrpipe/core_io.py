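"""Sequence and annotation I/O and the shared record types.

Every pipeline stage exchanges :class:`ProteinRecord` objects (plain
amino-acid sequences with an identifier and a species tag) and
:class:`DomainAnnotationTable` objects (per-protein SRCR-domain coordinates,
nomenclature letters and cysteine status).  All coordinates written to or
read from disk are 1-based inclusive positions on the protein.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids plus 'X' for unknown/missing residues
#: (several comparison proteins are conceptual translations of genomic
#: predictions, where assembly gaps surface as 'X').
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_ANNOT_COLUMNS = [
    "protein_id", "domain_index", "start", "end",
    "score", "letter", "missing_cysteines",
]


class CoreIOError(ValueError):
    """Raised for malformed sequence or annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    Parameters
    ----------
    id : str
        Short unique token, e.g. ``"BtCD163A"``.
    sequence : str
        Uppercase amino acids over the 20-letter alphabet plus ``X``.
    species : str
        Free-text species tag (``"Bt"``, ``"Hs"``, ...).
    description : str
        Free text carried through to FASTA output.
    """

    id: str
    sequence: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise CoreIOError("protein record requires a non-empty id")
        if len(self.sequence) < 1:
            raise CoreIOError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_RESIDUES:
                raise CoreIOError(
                    f"{self.id}: illegal residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DomainAnnotationTable:
    """Rows of located SRCR domains, one table per dataset.

    Each row holds ``(protein_id, domain_index, start, end, score, letter,
    missing_cysteines)``; ``domain_index`` is the 1-based N-to-C ordinal
    (the roman numerals of domain diagrams), ``start``/``end`` are 1-based
    inclusive protein coordinates, ``letter`` is a nomenclature letter or
    ``"undesignated"`` and ``missing_cysteines`` a subset of {1..8}.
    """

    rows: list[dict] = field(default_factory=list)

    def add(self, protein_id: str, domain_index: int, start: int, end: int,
            score: float = 0.0, letter: str = "undesignated",
            missing_cysteines: Iterable[int] = ()) -> None:
        self.rows.append({
            "protein_id": protein_id,
            "domain_index": int(domain_index),
            "start": int(start),
            "end": int(end),
            "score": float(score),
            "letter": letter,
            "missing_cysteines": frozenset(int(c) for c in missing_cysteines),
        })

    def validate(self, lengths: dict[str, int] | None = None) -> None:
        """Check per-protein ordering, coordinate sanity and index gaps."""
        by_protein: dict[str, list[dict]] = {}
        for r in self.rows:
            by_protein.setdefault(r["protein_id"], []).append(r)
        for pid, rs in by_protein.items():
            rs = sorted(rs, key=lambda r: r["domain_index"])
            if [r["domain_index"] for r in rs] != list(range(1, len(rs) + 1)):
                raise CoreIOError(f"{pid}: domain_index not consecutive from 1")
            prev_end = 0
            for r in rs:
                if not (1 <= r["start"] <= r["end"]):
                    raise CoreIOError(f"{pid}: bad coordinates {r['start']}..{r['end']}")
                if r["start"] <= prev_end:
                    raise CoreIOError(f"{pid}: overlapping/unsorted domains")
                prev_end = r["end"]
                if lengths is not None and r["end"] > lengths[pid]:
                    raise CoreIOError(f"{pid}: domain end beyond protein length")
                if not r["missing_cysteines"] <= frozenset(range(1, 9)):
                    raise CoreIOError(f"{pid}: missing_cysteines outside 1..8")

    def for_protein(self, protein_id: str) -> list[dict]:
        rs = [r for r in self.rows if r["protein_id"] == protein_id]
        return sorted(rs, key=lambda r: r["domain_index"])

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = dict(r)
            rec["missing_cysteines"] = ",".join(
                str(c) for c in sorted(r["missing_cysteines"])
            )
            recs.append(rec)
        return pd.DataFrame(recs, columns=_ANNOT_COLUMNS)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DomainAnnotationTable):
            return NotImplemented
        return self.rows == other.rows


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly multi-line, possibly lowercase) protein FASTA file.

    Sequences are uppercased; entry order is preserved.  Raises
    :class:`CoreIOError` on an empty file, duplicate IDs, or illegal
    residue characters (reported with their 1-based position).
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise CoreIOError(f"duplicate FASTA id: {rec.id}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        species = _species_from_id(rec.id)
        records.append(ProteinRecord(
            id=rec.id, sequence=str(rec.seq).upper(),
            species=species, description=desc,
        ))
    if not records:
        raise CoreIOError(f"no records in {path}")
    return records


def _species_from_id(token: str) -> str:
    """Leading capital+lowercase run of an id is used as the species tag
    (the 'Bt'/'Hs'/'Gg' convention of comparative SRCR datasets)."""
    m = re.match(r"([A-Z][a-z]+)", token)
    return m.group(1) if m else ""


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA with sequence lines wrapped at ``width``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Domain annotations (TSV / GFF3)

def write_domain_annotations(table: DomainAnnotationTable, path: str | Path,
                             format: str = "tsv") -> None:
    """Write a domain annotation table as TSV or GFF3.

    TSV carries one header plus one row per domain.  GFF3 writes one
    ``SRCR_domain`` feature per domain with 1-based inclusive coordinates
    and the letter plus missing-cysteine set in the attributes column.
    """
    path = Path(path)
    table.validate()
    if format == "tsv":
        table.to_frame().to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for r in sorted(table.rows,
                            key=lambda r: (r["protein_id"], r["domain_index"])):
                miss = ",".join(str(c) for c in sorted(r["missing_cysteines"]))
                attrs = (f"ID={r['protein_id']}.SRCR{r['domain_index']};"
                         f"letter={r['letter']};missing_cysteines={miss}")
                fh.write("\t".join([
                    r["protein_id"], "srcrpipe", "SRCR_domain",
                    str(r["start"]), str(r["end"]), f"{r['score']:.2f}",
                    ".", ".", attrs,
                ]) + "\n")
    else:
        raise CoreIOError(f"unknown annotation format: {format!r}")


def read_domain_annotations(path: str | Path) -> DomainAnnotationTable:
    """Read back a TSV annotation table written by
    :func:`write_domain_annotations`."""
    df = pd.read_csv(path, sep="\t", dtype={"letter": str},
                     keep_default_na=False)
    table = DomainAnnotationTable()
    for _, row in df.iterrows():
        miss = str(row["missing_cysteines"])
        cys = [int(c) for c in miss.split(",") if c.strip()]
        table.add(row["protein_id"], int(row["domain_index"]),
                  int(row["start"]), int(row["end"]), float(row["score"]),
                  str(row["letter"]), cys)
    table.validate()
    return table
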