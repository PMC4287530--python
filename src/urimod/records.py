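"""Annotated tRNA records: parsing, writing, and per-position resolution.

A record's sequence is written over modification-nomenclature codes, one
character per nucleotide, so a single string carries both the sequence and
its modification annotation (``GYU`` is G, pseudouridylated U, U).

The on-disk dialect is two lines per record::

    >id|organism|kingdom|compartment
    GCGGAUUYAGCUC...

``kingdom`` and ``compartment`` may be empty; a taxonomy map passed to
:func:`parse_records` can fill them in by organism. An optional structure
string (same length as the sequence) is attached separately — see
:mod:`urimod.structures`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .nomenclature import NomenclatureTable

logger = logging.getLogger(__name__)

KINGDOMS = ("archaea", "bacteria", "eukaryote", "virus")
COMPARTMENTS = ("cytosol", "mitochondrion", "plastid", "none")


@dataclass
class AnnotatedTRNA:
    """One modification-annotated tRNA sequence with taxonomy labels."""

    id: str
    organism: str = ""
    kingdom: str | None = None  # one of KINGDOMS, or None if unknown
    compartment: str | None = None  # one of COMPARTMENTS, or None
    sequence: str = ""
    structure: str | None = None
    structure_dialect: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.kingdom is not None and self.kingdom not in KINGDOMS:
            raise ValueError(
                f"record {self.id!r}: kingdom {self.kingdom!r} not in {KINGDOMS}"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"record {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )
        if self.structure is not None and len(self.structure) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: structure length {len(self.structure)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResolvedBase:
    """Resolution of one sequence position against a nomenclature table."""

    position: int  # 0-based
    parent: str  # A, C, G, U, or "other"
    modified: bool
    code: str  # the original character


def resolve(
    record: AnnotatedTRNA, table: NomenclatureTable
) -> list[ResolvedBase]:
    """Resolve every position of *record* to (parent base, modified?).

    Codes absent from *table* get ``parent="other"``, ``modified=False``
    and are counted in a warning; they are never fatal.
    """
    out: list[ResolvedBase] = []
    n_unknown = 0
    for i, code in enumerate(record.sequence):
        entry = table.get(code)
        if entry is None:
            out.append(ResolvedBase(i, "other", False, code))
            n_unknown += 1
        else:
            out.append(ResolvedBase(i, entry.parent, entry.modified, code))
    if n_unknown:
        logger.warning(
            "record %s: %d character(s) not in the nomenclature table",
            record.id,
            n_unknown,
        )
    return out


def demodified_sequence(record: AnnotatedTRNA, table: NomenclatureTable) -> str:
    """Sequence with every code replaced by its parent base.

    Unknown codes become ``X`` so the five-letter window alphabet
    {A, C, G, U, X} stays closed.
    """
    parents = []
    for base in resolve(record, table):
        parents.append(base.parent if base.parent != "other" else "X")
    return "".join(parents)


def parse_records(
    path: str | Path,
    taxonomy: Mapping[str, tuple[str, str]] | None = None,
) -> list[AnnotatedTRNA]:
    """Parse annotated-sequence text into records, in file order.

    *taxonomy* maps organism name → (kingdom, compartment) and fills in
    labels missing from the headers; organisms absent from the map leave
    kingdom/compartment unset with a warning. Raises ``ValueError`` on an
    empty file.
    """
    path = Path(path)
    records: list[AnnotatedTRNA] = []
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not seq_parts:
            raise ValueError(f"{path}: record {header!r} has no sequence line")
        records.append(_record_from_header(header, "".join(seq_parts), taxonomy))

    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            flush()
            header = line[1:]
            seq_parts = []
        else:
            if header is None:
                raise ValueError(f"{path}: sequence line before any header")
            seq_parts.append(line)
    flush()
    if not records:
        raise ValueError(f"{path}: no records found")
    return records


def _record_from_header(
    header: str,
    sequence: str,
    taxonomy: Mapping[str, tuple[str, str]] | None,
) -> AnnotatedTRNA:
    fields = [f.strip() for f in header.split("|")]
    fields += [""] * (4 - len(fields))
    rec_id, organism, kingdom, compartment = fields[:4]
    if not kingdom and taxonomy is not None:
        if organism in taxonomy:
            kingdom, compartment = taxonomy[organism]
        else:
            logger.warning(
                "organism %r not in taxonomy map; record %s left unassigned",
                organism,
                rec_id,
            )
    return AnnotatedTRNA(
        id=rec_id,
        organism=organism,
        kingdom=kingdom or None,
        compartment=compartment or None,
        sequence=sequence,
    )


def write_records(records: Sequence[AnnotatedTRNA], path: str | Path) -> None:
    """Write records in the two-line annotated dialect read by parse_records."""
    lines = []
    for rec in records:
        header = "|".join(
            [rec.id, rec.organism, rec.kingdom or "", rec.compartment or ""]
        )
        lines.append(f">{header}")
        lines.append(rec.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path: str | Path) -> list[AnnotatedTRNA]:
    """Read plain (unannotated) tRNA sequences from FASTA.

    ``T`` in FASTA input is read as thymidine-as-uridine only if the caller
    transcribes first; here sequences are taken verbatim, so DNA-alphabet
    input should be converted with ``str.replace("T", "U")`` beforehand.
    """
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            AnnotatedTRNA(id=seq_rec.id, sequence=str(seq_rec.seq))
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[AnnotatedTRNA], path: str | Path) -> None:
    lines = []
    for rec in records:
        lines.append(f">{rec.id}")
        lines.append(rec.sequence)
    Path(path).write_text("\n".join(lines) + "\n")


def with_structure(record: AnnotatedTRNA, structure: str, dialect: str) -> AnnotatedTRNA:
    """A copy of *record* with a structure string attached (length-checked)."""
    return replace(record, structure=structure, structure_dialect=dialect)
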