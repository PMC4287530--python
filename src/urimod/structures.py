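"""Secondary-structure strings for tRNA records.

Three dialects are understood, named after the predictors that emit them:

* ``rnafold`` — dot-bracket: ``(`` ``)`` ``.``
* ``ipknot``  — dot-bracket with pseudoknot square brackets: ``(`` ``)``
  ``[`` ``]`` ``.``
* ``trnascan`` — angle brackets: ``<`` ``>`` ``.``

The terminal dummy symbol ``X`` belongs to every alphabet but is added
only by window padding, never accepted in input structures. Pseudoknot
bracket tiers beyond square brackets are folded into ``.`` with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .records import AnnotatedTRNA, with_structure

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureDialect:
    name: str
    alphabet: tuple[str, ...]  # ordered; X always last

    @property
    def input_symbols(self) -> tuple[str, ...]:
        """Symbols legal in an input structure string (everything but X)."""
        return self.alphabet[:-1]


RNAFOLD = StructureDialect("rnafold", ("(", ")", ".", "X"))
TRNASCAN = StructureDialect("trnascan", ("<", ">", ".", "X"))
IPKNOT = StructureDialect("ipknot", ("(", ")", "[", "]", ".", "X"))

DIALECTS: dict[str, StructureDialect] = {
    d.name: d for d in (RNAFOLD, TRNASCAN, IPKNOT)
}

# deeper pseudoknot tiers some predictors emit; folded into '.'
_EXTRA_BRACKETS = set("{}<>AaBbCc")


def get_dialect(name: str) -> StructureDialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ValueError(
            f"unknown structure dialect {name!r}; expected one of {sorted(DIALECTS)}"
        ) from None


def attach_structure(
    record: AnnotatedTRNA, structure: str, dialect: str | StructureDialect
) -> AnnotatedTRNA:
    """Return *record* with *structure* attached after validation.

    The structure must match the sequence length exactly and use only the
    dialect's input alphabet. Deeper pseudoknot brackets are folded into
    ``.`` with a warning (only for dialects where they are not already
    legal symbols).
    """
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    if not structure:
        raise ValueError(f"record {record.id!r}: empty structure string")
    if len(structure) != len(record.sequence):
        raise ValueError(
            f"record {record.id!r}: structure length {len(structure)} does "
            f"not match sequence length {len(record.sequence)}"
        )
    legal = set(dialect.input_symbols)
    cleaned = []
    folded = 0
    for pos, sym in enumerate(structure):
        if sym in legal:
            cleaned.append(sym)
        elif sym in _EXTRA_BRACKETS and dialect.name == "ipknot":
            cleaned.append(".")
            folded += 1
        else:
            raise ValueError(
                f"record {record.id!r}: illegal structure symbol {sym!r} at "
                f"position {pos + 1} for dialect {dialect.name!r}"
            )
    if folded:
        logger.warning(
            "record %s: folded %d pseudoknot symbol(s) beyond square "
            "brackets into '.'",
            record.id,
            folded,
        )
    return with_structure(record, "".join(cleaned), dialect.name)


def load_paired_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Read a paired sequence/structure file.

    Format: optional ``#dialect: NAME`` comment, then per record a ``>id``
    header followed by exactly one sequence line and one structure line.
    Returns (id, sequence, structure) tuples in file order.
    """
    path = Path(path)
    tuples: list[tuple[str, str, str]] = []
    current: list[str] = []  # [id, seq?, struct?]
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if current:
                if len(current) != 3:
                    raise ValueError(
                        f"{path}: record {current[0]!r} lacks a "
                        f"{'sequence' if len(current) == 1 else 'structure'} line"
                    )
                tuples.append(tuple(current))
            current = [line[1:].split("|")[0].strip()]
        else:
            if not current:
                raise ValueError(f"{path}: data line before any header")
            if len(current) >= 3:
                raise ValueError(
                    f"{path}: record {current[0]!r} has more than two data lines"
                )
            current.append(line)
    if current:
        if len(current) != 3:
            raise ValueError(
                f"{path}: record {current[0]!r} lacks a "
                f"{'sequence' if len(current) == 1 else 'structure'} line"
            )
        tuples.append(tuple(current))
    if not tuples:
        raise ValueError(f"{path}: no records found")
    return tuples


def read_paired_dialect(path: str | Path, default: str = "trnascan") -> str:
    """The ``#dialect:`` declaration of a paired file, or *default*."""
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line.lower().startswith("#dialect:"):
            return line.split(":", 1)[1].strip()
        if line and not line.startswith("#"):
            break
    return default


def attach_from_paired_file(
    records: Sequence[AnnotatedTRNA], path: str | Path, dialect: str | None = None
) -> list[AnnotatedTRNA]:
    """Attach structures from a paired file to matching records by id.

    Records with no structure in the file are returned unchanged.
    """
    if dialect is None:
        dialect = read_paired_dialect(path)
    by_id = {rid: (seq, struct) for rid, seq, struct in load_paired_file(path)}
    out = []
    for rec in records:
        if rec.id in by_id:
            _, struct = by_id[rec.id]
            out.append(attach_structure(rec, struct, dialect))
        else:
            out.append(rec)
    return out


def partition_by_structure(
    records: Iterable[AnnotatedTRNA],
) -> tuple[list[AnnotatedTRNA], list[AnnotatedTRNA]]:
    """Split records into (with_structure, without_structure).

    Hybrid sequence+structure pipelines consume only the first part; the
    size of the second is logged so dropped records are visible.
    """
    with_s: list[AnnotatedTRNA] = []
    without_s: list[AnnotatedTRNA] = []
    for rec in records:
        (with_s if rec.structure is not None else without_s).append(rec)
    if without_s:
        logger.info(
            "%d of %d record(s) lack structure strings",
            len(without_s),
            len(with_s) + len(without_s),
        )
    return with_s, without_s
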