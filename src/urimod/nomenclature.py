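"""Modification-nomenclature table: single-character codes → parent canonical base.

Modified nucleotides in annotated tRNA sequences are written as single
characters borrowed from the MODOMICS one-letter nomenclature (e.g. ``Y``
for pseudouridine, ``D`` for dihydrouridine, ``T`` for 5-methyl-uridine).
Every code resolves to one parent base in {A, C, G, U}; the four canonical
characters resolve to themselves and count as unmodified.

Codes are case-significant: lowercase ``a c g u`` denote 2'-O-methylated
nucleosides, distinct from their uppercase parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

CANONICAL_BASES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class NomenclatureEntry:
    code: str
    parent: str  # one of A, C, G, U
    name: str

    @property
    def modified(self) -> bool:
        return self.code != self.parent


class NomenclatureTable:
    """Mapping from single-character modification codes to parent bases."""

    def __init__(self, entries: Iterable[NomenclatureEntry]):
        self._entries: dict[str, NomenclatureEntry] = {}
        for entry in entries:
            if entry.parent not in CANONICAL_BASES:
                raise ValueError(
                    f"parent base {entry.parent!r} for code {entry.code!r} "
                    f"is not one of {CANONICAL_BASES}"
                )
            if entry.code in self._entries:
                raise ValueError(f"duplicate modification code {entry.code!r}")
            self._entries[entry.code] = entry
        # canonical self-mappings are always present
        for base in CANONICAL_BASES:
            self._entries.setdefault(
                base, NomenclatureEntry(base, base, _CANONICAL_NAMES[base])
            )

    def __contains__(self, code: str) -> bool:
        return code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, code: str) -> NomenclatureEntry:
        return self._entries[code]

    def get(self, code: str) -> NomenclatureEntry | None:
        return self._entries.get(code)

    def parent_of(self, code: str) -> str:
        """Parent base of *code*, or ``"other"`` if the code is unknown."""
        entry = self._entries.get(code)
        return entry.parent if entry is not None else "other"

    def is_modified(self, code: str) -> bool:
        """True iff *code* is a known modification code (not canonical)."""
        entry = self._entries.get(code)
        return entry is not None and entry.modified

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._entries)


_CANONICAL_NAMES: Mapping[str, str] = {
    "A": "adenosine",
    "C": "cytidine",
    "G": "guanosine",
    "U": "uridine",
}

#: Built-in default table. Covers the canonical bases, the three named
#: uridine modifications the classifiers target, inosine, and the
#: 2'-O-methylated nucleosides (lowercase codes). A full table should be
#: loaded from a TSV with :func:`load_nomenclature`.
_DEFAULT_ROWS = [
    ("Y", "U", "pseudouridine"),
    ("D", "U", "dihydrouridine"),
    ("T", "U", "5-methyluridine"),
    ("I", "A", "inosine"),
    ("a", "A", "2'-O-methyladenosine"),
    ("c", "C", "2'-O-methylcytidine"),
    ("g", "G", "2'-O-methylguanosine"),
    ("u", "U", "2'-O-methyluridine"),
]


def default_table() -> NomenclatureTable:
    """The built-in nomenclature table (canonical bases + common codes)."""
    return NomenclatureTable(
        NomenclatureEntry(code, parent, name) for code, parent, name in _DEFAULT_ROWS
    )


def load_nomenclature(path: str | Path) -> NomenclatureTable:
    """Load a nomenclature table from whitespace- or tab-separated text.

    Each non-comment row is ``code  name  parent`` or ``code  parent``
    (a two-column row has no long name). Canonical self-mappings are
    injected if absent. Duplicate codes and parents outside {A, C, G, U}
    raise ``ValueError``.
    """
    path = Path(path)
    entries: list[NomenclatureEntry] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        fields = [f.strip() for f in fields if f.strip()]
        if len(fields) == 2:
            code, parent = fields
            name = ""
        elif len(fields) >= 3:
            code, parent = fields[0], fields[-1]
            name = " ".join(fields[1:-1])
        else:
            raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
        if len(code) != 1:
            raise ValueError(
                f"{path}:{lineno}: modification code must be a single "
                f"character, got {code!r}"
            )
        entries.append(NomenclatureEntry(code, parent, name))
    return NomenclatureTable(entries)


def write_nomenclature(table: NomenclatureTable, path: str | Path) -> None:
    """Write *table* as three-column TSV (code, name, parent)."""
    lines = ["#code\tname\tparent"]
    for code in table.codes:
        entry = table[code]
        lines.append(f"{entry.code}\t{entry.name}\t{entry.parent}")
    Path(path).write_text("\n".join(lines) + "\n")
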