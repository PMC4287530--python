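"""Sliding-window extraction and task labeling.

Each position of a tRNA yields one fixed-length window centred on it.
Terminal positions are completed with the dummy nucleotide ``X``:
``(L-1)/2`` copies are appended at each end, where L is the window length
(odd, 3–25). Window text is *demodified* — every modification code is
replaced by its parent base — so the classifier never sees the label
through the annotation itself; unresolvable codes render as ``X``.

Five classification tasks share the window machinery:

* ``UM``       — modified uridine vs unmodified uridine (all uridine centres)
* ``Y``        — pseudouridine vs all other uridine modifications
* ``D``        — dihydrouridine vs all other uridine modifications
* ``T``        — 5-methyl-uridine vs all other uridine modifications
* ``OTHER_UM`` — any uridine modification other than Y/D/T vs Y/D/T

For UM the candidate centres are all uridines; for the four subtype tasks
only modified uridines are candidates. All other centres are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .nomenclature import NomenclatureTable
from .records import AnnotatedTRNA, ResolvedBase, resolve

TASKS = ("UM", "Y", "D", "T", "OTHER_UM")
WINDOW_GRID = tuple(range(3, 26, 2))  # the 12 window sizes swept
PAD_CHAR = "X"

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"


@dataclass(frozen=True)
class WindowConfig:
    """Window length and task for one classification problem."""

    L: int
    task: str
    L_struct: int | None = None  # structure-window length for hybrid/struct

    def __post_init__(self) -> None:
        _check_length(self.L)
        if self.L_struct is not None:
            _check_length(self.L_struct)
        if self.task not in TASKS:
            raise ValueError(f"task {self.task!r} not in {TASKS}")


@dataclass(frozen=True)
class LabeledWindow:
    record_id: str
    center: int  # 0-based position in the unpadded sequence
    seq_window: str
    struct_window: str | None
    label: str  # positive / negative / excluded
    center_code: str = ""  # original (modified) character at the centre


def _check_length(L: int) -> None:
    if L % 2 == 0:
        raise ValueError(f"window length must be odd, got {L}")
    if not 3 <= L <= 25:
        raise ValueError(f"window length must be in 3..25, got {L}")


def pad(sequence: str, L: int) -> str:
    """Append ``(L-1)/2`` dummy ``X`` characters at each terminus."""
    _check_length(L)
    flank = PAD_CHAR * ((L - 1) // 2)
    return f"{flank}{sequence}{flank}"


def extract_windows(
    record: AnnotatedTRNA,
    table: NomenclatureTable,
    L: int,
    L_struct: int | None = None,
) -> list[LabeledWindow]:
    """One unlabeled window per sequence position (label=``excluded``).

    Window i is centred on position i of the unpadded sequence and uses
    parent-base characters. If the record has a structure and *L_struct*
    is given, a structure window (independently padded) is attached.
    """
    resolution = resolve(record, table)
    demod = "".join(b.parent if b.parent != "other" else PAD_CHAR for b in resolution)
    padded = pad(demod, L)
    padded_struct = None
    if L_struct is not None and record.structure is not None:
        padded_struct = pad(record.structure, L_struct)

    windows = []
    for i in range(len(record.sequence)):
        struct_win = (
            padded_struct[i : i + L_struct] if padded_struct is not None else None
        )
        windows.append(
            LabeledWindow(
                record_id=record.id,
                center=i,
                seq_window=padded[i : i + L],
                struct_window=struct_win,
                label=EXCLUDED,
                center_code=record.sequence[i],
            )
        )
    return windows


def label_windows(
    windows: Sequence[LabeledWindow],
    resolution: Sequence[ResolvedBase],
    task: str,
) -> list[LabeledWindow]:
    """Assign task labels to windows extracted from a single record."""
    if task not in TASKS:
        raise ValueError(f"task {task!r} not in {TASKS}")
    labeled = []
    for win in windows:
        base = resolution[win.center]
        labeled.append(
            LabeledWindow(
                record_id=win.record_id,
                center=win.center,
                seq_window=win.seq_window,
                struct_window=win.struct_window,
                label=_label_for(base, task),
                center_code=base.code,
            )
        )
    return labeled


def _label_for(base: ResolvedBase, task: str) -> str:
    if base.parent != "U":
        return EXCLUDED
    if task == "UM":
        return POSITIVE if base.modified else NEGATIVE
    # subtype tasks: only modified uridines are candidates
    if not base.modified:
        return EXCLUDED
    if task in ("Y", "D", "T"):
        return POSITIVE if base.code == task else NEGATIVE
    # OTHER_UM: Y, D, T are the negatives, everything else positive
    return NEGATIVE if base.code in ("Y", "D", "T") else POSITIVE


def windows_for_task(
    records: Iterable[AnnotatedTRNA],
    table: NomenclatureTable,
    config: WindowConfig,
) -> list[LabeledWindow]:
    """Labeled, non-excluded windows for *config* over all records."""
    out = []
    for rec in records:
        wins = extract_windows(rec, table, config.L, config.L_struct)
        for win in label_windows(wins, resolve(rec, table), config.task):
            if win.label != EXCLUDED:
                out.append(win)
    return out


def write_windows_tsv(windows: Sequence[LabeledWindow], path: str | Path) -> None:
    """Export windows as TSV; positions are 1-based in this user-facing file."""
    lines = ["record_id\tcenter\tseq_window\tstruct_window\tlabel"]
    for w in windows:
        lines.append(
            f"{w.record_id}\t{w.center + 1}\t{w.seq_window}\t"
            f"{w.struct_window or ''}\t{w.label}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
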