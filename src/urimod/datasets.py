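"""Dataset construction and corpus statistics.

Builds the dataset variants used throughout the pipeline: kingdom /
compartment splits, organism-exclusion independent sets, redundancy-reduced
sets (greedy clustering on pairwise global-alignment identity over
demodified sequences, with an import path for precomputed cluster files),
and class-balanced window subsamples. Also computes corpus composition
statistics: base composition, per-parent modification shares and rates,
and per-code counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .nomenclature import NomenclatureTable
from .records import AnnotatedTRNA, resolve
from .windows import LabeledWindow

logger = logging.getLogger(__name__)

PARENTS = ("A", "C", "G", "U", "other")

#: organism-name synonyms applied during normalized comparison
ORGANISM_ALIASES = {
    "halobacterium volcanii": "haloferax volcanii",
}


@dataclass
class CompositionReport:
    n_records: int
    n_bases: int
    n_modified: int
    per_base_composition: dict[str, float]  # includes "other"
    per_parent_modified_share: dict[str, float]  # of all modified bases
    per_parent_modified_rate: dict[str, float]  # of that base's occurrences
    per_modification_counts: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_bases": self.n_bases,
            "n_modified": self.n_modified,
            "per_base_composition": self.per_base_composition,
            "per_parent_modified_share": self.per_parent_modified_share,
            "per_parent_modified_rate": self.per_parent_modified_rate,
            "per_modification_counts": self.per_modification_counts,
        }


@dataclass
class DatasetSplit:
    name: str
    records: list[AnnotatedTRNA]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)


def composition_stats(
    records: Sequence[AnnotatedTRNA], table: NomenclatureTable
) -> CompositionReport:
    """Composition and modification statistics pooled over *records*.

    Composition fractions include "other" (unresolvable codes); per-parent
    modification rates use only that parent's occurrences as denominator,
    and "other" bases are excluded from rate denominators (unknown codes
    are never counted as modified).
    """
    if not records:
        raise ValueError("composition_stats needs at least one record")
    base_counts = {p: 0 for p in PARENTS}
    mod_counts = {p: 0 for p in PARENTS}
    code_counts: dict[str, int] = {}
    n_bases = 0
    for rec in records:
        for b in resolve(rec, table):
            n_bases += 1
            base_counts[b.parent] += 1
            if b.modified:
                mod_counts[b.parent] += 1
                code_counts[b.code] = code_counts.get(b.code, 0) + 1
    n_modified = sum(mod_counts.values())
    share = {
        p: (mod_counts[p] / n_modified if n_modified else 0.0) for p in PARENTS
    }
    rate = {
        p: (mod_counts[p] / base_counts[p] if base_counts[p] else 0.0)
        for p in PARENTS
    }
    return CompositionReport(
        n_records=len(records),
        n_bases=n_bases,
        n_modified=n_modified,
        per_base_composition={p: base_counts[p] / n_bases for p in PARENTS},
        per_parent_modified_share=share,
        per_parent_modified_rate=rate,
        per_modification_counts=dict(sorted(code_counts.items())),
    )


def normalize_organism(name: str) -> str:
    """Trim, collapse whitespace, lowercase, and apply known synonyms."""
    norm = " ".join(name.strip().split()).lower()
    return ORGANISM_ALIASES.get(norm, norm)


def exclude_organisms(
    records: Sequence[AnnotatedTRNA], organism_names: Iterable[str]
) -> DatasetSplit:
    """Records whose organism is NOT in *organism_names* (normalized)."""
    excluded = {normalize_organism(n) for n in organism_names}
    kept = [r for r in records if normalize_organism(r.organism) not in excluded]
    provenance = f"excluded organisms: {sorted(excluded)}"
    if not kept:
        provenance += " (empty after filter)"
    logger.info(
        "organism exclusion kept %d of %d records", len(kept), len(records)
    )
    return DatasetSplit("organism-excluded", kept, provenance)


TAXON_GROUPS = (
    "all",
    "archaea",
    "bacteria",
    "eukaryote-all",
    "eukaryote-cyto",
    "eukaryote-mito",
    "eukaryote-plastid",
    "virus",
)

_COMPARTMENT_GROUP = {
    "cytosol": "eukaryote-cyto",
    "mitochondrion": "eukaryote-mito",
    "plastid": "eukaryote-plastid",
}


def split_by_taxon(records: Sequence[AnnotatedTRNA]) -> dict[str, DatasetSplit]:
    """Group records by kingdom and eukaryotic compartment.

    ``eukaryote-all`` is the union of the three compartment groups (plus
    eukaryotes without a compartment label); records with no kingdom go
    to ``unassigned``.
    """
    groups: dict[str, list[AnnotatedTRNA]] = {g: [] for g in TAXON_GROUPS}
    groups["unassigned"] = []
    for rec in records:
        groups["all"].append(rec)
        if rec.kingdom is None:
            groups["unassigned"].append(rec)
        elif rec.kingdom == "eukaryote":
            groups["eukaryote-all"].append(rec)
            sub = _COMPARTMENT_GROUP.get(rec.compartment or "")
            if sub:
                groups[sub].append(rec)
        else:
            groups[rec.kingdom].append(rec)
    return {
        name: DatasetSplit(name, recs, provenance=f"taxon group {name}")
        for name, recs in groups.items()
    }


def _identity_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity = matches / alignment length.

    Scoring (match 1, mismatch 0, linear gap −1) shapes the alignment
    only; the identity fraction is computed from the aligned columns.
    """
    if not seq_a or not seq_b:
        return 0.0
    alignment = _identity_aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    aln_len = alignment.length
    return counts.identities / aln_len if aln_len else 0.0


def read_cluster_file(path: str | Path) -> dict[str, str]:
    """Two-column TSV (cluster_id, record_id) → record_id → cluster_id."""
    membership: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, "
                f"got {len(fields)}"
            )
        cluster_id, record_id = fields
        if record_id in membership:
            raise ValueError(
                f"{path}:{lineno}: record {record_id!r} assigned to two clusters"
            )
        membership[record_id] = cluster_id
    if not membership:
        raise ValueError(f"{path}: empty cluster file")
    return membership


def reduce_redundancy(
    records: Sequence[AnnotatedTRNA],
    table: NomenclatureTable,
    identity_threshold: float = 0.5,
    precomputed_clusters: Mapping[str, str] | None = None,
) -> DatasetSplit:
    """Greedy identity clustering; the longest sequence per cluster survives.

    Sequences are compared on their demodified (parent-base) text. Records
    are visited in (length desc, id asc) order; each joins the first
    retained representative with identity ≥ *identity_threshold*, else
    starts a new cluster. With *precomputed_clusters* (record_id →
    cluster_id) the clustering step is skipped and memberships applied
    verbatim; records absent from the mapping form singleton clusters.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must be in (0, 1]")
    from .records import demodified_sequence

    if precomputed_clusters is not None:
        clusters: dict[str, list[AnnotatedTRNA]] = {}
        for rec in records:
            cid = precomputed_clusters.get(rec.id, f"__singleton__{rec.id}")
            clusters.setdefault(cid, []).append(rec)
        kept = [
            sorted(members, key=lambda r: (-len(r.sequence), r.id))[0]
            for members in clusters.values()
        ]
        kept.sort(key=lambda r: [rec.id for rec in records].index(r.id))
        return DatasetSplit(
            "non-redundant",
            kept,
            provenance=f"precomputed clusters, {len(clusters)} cluster(s)",
        )

    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    demod = {r.id: demodified_sequence(r, table) for r in records}
    representatives: list[AnnotatedTRNA] = []
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(demod[rec.id], demod[rep.id]) >= identity_threshold:
                break  # joins rep's cluster; rep is at least as long
        else:
            representatives.append(rec)
    order_index = {r.id: i for i, r in enumerate(records)}
    representatives.sort(key=lambda r: order_index[r.id])
    return DatasetSplit(
        "non-redundant",
        representatives,
        provenance=(
            f"greedy clustering at identity ≥ {identity_threshold:g}, "
            f"{len(representatives)} of {len(records)} retained"
        ),
    )


def balanced_subsample(
    windows: Sequence[LabeledWindow],
    per_class_counts: Mapping[str, int],
    seed: int,
    class_of=None,
) -> list[LabeledWindow]:
    """Sample windows without replacement, a fixed count per class.

    *class_of* maps a window to its class name; the default uses the
    window's original centre character (the modification code), so
    ``{"Y": 30, "D": 30, "T": 30, "other": 92}`` draws by modification
    type with ``other`` meaning any code not named as its own class.
    Reproducible for a fixed *seed*; raises if a class is short.
    """
    if class_of is None:
        named = {c for c in per_class_counts if c != "other"}

        def class_of(w: LabeledWindow) -> str:
            return w.center_code if w.center_code in named else "other"

    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledWindow]] = {}
    for w in windows:
        by_class.setdefault(class_of(w), []).append(w)
    chosen: list[LabeledWindow] = []
    for cls, count in per_class_counts.items():
        pool = by_class.get(cls, [])
        if len(pool) < count:
            raise ValueError(
                f"class {cls!r} has only {len(pool)} window(s); {count} requested"
            )
        idx = rng.choice(len(pool), size=count, replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return chosen
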