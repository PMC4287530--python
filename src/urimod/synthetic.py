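"""Synthetic annotated tRNA corpora with planted, learnable modification signal.

The generator emits cloverleaf-like records: acceptor stem, D-arm,
anticodon arm, variable loop, T-arm and an NCCA tail, with a consistent
angle-bracket structure string. Modification codes are planted with
position- and context-biased rules that imitate the *shape* of real
signal without claiming biological realism:

* 5-methyl-uridine (``T``) only inside a fixed ``GUUCA`` motif at the
  start of the T-loop (the conserved GTΨC site), with a pseudouridine
  at the following position;
* dihydrouridine (``D``) at defined D-loop sites, flanked by adenines;
* pseudouridine (``Y``) at anticodon-loop sites with a G·U 5' / A 3'
  neighborhood;
* 2'-O-methyluridine (``u``, an "other" modification) in the variable
  loop, flanked by cytosines;
* decoy unmodified uridines keep a C 5' / G 3' neighborhood.

A null-signal variant plants modifications uniformly at random over all
uridines, so labels carry no sequence signal and any classifier should
score near AUC 0.5. Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nomenclature import NomenclatureTable, default_table
from .records import AnnotatedTRNA, resolve
from .structures import attach_structure

_PAIR = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class MotifRule:
    """Plant *code* at a region site, stamping context around it."""

    code: str
    region: str  # dloop / acloop / tloop / varloop
    left_context: str  # characters stamped immediately 5' of the site
    right_context: str  # stamped immediately 3'
    probability: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("rule probability must be in [0, 1]")


STRONG_RULES = (
    MotifRule("D", "dloop", "AA", "AA", probability=0.9),
    MotifRule("Y", "acloop", "GU", "AA", probability=0.9),
    MotifRule("T", "tloop", "", "", probability=0.9),  # GUUCA motif site
    MotifRule("u", "varloop", "CC", "CC", probability=0.85),
)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic corpus."""

    n_records: int = 60
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    var_loop_range: tuple[int, int] = (6, 9)  # inclusive bounds
    rules: tuple[MotifRule, ...] = STRONG_RULES
    decoy_context: tuple[str, str] = ("C", "G")
    decoy_probability: float = 0.8
    null_signal: bool = False
    null_modification_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base composition must sum to 1")
        if not 0 <= self.decoy_probability <= 1:
            raise ValueError("decoy probability must be in [0, 1]")
        if not 0 <= self.null_modification_rate <= 1:
            raise ValueError("null modification rate must be in [0, 1]")


def strong_signal_spec(seed: int = 0, n_records: int = 60) -> FixtureSpec:
    """Corpus whose planted contexts make every task learnable."""
    return FixtureSpec(n_records=n_records, seed=seed)


def null_signal_spec(seed: int = 0, n_records: int = 60) -> FixtureSpec:
    """Corpus with modifications placed independently of sequence context."""
    return FixtureSpec(n_records=n_records, null_signal=True, seed=seed)


_BASES = ("A", "C", "G", "U")

# arm geometry: (name, kind, length); stems emit both strands
_LAYOUT = (
    ("acceptor", "stem", 7),
    ("spacer1", "loop", 2),
    ("dstem", "stem", 4),
    ("dloop", "loop", 8),
    ("spacer2", "loop", 1),
    ("acstem", "stem", 5),
    ("acloop", "loop", 7),
    ("varloop", "loop", None),  # drawn from var_loop_range
    ("tstem", "stem", 5),
    ("tloop", "loop", 7),
    ("tail", "loop", 4),  # discriminator + CCA
)


def _random_bases(rng: np.random.Generator, n: int, comp) -> list[str]:
    return list(rng.choice(_BASES, size=n, p=comp))


class _Cloverleaf:
    """One record under construction: characters, structure, region spans."""

    def __init__(self, rng: np.random.Generator, spec: FixtureSpec):
        comp = np.asarray(spec.base_composition)
        chars: list[str] = []
        struct: list[str] = []
        spans: dict[str, tuple[int, int]] = {}
        closing: list[tuple[str, list[str]]] = []  # LIFO of 3' stem strands

        var_lo, var_hi = spec.var_loop_range
        for name, kind, length in _LAYOUT:
            if length is None:
                length = int(rng.integers(var_lo, var_hi + 1))
            if kind == "stem":
                strand = _random_bases(rng, length, comp)
                spans[name] = (len(chars), len(chars) + length)
                chars.extend(strand)
                struct.extend("<" * length)
                closing.append((name, [_PAIR[b] for b in reversed(strand)]))
                if name in ("dstem", "acstem", "tstem"):
                    continue  # closed right after its loop
            else:
                spans[name] = (len(chars), len(chars) + length)
                chars.extend(_random_bases(rng, length, comp))
                struct.extend("." * length)
            # close the innermost open stem after its loop
            if name in ("dloop", "acloop", "tloop") and closing:
                stem_name, strand3 = closing.pop()
                chars.extend(strand3)
                struct.extend(">" * len(strand3))
        # remaining open stems (the acceptor) close before the tail;
        # rebuild: acceptor 3' strand must precede the tail
        while closing:
            stem_name, strand3 = closing.pop()
            tail_start, tail_end = spans["tail"]
            tail = chars[tail_start:tail_end]
            del chars[tail_start:tail_end]
            del struct[tail_start:tail_end]
            spans[stem_name + "_3p"] = (len(chars), len(chars) + len(strand3))
            chars.extend(strand3)
            struct.extend(">" * len(strand3))
            spans["tail"] = (len(chars), len(chars) + len(tail))
            chars.extend(tail)
            struct.extend("." * len(tail))
        self.chars = chars
        self.struct = struct
        self.spans = spans

    def stamp(self, pos: int, text: str) -> None:
        for i, ch in enumerate(text):
            j = pos + i
            if 0 <= j < len(self.chars) and self.struct[j] == ".":
                self.chars[j] = ch

    def loop_positions(self, region: str) -> list[int]:
        lo, hi = self.spans[region]
        return list(range(lo, hi))


def _plant_strong(leaf: _Cloverleaf, rng: np.random.Generator, spec: FixtureSpec) -> None:
    decoy_left, decoy_right = spec.decoy_context
    for rule in spec.rules:
        positions = leaf.loop_positions(rule.region)
        if rule.region == "tloop":
            # conserved GUUCA motif at the loop start; T then Y when the
            # rule fires, a uridine-free motif otherwise so that the site
            # never becomes an ambiguous negative
            start = positions[0]
            if rng.random() < rule.probability:
                leaf.stamp(start, "GUUCA")
                leaf.chars[start + 1] = "T"
                leaf.chars[start + 2] = "Y"
            else:
                leaf.stamp(start, "GAACA")
            continue
        # site in the loop interior, leaving room for context
        need_left, need_right = len(rule.left_context), len(rule.right_context)
        candidates = positions[need_left : len(positions) - need_right or None]
        if not candidates:
            raise ValueError(
                f"rule for {rule.code!r}: region {rule.region!r} too short "
                "for its context"
            )
        site = candidates[int(rng.integers(len(candidates)))]
        if rng.random() < rule.probability:
            leaf.stamp(site - need_left, rule.left_context)
            leaf.stamp(site + 1, rule.right_context)
            leaf.chars[site] = rule.code
        else:
            # unplanted site becomes an ordinary decoy uridine
            leaf.stamp(site - 1, decoy_left)
            leaf.stamp(site + 1, decoy_right)
            leaf.chars[site] = "U"
    # decoy unmodified uridines keep the anti-context
    for region in ("dloop", "acloop", "varloop"):
        for pos in leaf.loop_positions(region):
            if leaf.chars[pos] == "U" and rng.random() < spec.decoy_probability:
                leaf.stamp(pos - 1, decoy_left)
                leaf.stamp(pos + 1, decoy_right)


def _plant_null(leaf: _Cloverleaf, rng: np.random.Generator, spec: FixtureSpec) -> None:
    codes = [r.code for r in spec.rules]
    for pos, ch in enumerate(leaf.chars):
        if ch == "U" and rng.random() < spec.null_modification_rate:
            leaf.chars[pos] = codes[int(rng.integers(len(codes)))]


def generate(spec: FixtureSpec) -> list[AnnotatedTRNA]:
    """Generate a corpus of annotated records with attached structures."""
    rng = np.random.default_rng(spec.seed)
    kingdoms = ("archaea", "bacteria", "eukaryote", "virus")
    records: list[AnnotatedTRNA] = []
    for i in range(spec.n_records):
        leaf = _Cloverleaf(rng, spec)
        if spec.null_signal:
            _plant_null(leaf, rng, spec)
        else:
            _plant_strong(leaf, rng, spec)
        kingdom = kingdoms[int(rng.integers(len(kingdoms)))]
        compartment = None
        if kingdom == "eukaryote":
            compartment = ("cytosol", "mitochondrion", "plastid")[
                int(rng.integers(3))
            ]
        rec = AnnotatedTRNA(
            id=f"synth{i:04d}",
            organism=f"Synthetica specimen{i % 7}",
            kingdom=kingdom,
            compartment=compartment,
            sequence="".join(leaf.chars),
        )
        records.append(attach_structure(rec, "".join(leaf.struct), "trnascan"))
    return records


@dataclass
class LeakReport:
    n_records: int
    n_modified_uridines: int
    n_unmodified_uridines: int
    alphabet_closed: bool  # demodified text only over A,C,G,U,X
    structure_balanced: bool  # '<' and '>' counts match in every record
    codes_seen: dict[str, int] = field(default_factory=dict)


def leak_check(
    corpus: Sequence[AnnotatedTRNA], table: NomenclatureTable | None = None
) -> LeakReport:
    """Sanity-check a corpus: labels must not leak through the window text.

    Confirms the demodified alphabet is closed over {A, C, G, U, X} (so a
    modification code can never surface in a window) and that structures
    are balanced angle-bracket strings.
    """
    table = table or default_table()
    n_mod = n_unmod = 0
    alphabet_ok = True
    struct_ok = True
    codes: dict[str, int] = {}
    for rec in corpus:
        for b in resolve(rec, table):
            if b.parent == "U":
                if b.modified:
                    n_mod += 1
                    codes[b.code] = codes.get(b.code, 0) + 1
                else:
                    n_unmod += 1
            if b.parent not in ("A", "C", "G", "U", "other"):
                alphabet_ok = False
        if rec.structure is not None:
            if rec.structure.count("<") != rec.structure.count(">"):
                struct_ok = False
    return LeakReport(
        n_records=len(corpus),
        n_modified_uridines=n_mod,
        n_unmodified_uridines=n_unmod,
        alphabet_closed=alphabet_ok,
        structure_balanced=struct_ok,
        codes_seen=dict(sorted(codes.items())),
    )
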