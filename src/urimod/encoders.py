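"""Feature encodings for sequence and structure windows.

Schemes
-------
``mnc`` / ``dnc`` / ``tnc``
    Mono-, di- and tri-nucleotide composition over the five-letter window
    alphabet {A, C, G, U, X}: overlapping k-mer frequencies in fixed
    lexicographic order (A < C < G < U < X), dimensions 5 / 25 / 125.
``bpp``
    Binary profile of patterns: per-position 5-bit one-hot
    (A={1,0,0,0,0} … X={0,0,0,0,1}) concatenated 5'→3'; dimension 5·L.
``struct:<dialect>``
    Per-position one-hot over the dialect's ordered alphabet
    (rnafold/trnascan: 4 per position; ipknot: 6).
``hybrid``
    BPP of a 17-mer sequence window concatenated with the trnascan
    structure one-hot of a 19-mer window on the same centre:
    85 + 76 = 161 features.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .structures import StructureDialect, TRNASCAN, get_dialect

SEQ_ALPHABET = ("A", "C", "G", "U", "X")
_SEQ_INDEX = {c: i for i, c in enumerate(SEQ_ALPHABET)}

HYBRID_SEQ_LEN = 17
HYBRID_STRUCT_LEN = 19


@dataclass(frozen=True)
class FeatureVector:
    scheme: str
    values: np.ndarray

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def _check_seq_window(window: str) -> None:
    for pos, ch in enumerate(window):
        if ch not in _SEQ_INDEX:
            raise ValueError(
                f"illegal window character {ch!r} at position {pos + 1}; "
                f"alphabet is {SEQ_ALPHABET}"
            )


def _kmer_composition(window: str, k: int) -> np.ndarray:
    _check_seq_window(window)
    if len(window) < k:
        raise ValueError(f"window of length {len(window)} too short for k={k}")
    index = {
        "".join(kmer): i
        for i, kmer in enumerate(product(SEQ_ALPHABET, repeat=k))
    }
    counts = np.zeros(len(index))
    for i in range(len(window) - k + 1):
        counts[index[window[i : i + k]]] += 1
    return counts / counts.sum()


def encode_mnc(window: str) -> FeatureVector:
    """Mono-nucleotide composition; 5 frequencies in order A,C,G,U,X."""
    return FeatureVector("mnc", _kmer_composition(window, 1))


def encode_dnc(window: str) -> FeatureVector:
    """Overlapping di-nucleotide composition; dim 25, denominator L−1."""
    return FeatureVector("dnc", _kmer_composition(window, 2))


def encode_tnc(window: str) -> FeatureVector:
    """Overlapping tri-nucleotide composition; dim 125, denominator L−2."""
    return FeatureVector("tnc", _kmer_composition(window, 3))


def encode_bpp(window: str) -> FeatureVector:
    """Binary profile: per-position one-hot over A,C,G,U,X; dim 5·L."""
    _check_seq_window(window)
    vec = np.zeros(5 * len(window))
    for i, ch in enumerate(window):
        vec[5 * i + _SEQ_INDEX[ch]] = 1.0
    return FeatureVector("bpp", vec)


def encode_structure(
    struct_window: str, dialect: str | StructureDialect
) -> FeatureVector:
    """Per-position one-hot over the dialect's ordered alphabet (X last)."""
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    index = {sym: i for i, sym in enumerate(dialect.alphabet)}
    width = len(dialect.alphabet)
    vec = np.zeros(width * len(struct_window))
    for i, sym in enumerate(struct_window):
        if sym not in index:
            raise ValueError(
                f"structure symbol {sym!r} at position {i + 1} outside "
                f"dialect {dialect.name!r} alphabet {dialect.alphabet}"
            )
        vec[width * i + index[sym]] = 1.0
    return FeatureVector(f"struct:{dialect.name}", vec)


def encode_hybrid(seq_window17: str, struct_window19: str) -> FeatureVector:
    """BPP(17) ‖ trnascan structure one-hot(19) on the same centre; dim 161."""
    if len(seq_window17) != HYBRID_SEQ_LEN:
        raise ValueError(
            f"hybrid sequence window must have length {HYBRID_SEQ_LEN}, "
            f"got {len(seq_window17)}"
        )
    if len(struct_window19) != HYBRID_STRUCT_LEN:
        raise ValueError(
            f"hybrid structure window must have length {HYBRID_STRUCT_LEN}, "
            f"got {len(struct_window19)}"
        )
    bpp = encode_bpp(seq_window17)
    struct = encode_structure(struct_window19, TRNASCAN)
    return FeatureVector("hybrid", np.concatenate([bpp.values, struct.values]))


def encode_windows(windows, scheme: str, dialect: str = "trnascan") -> np.ndarray:
    """Feature matrix (n_windows × dim) for a list of LabeledWindow.

    *scheme* is one of mnc/dnc/tnc/bpp/struct/hybrid; struct and hybrid
    require every window to carry a structure window.
    """
    rows = []
    for w in windows:
        if scheme == "mnc":
            rows.append(encode_mnc(w.seq_window).values)
        elif scheme == "dnc":
            rows.append(encode_dnc(w.seq_window).values)
        elif scheme == "tnc":
            rows.append(encode_tnc(w.seq_window).values)
        elif scheme == "bpp":
            rows.append(encode_bpp(w.seq_window).values)
        elif scheme == "struct":
            if w.struct_window is None:
                raise ValueError(
                    f"window {w.record_id}:{w.center + 1} has no structure; "
                    "partition records by structure first"
                )
            rows.append(encode_structure(w.struct_window, dialect).values)
        elif scheme == "hybrid":
            if w.struct_window is None:
                raise ValueError(
                    f"window {w.record_id}:{w.center + 1} has no structure; "
                    "partition records by structure first"
                )
            rows.append(encode_hybrid(w.seq_window, w.struct_window).values)
        else:
            raise ValueError(f"unknown encoding scheme {scheme!r}")
    return np.array(rows) if rows else np.empty((0, 0))
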