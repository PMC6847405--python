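"""Small nucleotide-alphabet helpers shared across modules.

Encoding convention: A=0, C=1, G=2, T/U=3.  Two codes a, b form a
Watson-Crick pair iff a + b == 3; a G:U wobble pair iff a + b == 5.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_DNA = "ACGT"
_RNA = "ACGU"

_DNA_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")
_RNA_COMP = str.maketrans("ACGUTacgut", "UGCAAugcaa")


def to_rna(seq: str) -> str:
    """Transcribe a DNA string to RNA (T -> U), uppercased."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1].upper()


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMP)[::-1].upper()


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as an int8 array (A=0, C=1, G=2, T/U=3)."""
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in sequence") from exc


def decode_rna(codes: np.ndarray) -> str:
    return "".join(_RNA[c] for c in codes)


def decode_dna(codes: np.ndarray) -> str:
    return "".join(_DNA[c] for c in codes)


def is_wc(a: int, b: int) -> bool:
    return a + b == 3


def validate_rna(seq: str) -> None:
    bad = set(seq.upper()) - set("ACGU")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
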