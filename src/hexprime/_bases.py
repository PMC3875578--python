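"""Base encodings shared across the package.

Bases are encoded A=0, C=1, G=2, T/U=3, N=4.  With this encoding the
Watson-Crick complement of a non-N code ``b`` is ``3 - b``, which keeps
strand arithmetic branch-free in the vectorised paths.
"""
from __future__ import annotations

import numpy as np

A, C, G, T = 0, 1, 2, 3
N = 4

DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

# ASCII -> code lookup; anything that is not an unambiguous base maps to N.
ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _ch in enumerate(DNA_ALPHABET):
    ENCODE[ord(_ch)] = _i
    ENCODE[ord(_ch.lower())] = _i
ENCODE[ord("U")] = T
ENCODE[ord("u")] = T

DECODE_DNA = np.frombuffer(b"ACGTN", dtype=np.uint8)
DECODE_RNA = np.frombuffer(b"ACGUN", dtype=np.uint8)

COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_COMP_STR = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    return ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray, rna: bool = False) -> str:
    table = DECODE_RNA if rna else DECODE_DNA
    return table[codes].tobytes().decode("ascii")


def complement_base(base: str) -> str:
    """Watson-Crick DNA complement of a single base (U treated as T)."""
    return _COMP_STR[base.upper()]


def reverse_complement(seq: str) -> str:
    return "".join(_COMP_STR[b] for b in reversed(seq.upper()))
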