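"""Shared low-level sequence helpers."""

from __future__ import annotations

import numpy as np

NUCLEOTIDES = "ACGT"
VALID_NT = frozenset("ACGTN")

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    # standard genetic code; '*' marks stop
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        table[stop] = "*"
    return table


def translate_codon(codon: str) -> str:
    """Translate a single codon; 'X' for codons containing N."""
    global _CODON_TABLE
    if not _CODON_TABLE:
        _CODON_TABLE.update(_build_codon_table())
    return _CODON_TABLE.get(codon, "X")


def encode(seq: str) -> np.ndarray:
    """Nucleotide string -> uint8 array (byte codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        return 0
    return int(np.count_nonzero(encode(a) != encode(b)))


def check_nucleotides(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - VALID_NT
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")
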