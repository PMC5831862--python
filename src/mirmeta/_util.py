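"""Shared sequence helpers: alphabet normalization, complements, hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

_COMPLEMENT_RNA = str.maketrans("ACGUN", "UGCAN")
_COMPLEMENT_DNA = str.maketrans("ACGTN", "TGCAN")


def to_rna(seq: str) -> str:
    """Uppercase and convert T->U. U and T are treated as the same base."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert U->T."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_COMPLEMENT_RNA)[::-1]


def revcomp_dna(seq: str) -> str:
    return to_dna(seq).translate(_COMPLEMENT_DNA)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def validate_rna(seq: str, *, context: str = "sequence") -> str:
    s = to_rna(seq)
    bad = set(s) - set(RNA_BASES)
    if bad:
        raise ValueError(f"{context} contains non-RNA characters: {sorted(bad)}")
    return s


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
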