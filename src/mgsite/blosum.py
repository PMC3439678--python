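"""BLOSUM62 access used by alignment and substitution classification."""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@lru_cache(maxsize=1)
def blosum62() -> dict[tuple[str, str], int]:
    """BLOSUM62 as a plain symmetric dict over one-letter codes (incl. X)."""
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], int] = {}
    for a in mat.alphabet:
        for b in mat.alphabet:
            table[(a, b)] = int(mat[a, b])
    return table


def score(a: str, b: str) -> int:
    """BLOSUM62 score for a residue pair; unknown letters fall back to X."""
    table = blosum62()
    key = (a if (a, a) in table else "X", b if (b, b) in table else "X")
    return table[key]
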