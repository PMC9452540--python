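"""Small sequence helpers shared across the package.

Internal alphabet is RNA (A, C, G, U); DNA input is converted on read and
converted back only at file boundaries (FASTQ output).
"""

from __future__ import annotations

RNA_ALPHABET = frozenset("ACGU")

_DNA2RNA = str.maketrans("Tt", "Uu")
_RNA2DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT_DNA = str.maketrans("ACGTacgt", "TGCAtgca")


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().translate(_DNA2RNA)


def to_dna(seq: str) -> str:
    return seq.upper().translate(_RNA2DNA)


def revcomp_dna(seq: str) -> str:
    return seq.translate(_COMPLEMENT_DNA)[::-1]


def validate_rna(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` uppercased as RNA, raising on non-ACGTU characters."""
    rna = to_rna(seq)
    bad = set(rna) - RNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGTU characters: {sorted(bad)!r}")
    return rna
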