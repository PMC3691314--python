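"""Shared sequence helpers (DNA/RNA normalization, reverse complement)."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA2DNA = str.maketrans("Uu", "Tt")

VALID_BASES = frozenset("ACGTN")


def norm_seq(seq: str) -> str:
    """Uppercase and map U->T so catalog RNA and sequencer DNA compare."""
    return seq.upper().translate(_RNA2DNA)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA-space sequence (after norm_seq)."""
    return norm_seq(seq).translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return norm_seq(seq).replace("T", "U")


def check_alphabet(seq: str, allow_n: bool = False) -> None:
    allowed = VALID_BASES if allow_n else frozenset("ACGT")
    bad = set(norm_seq(seq)) - allowed
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
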