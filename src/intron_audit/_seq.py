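"""Small sequence utilities shared across modules."""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction of a non-empty sequence."""
    return (seq.count("G") + seq.count("C")) / len(seq)


def normalize_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and validate a DNA string against the ACGTN alphabet."""
    up = seq.upper().replace("U", "T")
    bad = set(up) - VALID_BASES
    if bad:
        raise ValueError(f"{context}: invalid characters {sorted(bad)!r}")
    return up


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming: unequal lengths")
    return sum(x != y for x, y in zip(a, b))
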