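"""Small nucleotide-string helpers shared across the package."""

from __future__ import annotations

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(COMPLEMENT)[::-1]


def is_pyrimidine(base: str) -> bool:
    return base in PYRIMIDINES
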