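"""Small shared DNA-string helpers."""

from __future__ import annotations

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = frozenset("ACGT")


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_percent(seq: str) -> float:
    """GC% over A/C/G/T characters only; masked/ambiguous characters are
    excluded from the denominator. Returns 0.0 for sequences with no bases."""
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return 0.0
    return 100.0 * (seq.count("G") + seq.count("C")) / n


def is_acgt(seq: str) -> bool:
    return bool(seq) and set(seq) <= BASES
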