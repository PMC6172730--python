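"""Small sequence helpers shared across modules.

All internal sequences are uppercase RNA (``A C G U``); DNA input is
converted at read time (``T`` -> ``U``).  Ambiguity codes (``N`` etc.) are
preserved but never form a Watson-Crick pair, so they can never be part of
a seed match.
"""

from __future__ import annotations

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}

#: Watson-Crick pairs over the RNA alphabet (no wobble).
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def normalize_rna(seq: str) -> str:
    """Uppercase a sequence and convert DNA thymine to uracil."""
    return seq.upper().replace("T", "U")


def complement(base: str) -> str:
    """WC complement of a single RNA base; ambiguity codes map to ``N``."""
    return _COMPLEMENT.get(base, "N")


def revcomp(seq: str) -> str:
    """Reverse complement over the RNA alphabet."""
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(seq))


def pairs_wc(a: str, b: str) -> bool:
    """True when bases *a* and *b* form a Watson-Crick pair."""
    return (a, b) in WC_PAIRS


def au_fraction(seq: str) -> float:
    """Fraction of A/U bases in *seq* (0.0 for an empty sequence)."""
    if not seq:
        return 0.0
    return sum(1 for b in seq if b in "AU") / len(seq)
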