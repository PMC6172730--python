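"""Pluggable thermodynamic backends.

Two contracts are used by the context features:

* a *duplex backend* maps ``(target_strand, mirna_strand)`` (both 5'->3')
  to a duplex free energy in kcal/mol (more negative = more stable);
* a *fold backend* maps an RNA segment to per-base unpaired probabilities
  in ``[0, 1]``.

Production scoring uses the ViennaRNA library; the deterministic toy
backends give exact, hand-checkable numbers and are what the unit tests
exercise.
"""

from __future__ import annotations

import numpy as np

from .seqtools import normalize_rna, revcomp

__all__ = [
    "toy_duplex_backend",
    "constant_fold_backend",
    "vienna_duplex_backend",
    "vienna_fold_backend",
]


def toy_duplex_backend(target: str, mirna: str) -> float:
    """-1.0 kcal/mol per Watson-Crick pair in the best gapless duplex.

    The two strands are aligned antiparallel at every offset; the offset
    with the most WC pairs wins.  Crude, but exactly predictable.
    """
    t = normalize_rna(target)
    m = revcomp(normalize_rna(mirna))  # same orientation as the target now
    best = 0
    for k in range(-(len(m) - 1), len(t)):
        matches = sum(
            1
            for i in range(len(m))
            if 0 <= k + i < len(t) and t[k + i] == m[i] and m[i] in "ACGU"
        )
        best = max(best, matches)
    return -1.0 * best


def constant_fold_backend(p: float = 1.0):
    """A fold backend returning the same unpaired probability everywhere."""

    def backend(segment: str) -> np.ndarray:
        return np.full(len(segment), float(p))

    return backend


def vienna_duplex_backend(target: str, mirna: str) -> float:
    """Duplex free energy from ViennaRNA's RNAduplex (kcal/mol)."""
    import RNA

    duplex = RNA.duplexfold(normalize_rna(target), normalize_rna(mirna))
    return float(duplex.energy)


def vienna_fold_backend(segment: str) -> np.ndarray:
    """Per-base unpaired probabilities from the partition function.

    The unpaired probability of base *i* is one minus the sum of its
    base-pairing probabilities.
    """
    import RNA

    seq = normalize_rna(segment)
    fc = RNA.fold_compound(seq)
    fc.pf()
    bpp = np.array(fc.bpp())[1:, 1:]  # 1-based matrix from ViennaRNA
    paired = bpp.sum(axis=0) + bpp.sum(axis=1)
    return np.clip(1.0 - paired, 0.0, 1.0)
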