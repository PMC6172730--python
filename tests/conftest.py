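"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from flyseed.seqtools import WC_PAIRS

#: A toy miRNA whose seed-region target match is easy to reason about.
TOY_MIRNA = "UGGAAUGUAAAGAAGUAUGUAU"


def oracle_sites(region_seq: str, mirna_seq: str) -> list[tuple[int, int, str]]:
    """Brute-force site scan by explicit Watson-Crick pairing.

    Every window of every length is checked against the six canonical
    definitions by pairing target bases to miRNA positions one at a time;
    overlapping candidates contained in a higher-priority candidate are
    suppressed.  Deliberately independent of the package's pattern-string
    implementation.
    """
    m = mirna_seq

    def pairs(t: str, mirna_pos: int) -> bool:
        return (t, m[mirna_pos - 1]) in WC_PAIRS

    definitions = [
        ("8mer", 8,
         lambda w: all(pairs(w[k], 8 - k) for k in range(7)) and w[7] == "A"),
        ("7mer-m8", 7,
         lambda w: all(pairs(w[k], 8 - k) for k in range(7))),
        ("7mer-A1", 7,
         lambda w: all(pairs(w[k], 7 - k) for k in range(6)) and w[6] == "A"),
        ("6mer", 6,
         lambda w: all(pairs(w[k], 7 - k) for k in range(6))),
        ("offset-6mer", 6,
         lambda w: all(pairs(w[k], 8 - k) for k in range(6))),
        ("6mer-A1", 6,
         lambda w: all(pairs(w[k], 6 - k) for k in range(5)) and w[5] == "A"),
    ]
    candidates = []
    for priority, (name, k, check) in enumerate(definitions):
        for i in range(len(region_seq) - k + 1):
            if check(region_seq[i : i + k]):
                candidates.append((i, i + k, name, priority))
    kept = [
        (s, e, t)
        for s, e, t, p in candidates
        if not any(
            os_ <= s and e <= oe and op < p
            for os_, oe, _, op in candidates
            if (os_, oe) != (s, e) or op != p
        )
    ]
    return sorted(kept)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic world shared across read-only tests."""
    from flyseed.synthetic import WorldConfig, make_world

    return make_world(WorldConfig(n_genes=120, seed=7))
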