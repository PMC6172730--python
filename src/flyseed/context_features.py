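"""The 17 site-context features of the targeting-efficacy model.

Each (site, mRNA) pair is described by 17 features spanning the site
itself (type, flanking nucleotide identities, local AU content, 3'
supplementary pairing, structural accessibility, conservation) and the
host mRNA (region lengths, region AU contents, positional features, and
the count of weak canonical sites).  Two features carry tunable windows
that were optimised by grid search against repression data:

* ``3P_energy`` — energy of 3' supplementary pairing, the duplex free
  energy of (upstream target window + seed match) against (miRNA seed
  region + a 3' miRNA segment), minus the seed-only duplex energy.
  Optimum in flies: miRNA nucleotides 13-17 against a 9-nt window.
* ``SA`` — structural accessibility, log10 of the mean per-base unpaired
  probability of a window near the seed match within a locally folded
  80-nt segment.  Optimum in flies: a 25-nt window centred on the
  nucleotide pairing miRNA position 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .seqtools import au_fraction, normalize_rna, pairs_wc
from .site_finder import STRONG_TYPES, MirnaRecord, SiteMatch, SiteType

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "PairingWindowConfig",
    "AccessibilityConfig",
    "three_prime_pairing_energy",
    "three_prime_score",
    "structural_accessibility",
    "local_au",
    "positional_and_bulk_features",
    "assemble_feature_vector",
    "optimize_pairing_window",
    "optimize_sa_window",
]

#: Names of the 17 features, in canonical order.
FEATURE_NAMES = [
    "site_type",
    "site9",
    "site10",
    "local_AU",
    "3P_score",
    "3P_energy",
    "SA",
    "PCT",
    "len_5UTR",
    "len_ORF",
    "len_3UTR",
    "AU_5UTR",
    "AU_ORF",
    "AU_3UTR",
    "dist_stop",
    "min_dist",
    "other_sites",
]


@dataclass(frozen=True)
class PairingWindowConfig:
    """Window parameters for the 3' supplementary pairing energy.

    ``mirna_start`` is 1-based on the miRNA (range 9-19), ``mirna_len``
    the length of the 3' miRNA segment (4-13 nt), ``target_window`` the
    length of the upstream target region (4-20 nt).  Defaults are the fly
    optimum (13, 5, 9).
    """

    mirna_start: int = 13
    mirna_len: int = 5
    target_window: int = 9

    def __post_init__(self) -> None:
        if not 9 <= self.mirna_start <= 19:
            raise ValueError("mirna_start must be in 9..19")
        if not 4 <= self.mirna_len <= 13:
            raise ValueError("mirna_len must be in 4..13")
        if not 4 <= self.target_window <= 20:
            raise ValueError("target_window must be in 4..20")


@dataclass(frozen=True)
class AccessibilityConfig:
    """Window parameters for structural accessibility.

    An 80-nt segment centred on the seed match is folded; the score
    averages unpaired probabilities over a ``window``-nt region whose
    centre sits ``center`` nt downstream (3') of the nucleotide pairing
    miRNA position 7.  Defaults are the fly optimum (80, 25, 0).
    """

    fold_span: int = 80
    window: int = 25
    center: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.window <= self.fold_span:
            raise ValueError("window must be in 1..fold_span")


def _m7_position(site: SiteMatch) -> int:
    """UTR coordinate of the target nucleotide opposite miRNA position 7."""
    offsets = {
        SiteType.EIGHTMER: 1,
        SiteType.SEVENMER_M8: 1,
        SiteType.OFFSET_SIXMER: 1,
        SiteType.SEVENMER_A1: 0,
        SiteType.SIXMER: 0,
        SiteType.SIXMER_A1: -1,
    }
    return site.start + offsets[site.site_type]


def _opposite(site: SiteMatch, utr: str, mirna_pos: int) -> str:
    """Target nucleotide opposite 1-based miRNA position *mirna_pos*."""
    pos = _m7_position(site) - (mirna_pos - 7)
    if 0 <= pos < len(utr):
        return utr[pos]
    return "N"


def three_prime_pairing_energy(
    mirna_seq: str,
    utr: str,
    site: SiteMatch,
    cfg: PairingWindowConfig = PairingWindowConfig(),
    duplex_backend=None,
) -> float:
    """3P_energy: Delta-G of the full duplex minus the seed-only duplex.

    The full duplex pairs (upstream target window + seed match) against
    (miRNA seed region + the configured 3' miRNA segment); subtracting the
    seed-only duplex energy isolates the contribution of 3' supplementary
    pairing.  The upstream window is truncated at the UTR start.
    """
    if duplex_backend is None:
        from .backends import vienna_duplex_backend as duplex_backend
    if site.site_type not in STRONG_TYPES:
        raise ValueError(
            f"3' pairing energy is defined for 7-8-nt 3' UTR sites, "
            f"not {site.site_type.value}"
        )
    mirna_seq = normalize_rna(mirna_seq)
    utr = normalize_rna(utr)
    seed_region = mirna_seq[1:8]
    seg0 = cfg.mirna_start - 1
    segment = mirna_seq[seg0 : seg0 + cfg.mirna_len]
    window_start = max(0, site.start - cfg.target_window)
    target = utr[window_start : site.end]
    site_seq = utr[site.start : site.end]
    dg_full = duplex_backend(target, seed_region + segment)
    dg_seed = duplex_backend(site_seq, seed_region)
    return float(dg_full - dg_seed)


def three_prime_score(
    mirna_seq: str,
    utr: str,
    site: SiteMatch,
    max_offset: int = 7,
) -> float:
    """3P_score: the pairing-based score of 3' supplementary pairing.

    The best contiguous Watson-Crick run between the miRNA 3' region
    (nucleotide 9 onward) and the target region upstream of the seed match
    is scored with weight 1.0 per pair overlapping miRNA nucleotides 13-16
    and 0.5 elsewhere, minus 0.5 per nucleotide of loop-length asymmetry
    beyond 2.  Retained as the older alternative to ``3P_energy``.
    """
    mirna_seq = normalize_rna(mirna_seq)
    utr = normalize_rna(utr)
    tail = mirna_seq[8:]  # miRNA nt 9.. (index j -> miRNA position 9+j)
    upstream = utr[max(0, site.start - len(tail) - max_offset) : site.start]
    if not tail or not upstream:
        return 0.0
    best = 0.0
    n_up = len(upstream)
    for offset in range(-max_offset, max_offset + 1):
        # target position pairing miRNA nt (9+j) is n_up-1-j-offset
        run, run_best = 0.0, 0.0
        for j in range(len(tail)):
            pos = n_up - 1 - j - offset
            if 0 <= pos < n_up and pairs_wc(upstream[pos], tail[j]):
                run += 1.0 if 13 <= 9 + j <= 16 else 0.5
                run_best = max(run_best, run)
            else:
                run = 0.0
        penalty = 0.5 * max(0, abs(offset) - 2)
        best = max(best, run_best - penalty)
    return best


def structural_accessibility(
    utr: str,
    site: SiteMatch,
    cfg: AccessibilityConfig = AccessibilityConfig(),
    fold_backend=None,
) -> float:
    """SA: log10 mean unpaired probability near the seed match.

    The ``fold_span``-nt region centred on the seed match (truncated at
    UTR boundaries) is folded; the score averages the per-base unpaired
    probabilities over the window positions inside the folded segment.
    """
    if fold_backend is None:
        from .backends import vienna_fold_backend as fold_backend
    utr = normalize_rna(utr)
    mid = (site.start + site.end) // 2
    seg_start = max(0, mid - cfg.fold_span // 2)
    seg_end = min(len(utr), seg_start + cfg.fold_span)
    segment = utr[seg_start:seg_end]
    probs = np.asarray(fold_backend(segment), dtype=float)

    center = _m7_position(site) + cfg.center
    win_start = center - (cfg.window - 1) // 2
    win_end = win_start + cfg.window
    lo = max(win_start, seg_start)
    hi = min(win_end, seg_end)
    if hi <= lo:
        raise ValueError("accessibility window is empty after truncation")
    mean_p = float(probs[lo - seg_start : hi - seg_start].mean())
    return math.log10(mean_p) if mean_p > 0 else -math.inf


def local_au(utr: str, site: SiteMatch, flank: int = 30) -> float:
    """Fraction of A/U in the up-to-*flank*-nt regions flanking the site.

    Both flanks are pooled unweighted; the site itself is excluded and
    flanks are truncated at the UTR boundaries.
    """
    utr = normalize_rna(utr)
    left = utr[max(0, site.start - flank) : site.start]
    right = utr[site.end : site.end + flank]
    both = left + right
    return au_fraction(both) if both else 0.0


def positional_and_bulk_features(
    utr5: str, orf: str, utr3: str, site: SiteMatch
) -> dict[str, float]:
    """Length, AU-content and positional features of the host mRNA.

    Distances run from the nearest end of the site to the 3' UTR boundary
    (stop codon upstream, poly(A) cleavage site downstream), floored at
    1 nt before log10; lengths are log10(len + 1).
    """
    dist_stop = max(site.start, 1)
    dist_polya = max(len(utr3) - site.end, 1)
    return {
        "len_5UTR": math.log10(len(utr5) + 1),
        "len_ORF": math.log10(len(orf) + 1),
        "len_3UTR": math.log10(len(utr3) + 1),
        "AU_5UTR": au_fraction(utr5),
        "AU_ORF": au_fraction(orf),
        "AU_3UTR": au_fraction(utr3),
        "dist_stop": math.log10(dist_stop),
        "min_dist": math.log10(min(dist_stop, dist_polya)),
    }


@dataclass(frozen=True)
class FeatureVector:
    """The 17 context features of one (site, mRNA) pair."""

    site_type: SiteType
    site9: str
    site10: str
    local_AU: float
    threep_score: float
    threep_energy: float
    SA: float
    PCT: float
    len_5UTR: float
    len_ORF: float
    len_3UTR: float
    AU_5UTR: float
    AU_ORF: float
    AU_3UTR: float
    dist_stop: float
    min_dist: float
    other_sites: int

    def __post_init__(self) -> None:
        if self.SA > 0:
            raise ValueError("SA is a log10 probability and must be <= 0")
        if not 0.0 <= self.PCT <= 1.0:
            raise ValueError("PCT must lie in [0, 1]")
        for name in ("local_AU", "AU_5UTR", "AU_ORF", "AU_3UTR"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.other_sites < 0:
            raise ValueError("other_sites must be >= 0")

    def as_dict(self) -> dict[str, object]:
        """Feature values keyed by their published abbreviations."""
        rename = {"threep_score": "3P_score", "threep_energy": "3P_energy"}
        return {
            rename.get(f.name, f.name): getattr(self, f.name)
            for f in fields(self)
        }

    def to_numeric(self) -> dict[str, float]:
        """Numeric encoding for regression.

        ``site_type`` is left out (it is modelled by the per-type
        intercept); nucleotide identities become A/U indicators.
        """
        d = self.as_dict()
        d.pop("site_type")
        for key in ("site9", "site10"):
            d[key] = 1.0 if d[key] in ("A", "U") else 0.0
        return {k: float(v) for k, v in d.items()}


def assemble_feature_vector(
    mirna: MirnaRecord,
    utr5: str,
    orf: str,
    utr3: str,
    site: SiteMatch,
    pct: float | None = None,
    pairing_cfg: PairingWindowConfig = PairingWindowConfig(),
    sa_cfg: AccessibilityConfig = AccessibilityConfig(),
    duplex_backend=None,
    fold_backend=None,
) -> FeatureVector:
    """Compute all 17 features for one 7-8-nt 3' UTR site.

    *pct* of ``None`` means no conservation estimate is available (poorly
    conserved family, or a site overlapping annotated ORF sequence) and
    scores 0.
    """
    from .site_finder import count_other_sites

    utr3 = normalize_rna(utr3)
    return FeatureVector(
        site_type=site.site_type,
        site9=_opposite(site, utr3, 9),
        site10=_opposite(site, utr3, 10),
        local_AU=local_au(utr3, site),
        threep_score=three_prime_score(mirna.mature_seq, utr3, site),
        threep_energy=three_prime_pairing_energy(
            mirna.mature_seq, utr3, site, pairing_cfg, duplex_backend
        ),
        SA=structural_accessibility(utr3, site, sa_cfg, fold_backend),
        PCT=0.0 if pct is None else float(pct),
        other_sites=count_other_sites(utr5, orf, utr3, mirna),
        **positional_and_bulk_features(utr5, orf, utr3, site),
    )


# ---------------------------------------------------------------------------
# Grid-search optimisers for the two windowed features


def optimize_pairing_window(
    data: list[tuple[str, str, SiteMatch, float]],
    duplex_backend=None,
    mirna_starts: range = range(9, 20),
    mirna_lens: range = range(4, 14),
    target_windows: range = range(4, 21),
) -> pd.DataFrame:
    """Grid search of the 3' pairing window against observed repression.

    *data* rows are ``(mirna_seq, utr3, site, fold_change)`` for mRNAs with
    a single 7-8-nt 3' UTR site.  For every (start, length, window)
    combination the partial correlation between 3P_energy and fold change,
    controlling for site type, is computed.  Default ranges give the
    11 x 10 x 17 = 1870-combination grid.
    """
    from .evaluation import partial_correlation

    if len(data) < 3:
        raise ValueError("need at least 3 data points for the grid search")
    fold_changes = np.array([fc for *_, fc in data])
    labels = [site.site_type.value for _, _, site, _ in data]
    records = []
    for start in mirna_starts:
        for length in mirna_lens:
            for window in target_windows:
                cfg = PairingWindowConfig(start, length, window)
                energies = np.array([
                    three_prime_pairing_energy(m, u, s, cfg, duplex_backend)
                    for m, u, s, _ in data
                ])
                r = partial_correlation(energies, fold_changes, labels)
                records.append(
                    {"mirna_start": start, "mirna_len": length,
                     "target_window": window, "partial_r": r}
                )
    return pd.DataFrame.from_records(records)


def optimize_sa_window(
    data: list[tuple[str, SiteMatch, float]],
    fold_backend=None,
    centers: range = range(-20, 21),
    windows: range = range(1, 26),
    fold_span: int = 80,
) -> pd.DataFrame:
    """Grid search of the accessibility window against observed repression.

    *data* rows are ``(utr3, site, fold_change)``.  Each site's fold-span
    segment is folded once; every (center, window) cell then averages the
    cached unpaired probabilities.  Default ranges give the 41 x 25 grid.
    """
    from .evaluation import partial_correlation

    if fold_backend is None:
        from .backends import vienna_fold_backend as fold_backend
    if len(data) < 3:
        raise ValueError("need at least 3 data points for the grid search")
    fold_changes = np.array([fc for *_, fc in data])
    labels = [site.site_type.value for _, site, _ in data]

    cached = []
    for utr, site, _ in data:
        utr = normalize_rna(utr)
        mid = (site.start + site.end) // 2
        seg_start = max(0, mid - fold_span // 2)
        seg_end = min(len(utr), seg_start + fold_span)
        probs = np.asarray(fold_backend(utr[seg_start:seg_end]), dtype=float)
        cached.append((probs, seg_start, seg_end, _m7_position(site)))

    records = []
    for center in centers:
        for window in windows:
            values = np.empty(len(data))
            for i, (probs, seg_start, seg_end, anchor) in enumerate(cached):
                c = anchor + center
                lo = max(c - (window - 1) // 2, seg_start)
                hi = min(c - (window - 1) // 2 + window, seg_end)
                if hi <= lo:
                    values[i] = np.nan
                    continue
                mean_p = probs[lo - seg_start : hi - seg_start].mean()
                values[i] = math.log10(mean_p) if mean_p > 0 else -12.0
            ok = ~np.isnan(values)
            r = (
                partial_correlation(
                    values[ok], fold_changes[ok],
                    [labels[i] for i in range(len(data)) if ok[i]],
                )
                if ok.sum() >= 3
                else np.nan
            )
            records.append({"center": center, "window": window, "partial_r": r})
    return pd.DataFrame.from_records(records)
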