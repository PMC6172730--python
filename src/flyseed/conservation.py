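"""Evolutionary conservation of seed-matched sites.

The conservation analysis asks, for every canonical site, how deeply it is
conserved across an insect phylogeny, and whether sites of a given miRNA
family and type are conserved in excess of matched background.  The parts
are:

* **Branch-length score (BLS)** — the total branch length of the minimal
  subtree connecting the reference species with every species whose
  orthologous alignment columns still contain a same-type site.  A site
  present only in the reference scores 0; a site in every species scores
  the total tree length.
* **Conservation bins** — UTRs are split into five bins by the median
  per-nucleotide BLS of their reference nucleotides, and branch lengths
  are re-estimated per bin so that a site's BLS is measured against the
  background substitution rate of its own UTR context (bin 1 = least
  conserved background, bin 5 = most).
* **Signal:background curves** — the signal at a branch-length cutoff is
  the number of sites whose BLS reaches the cutoff; the background is the
  count expected by chance, estimated from 50 length-matched control
  k-mers with similar expected conservation (from aggregated dinucleotide
  conservation rates).
* **P_CT** — the probability of conserved targeting,
  ``max(0, (S - B) / S)`` at the site's BLS on its (family, type, bin)
  curve, smoothed to be monotone non-decreasing in BLS.  Aggregate P_CT
  combines the sites of one family in one UTR as ``1 - prod(1 - p_i)``.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize
from sklearn.isotonic import IsotonicRegression

from .seqtools import normalize_rna
from .site_finder import SiteMatch, SiteType, site_patterns

logger = logging.getLogger(__name__)

__all__ = [
    "MultipleAlignment",
    "TreeIndex",
    "BlsRecord",
    "SignalBackgroundCurve",
    "PctParameters",
    "bin_utrs",
    "fit_bin_trees",
    "motif_bls",
    "site_bls",
    "control_kmers",
    "signal_background_curve",
    "lower_confidence_limit",
    "fit_pct_parameters",
    "pct_score",
    "aggregate_pct",
    "simulate_conserved_gene_count",
]

_GAP = "-"


@dataclass
class MultipleAlignment:
    """A gapped multiple alignment of one UTR across species.

    The reference row, with gaps removed, is the UTR sequence itself.
    """

    rows: dict[str, str]
    reference: str
    region_label: str = ""

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if self.reference not in self.rows:
            raise ValueError(f"reference row {self.reference!r} absent")

    @property
    def n_columns(self) -> int:
        return len(self.rows[self.reference])

    def reference_sequence(self) -> str:
        return self.rows[self.reference].replace(_GAP, "")

    def reference_columns(self) -> np.ndarray:
        """Alignment column index of each reference (ungapped) position."""
        ref = self.rows[self.reference]
        return np.array([i for i, b in enumerate(ref) if b != _GAP], dtype=int)


class TreeIndex:
    """A species tree indexed for fast spanning-subtree length queries."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.leaves = sorted(
            leaf.taxon.label for leaf in tree.leaf_node_iter()
        )
        self._leaf_bit = {name: 1 << i for i, name in enumerate(self.leaves)}
        self._edges: list[tuple[int, float]] = []  # (leafset bitmask, length)
        for node in tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            mask = 0
            for leaf in node.leaf_iter():
                mask |= self._leaf_bit[leaf.taxon.label]
            self._edges.append((mask, node.edge.length or 0.0))
        self.total_length = sum(length for _, length in self._edges)

    @classmethod
    def from_newick(cls, newick: str) -> "TreeIndex":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def spanning_length(self, species: set[str]) -> float:
        """Total branch length of the minimal subtree connecting *species*.

        An edge belongs to the subtree iff it separates the species set
        into two non-empty parts.  Fewer than two species span nothing.
        """
        mask = 0
        for sp in species:
            bit = self._leaf_bit.get(sp)
            if bit is not None:
                mask |= bit
        if bin(mask).count("1") < 2:
            return 0.0
        total = 0.0
        for below, length in self._edges:
            inside = mask & below
            if inside and inside != mask:
                total += length
        return total


@dataclass(frozen=True)
class BlsRecord:
    """A site together with its branch-length score and conservation bin."""

    site: SiteMatch
    bls: float
    bin: int

    def __post_init__(self) -> None:
        if self.bls < 0:
            raise ValueError("BLS must be >= 0")
        if not 1 <= self.bin <= 5:
            raise ValueError("conservation bin must be in 1..5")


# ---------------------------------------------------------------------------
# Conservation bins and per-bin branch-length fitting


def per_nucleotide_bls(alignment: MultipleAlignment, tree: TreeIndex) -> np.ndarray:
    """BLS of each reference nucleotide: species sharing the reference base."""
    cols = alignment.reference_columns()
    ref_row = alignment.rows[alignment.reference]
    out = np.zeros(len(cols))
    species_rows = [
        (sp, row) for sp, row in alignment.rows.items() if sp != alignment.reference
    ]
    for i, c in enumerate(cols):
        base = ref_row[c]
        kept = {alignment.reference}
        for sp, row in species_rows:
            if row[c] == base:
                kept.add(sp)
        out[i] = tree.spanning_length(kept)
    return out


def bin_utrs(
    alignments: dict[str, MultipleAlignment],
    tree: TreeIndex,
    n_bins: int = 5,
    utr_ids: list[str] | None = None,
) -> dict[str, int]:
    """Assign each UTR a conservation bin 1 (lowest) .. 5 (highest).

    The statistic is the median per-nucleotide BLS over the UTR; UTRs are
    quintile-split on it.  UTRs listed in *utr_ids* but absent from the
    alignments fall back to bin 1 with a warning.
    """
    if len(alignments) < n_bins:
        raise ValueError(f"need >= {n_bins} aligned UTRs to form {n_bins} bins")
    medians = {
        utr_id: float(np.median(per_nucleotide_bls(aln, tree)))
        for utr_id, aln in alignments.items()
    }
    ordered = sorted(medians, key=lambda u: (medians[u], u))
    n = len(ordered)
    bins = {
        utr_id: min(n_bins, 1 + (rank * n_bins) // n)
        for rank, utr_id in enumerate(ordered)
    }
    for utr_id in utr_ids or []:
        if utr_id not in bins:
            logger.warning("UTR %s absent from alignments; assigned bin 1", utr_id)
            bins[utr_id] = 1
    return bins


_BASES = "ACGU"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _jc_matrix(t: float) -> np.ndarray:
    """Jukes-Cantor transition probabilities for branch length *t*."""
    e = np.exp(-4.0 * t / 3.0)
    same = 0.25 + 0.75 * e
    diff = 0.25 - 0.25 * e
    p = np.full((4, 4), diff)
    np.fill_diagonal(p, same)
    return p


def _concatenate_patterns(
    alignments: list[MultipleAlignment], species: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Site patterns (codes per species) and their counts, gaps = missing."""
    counter: Counter[tuple[int, ...]] = Counter()
    for aln in alignments:
        ncol = aln.n_columns
        rows = [aln.rows.get(sp, _GAP * ncol) for sp in species]
        for c in range(ncol):
            pattern = tuple(_BASE_INDEX.get(row[c], 4) for row in rows)
            if all(code == 4 for code in pattern):
                continue
            counter[pattern] += 1
    patterns = np.array(list(counter.keys()), dtype=int)
    counts = np.array(list(counter.values()), dtype=float)
    return patterns, counts


def fit_bin_trees(
    alignments: list[MultipleAlignment],
    topology: TreeIndex,
    min_length: float = 1e-8,
    max_length: float = 10.0,
) -> TreeIndex:
    """Re-estimate branch lengths on a fixed topology by maximum likelihood.

    A single-rate Jukes-Cantor substitution model is pruned over the
    concatenated alignment columns (gap = missing data).  Returns a new
    :class:`TreeIndex` whose topology equals the input but whose branch
    lengths maximise the likelihood, so that each conservation bin gets a
    tree reflecting its own substitution rate.
    """
    if not alignments:
        raise ValueError("no alignments to fit branch lengths from")
    tree = topology.tree.clone(depth=1)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    patterns, counts = _concatenate_patterns(alignments, species)
    if patterns.size == 0:
        raise ValueError("alignments contain no informative columns")

    nodes = [n for n in tree.postorder_node_iter()]
    edge_nodes = [n for n in nodes if n.parent_node is not None]
    leaf_pos = {sp: i for i, sp in enumerate(species)}

    # Pre-build leaf conditional likelihoods: (n_patterns, 4) per leaf.
    leaf_cl = {}
    for node in nodes:
        if node.is_leaf():
            codes = patterns[:, leaf_pos[node.taxon.label]]
            cl = np.ones((len(patterns), 4))
            known = codes < 4
            cl[known] = 0.0
            cl[known, codes[known]] = 1.0
            leaf_cl[node] = cl

    def neg_log_likelihood(lengths: np.ndarray) -> float:
        pmats = {node: _jc_matrix(t) for node, t in zip(edge_nodes, lengths)}
        cl: dict[object, np.ndarray] = {}
        scale_log = np.zeros(len(patterns))
        for node in nodes:
            if node.is_leaf():
                cl[node] = leaf_cl[node]
                continue
            prod = np.ones((len(patterns), 4))
            for child in node.child_nodes():
                prod *= cl[child] @ pmats[child].T
                del cl[child]
            # rescale to avoid underflow on deep trees
            mx = prod.max(axis=1)
            mx[mx == 0] = 1.0
            prod /= mx[:, None]
            scale_log += np.log(mx)
            cl[node] = prod
        root = nodes[-1]
        site_lik = cl[root].mean(axis=1)  # uniform 1/4 root frequencies
        site_lik = np.maximum(site_lik, 1e-300)
        return -float(np.sum(counts * (np.log(site_lik) + scale_log)))

    x0 = np.array([
        max(node.edge.length or 0.1, 0.05) for node in edge_nodes
    ])
    res = minimize(
        neg_log_likelihood,
        x0,
        method="L-BFGS-B",
        bounds=[(min_length, max_length)] * len(edge_nodes),
    )
    for node, t in zip(edge_nodes, res.x):
        node.edge.length = float(t)
    return TreeIndex(tree)


# ---------------------------------------------------------------------------
# Site-level BLS


def motif_bls(
    pattern: str,
    start: int,
    alignment: MultipleAlignment,
    tree: TreeIndex,
) -> float:
    """Branch-length score of a motif occurrence at a reference position.

    A species retains the occurrence when its aligned orthologous columns,
    after gap removal, still contain the motif (no positional slack beyond
    those columns).  Used both for canonical sites and for control k-mers.
    """
    cols = alignment.reference_columns()
    end = start + len(pattern)
    if start < 0 or end > len(cols):
        raise ValueError(
            f"occurrence [{start}, {end}) outside aligned reference span "
            f"of {len(cols)} nt"
        )
    c0, c1 = cols[start], cols[end - 1] + 1
    kept = {alignment.reference}
    for sp, row in alignment.rows.items():
        if sp == alignment.reference:
            continue
        segment = row[c0:c1].replace(_GAP, "")
        if pattern in segment:
            kept.add(sp)
    return tree.spanning_length(kept)


def site_bls(
    site: SiteMatch,
    alignment: MultipleAlignment,
    tree: TreeIndex,
) -> float:
    """Branch-length score of one canonical site.

    A species retains the site when its aligned orthologous columns, after
    gap removal, contain a match of the same type for the same family.
    """
    pattern = site_patterns(site.family_key)[site.site_type]
    return motif_bls(pattern, site.start, alignment, tree)


# ---------------------------------------------------------------------------
# Control k-mers


def dinucleotide_conservation_rates(
    alignments: dict[str, MultipleAlignment] | list[MultipleAlignment],
) -> dict[str, float]:
    """Genome-aggregated conservation rate of each reference dinucleotide.

    An instance of a dinucleotide is conserved in a species when both
    aligned bases equal the reference bases.  Rates are pooled over all
    species and alignments.
    """
    if isinstance(alignments, dict):
        alignments = list(alignments.values())
    seen: Counter[str] = Counter()
    conserved: Counter[str] = Counter()
    for aln in alignments:
        cols = aln.reference_columns()
        ref_row = aln.rows[aln.reference]
        others = [row for sp, row in aln.rows.items() if sp != aln.reference]
        for i in range(len(cols) - 1):
            c0, c1 = cols[i], cols[i + 1]
            dinuc = ref_row[c0] + ref_row[c1]
            if any(b not in _BASES for b in dinuc):
                continue
            for row in others:
                seen[dinuc] += 1
                if row[c0] == dinuc[0] and row[c1] == dinuc[1]:
                    conserved[dinuc] += 1
    return {
        d: (conserved[d] / seen[d]) if seen[d] else 0.0 for d in seen
    }


def expected_kmer_conservation(kmer: str, rates: dict[str, float]) -> float:
    """Expected conservation of a k-mer: product of its dinucleotide rates."""
    kmer = normalize_rna(kmer)
    p = 1.0
    for i in range(len(kmer) - 1):
        p *= rates.get(kmer[i : i + 2], 0.0)
    return p


def control_kmers(
    site_kmer: str,
    utr_sequences: list[str],
    rates: dict[str, float],
    conserved_family_keys: list[str] = (),
    n: int = 50,
) -> list[str]:
    """Length-matched control k-mers with similar expected conservation.

    Candidates are the distinct k-mers occurring in *utr_sequences*; k-mers
    that equal a canonical site of any conserved family (or the site k-mer
    itself) are excluded.  The *n* candidates nearest to the site k-mer in
    expected conservation are returned; if fewer exist, all are returned
    with a warning.
    """
    site_kmer = normalize_rna(site_kmer)
    k = len(site_kmer)
    forbidden = {site_kmer}
    for fam in conserved_family_keys:
        forbidden.update(site_patterns(fam).values())

    candidates = set()
    for seq in utr_sequences:
        seq = normalize_rna(seq)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if kmer not in forbidden and all(b in _BASES for b in kmer):
                candidates.add(kmer)

    target = expected_kmer_conservation(site_kmer, rates)
    ranked = sorted(
        candidates,
        key=lambda km: (abs(expected_kmer_conservation(km, rates) - target), km),
    )
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} control candidates available for {site_kmer} "
            f"(requested {n})",
            stacklevel=2,
        )
    return ranked[:n]


# ---------------------------------------------------------------------------
# Signal:background curves, confidence limits, P_CT


@dataclass
class SignalBackgroundCurve:
    """Conserved-site counts vs. matched-control expectation by BLS cutoff."""

    family_key: str
    site_type: SiteType
    cutoffs: np.ndarray
    signal: np.ndarray
    background: np.ndarray
    background_sd: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        """Signal:background; NaN where the background is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.background > 0, self.signal / self.background, np.nan
            )

    @property
    def signal_above(self) -> np.ndarray:
        return self.signal - self.background


def signal_background_curve(
    family_key: str,
    site_type: SiteType,
    site_bls_by_bin: dict[int, np.ndarray],
    control_bls_by_bin: dict[int, list[np.ndarray]],
    cutoffs: np.ndarray,
) -> SignalBackgroundCurve:
    """Signal and background counts over branch-length cutoffs.

    ``site_bls_by_bin[b]`` holds the BLS of every site of this family/type
    whose UTR is in bin *b*; ``control_bls_by_bin[b][j]`` holds the BLS of
    every occurrence of control k-mer *j* in bin *b* (index *j* refers to
    the same control across bins).  Counts are computed per bin and summed:
    the background contributed by bin *b* is the mean conserved fraction of
    its controls times the bin's site count, and the spread across the
    controls gives the background SD.
    """
    cutoffs = np.asarray(cutoffs, dtype=float)
    total_sites = sum(len(v) for v in site_bls_by_bin.values())
    if total_sites == 0:
        empty = np.zeros(0)
        return SignalBackgroundCurve(
            family_key, site_type, np.zeros(0), empty, empty.copy(), empty.copy()
        )

    n_controls = max(
        (len(v) for v in control_bls_by_bin.values()), default=0
    )
    signal = np.zeros(len(cutoffs))
    # per-control background counts, accumulated over bins
    per_control = np.zeros((max(n_controls, 1), len(cutoffs)))
    for b, site_vals in site_bls_by_bin.items():
        site_vals = np.asarray(site_vals, dtype=float)
        n_b = len(site_vals)
        if n_b == 0:
            continue
        signal += (site_vals[:, None] >= cutoffs[None, :]).sum(axis=0)
        controls = control_bls_by_bin.get(b, [])
        for j in range(n_controls):
            occ = np.asarray(controls[j], dtype=float) if j < len(controls) else np.zeros(0)
            if len(occ) == 0:
                continue
            frac = (occ[:, None] >= cutoffs[None, :]).mean(axis=0)
            per_control[j] += frac * n_b
    background = per_control.mean(axis=0)
    background_sd = per_control.std(axis=0, ddof=1) if n_controls > 1 else np.zeros(
        len(cutoffs)
    )
    return SignalBackgroundCurve(
        family_key, site_type, cutoffs, signal, background, background_sd
    )


def lower_confidence_limit(
    curve: SignalBackgroundCurve, level: float = 0.05
) -> np.ndarray:
    """One-sided lower confidence bound on the signal above background.

    A z-test against the empirical spread of the 50 control k-mers:
    ``signal_above - z_(1-level) * background_sd``.
    """
    from scipy.stats import norm

    z = norm.ppf(1.0 - level)
    return curve.signal_above - z * curve.background_sd


@dataclass
class PctParameters:
    """Monotone BLS -> P_CT maps per (family, site type, conservation bin)."""

    curves: dict[tuple[str, SiteType, int], tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add(
        self,
        family_key: str,
        site_type: SiteType,
        bin: int,
        cutoffs: np.ndarray,
        pct: np.ndarray,
    ) -> None:
        pct = np.asarray(pct, dtype=float)
        if np.any(pct < 0) or np.any(pct > 1):
            raise ValueError("P_CT values must lie in [0, 1]")
        if np.any(np.diff(pct) < -1e-12):
            raise ValueError("P_CT curve must be non-decreasing in BLS")
        self.curves[(family_key, site_type, bin)] = (
            np.asarray(cutoffs, dtype=float), pct,
        )


def fit_pct_parameters(
    family_key: str,
    site_type: SiteType,
    per_bin_curves: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]],
) -> PctParameters:
    """Fit P_CT curves from per-bin (cutoffs, signal, background) triples.

    The raw estimate at each cutoff is ``max(0, (S - B) / S)``; isotonic
    regression then enforces monotone non-decrease in BLS.
    """
    params = PctParameters()
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
    for b, (cutoffs, signal, background) in per_bin_curves.items():
        signal = np.asarray(signal, dtype=float)
        background = np.asarray(background, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.where(signal > 0, (signal - background) / signal, 0.0)
        raw = np.clip(raw, 0.0, 1.0)
        smooth = iso.fit_transform(np.asarray(cutoffs, dtype=float), raw)
        params.add(family_key, site_type, b, cutoffs, smooth)
    return params


def pct_score(record: BlsRecord, params: PctParameters) -> float:
    """P_CT of one site: its curve evaluated at the site's BLS.

    The curve is a right-continuous step function over the cutoffs; a BLS
    below the lowest cutoff scores 0.  A missing curve scores 0 with a
    warning.
    """
    key = (record.site.family_key, record.site.site_type, record.bin)
    if key not in params.curves:
        warnings.warn(
            f"no P_CT curve for {key}; scoring 0", stacklevel=2
        )
        return 0.0
    cutoffs, pct = params.curves[key]
    idx = np.searchsorted(cutoffs, record.bls, side="right") - 1
    if idx < 0:
        return 0.0
    return float(pct[idx])


def aggregate_pct(site_pcts: list[float]) -> float:
    """Combine the P_CT of several sites: ``1 - prod(1 - p_i)``.

    The combined value is the probability that at least one site is
    preferentially conserved, assuming independence; it never falls below
    the largest individual P_CT.  An empty list scores 0.
    """
    out = 1.0
    for p in site_pcts:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"P_CT {p} outside [0, 1]")
        out *= 1.0 - p
    return 1.0 - out


# ---------------------------------------------------------------------------
# Conserved-gene-count simulation


def simulate_conserved_gene_count(
    utr5_site_genes: list[str],
    utr3_site_genes: list[str],
    n5_dist: tuple[float, float] = (840.0, 40.0),
    n3_dist: tuple[float, float] = (12285.0, 214.0),
    reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Monte-Carlo estimate of the number of genes with conserved sites.

    Each replicate draws the number of preferentially conserved 5' UTR and
    3' UTR sites from the two normal distributions, samples that many sites
    without replacement from the respective gene-labelled pools, and counts
    the unique genes hit.  Returns the mean and the symmetric 90% interval
    (5th and 95th percentiles) over replicates.
    """
    if not utr5_site_genes and not utr3_site_genes:
        raise ValueError("both site pools are empty")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pools = [np.asarray(utr5_site_genes), np.asarray(utr3_site_genes)]
    dists = [n5_dist, n3_dist]
    counts = np.zeros(reps)
    warned = False
    for r in range(reps):
        genes: set[str] = set()
        for pool, (mu, sd) in zip(pools, dists):
            if len(pool) == 0:
                continue
            n = int(round(rng.normal(mu, sd)))
            n = max(n, 0)
            if n > len(pool):
                if not warned:
                    logger.warning(
                        "draw %d exceeds pool size %d; truncating", n, len(pool)
                    )
                    warned = True
                n = len(pool)
            take = rng.choice(len(pool), size=n, replace=False)
            genes.update(pool[take])
        counts[r] = len(genes)
    lo, hi = np.percentile(counts, [5.0, 95.0])
    return float(counts.mean()), (float(lo), float(hi))
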