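"""Poly(A)-site calling and tandem 3' UTR isoform profiles from 3'-end tags.

3P-seq/3'-seq tags mark mRNA cleavage-and-polyadenylation positions.
Clustering the tags calls poly(A) sites; grouping nearby 3' UTR ends
yields the tandem isoforms of a gene, whose normalised tag counts form
the *UTR profile*: the fraction ``f(p)`` of transcript molecules whose
3' UTR extends beyond position ``p``.  ``f`` is the weight applied to a
site's context score, since only isoforms that contain the site can
respond to the miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .site_finder import SiteMatch

logger = logging.getLogger(__name__)

__all__ = [
    "EndTag",
    "PolyASite",
    "UtrProfile",
    "cluster_tags",
    "mark_known",
    "group_ends_and_longest",
    "build_profile",
    "dominant_isoform",
    "site_weight",
    "extend_reference_utrs",
]


@dataclass(frozen=True)
class EndTag:
    """One 3'-end tag position with total and unique read counts."""

    position: int
    count: int
    unique_count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1 or self.unique_count < 1:
            raise ValueError("tag counts must be >= 1")
        if self.unique_count > self.count:
            raise ValueError("unique_count cannot exceed count")


@dataclass(frozen=True)
class PolyASite:
    """A called poly(A) site: a tag cluster passing the read thresholds."""

    representative_position: int
    total_reads: int
    unique_reads: int
    known: bool = False


def cluster_tags(
    tags: list[EndTag],
    radius: int = 30,
    min_reads: int = 3,
    min_unique: int = 2,
) -> list[PolyASite]:
    """Greedy clustering of 3'-end tags into poly(A) sites.

    Positions are visited in descending read-count order (ties by
    ascending position); the highest-count position absorbs every tag
    within *radius* nt and the cluster is removed.  Clusters below
    *min_reads* total or *min_unique* unique reads are dropped.  The
    representative position is the one supported by the most reads.
    """
    remaining = sorted(tags, key=lambda t: (-t.count, t.position))
    active = list(remaining)
    sites: list[PolyASite] = []
    while active:
        seed = active[0]
        members = [t for t in active if abs(t.position - seed.position) <= radius]
        active = [t for t in active if abs(t.position - seed.position) > radius]
        total = sum(t.count for t in members)
        unique = sum(t.unique_count for t in members)
        rep = max(members, key=lambda t: (t.count, -t.position)).position
        if total >= min_reads and unique >= min_unique:
            sites.append(PolyASite(rep, total, unique))
    sites.sort(key=lambda s: s.representative_position)
    return sites


def mark_known(
    sites: list[PolyASite],
    annotation_ends: list[int],
    tolerance: int = 20,
) -> list[PolyASite]:
    """Flag poly(A) sites within *tolerance* nt of an annotated site."""
    ends = np.asarray(sorted(annotation_ends)) if annotation_ends else None
    out = []
    for s in sites:
        if ends is None:
            known = False
        else:
            i = int(np.searchsorted(ends, s.representative_position))
            near = [
                ends[j] for j in (i - 1, i) if 0 <= j < len(ends)
            ]
            known = any(
                abs(int(e) - s.representative_position) <= tolerance for e in near
            )
        out.append(replace(s, known=known))
    return out


def group_ends_and_longest(
    sites: list[PolyASite],
    radius: int = 30,
    min_fraction: float = 0.01,
) -> tuple[list[tuple[int, int]], int | None]:
    """Group nearby 3' UTR ends and pick the longest supported isoform.

    Ends within *radius* nt of each other merge into one isoform group
    carrying the combined read count (representative = the most-read end
    of the group).  The longest 3' UTR is the most distal group holding at
    least *min_fraction* of all reads (``None`` when no sites).

    Returns ``(groups, longest_end)`` where groups are
    ``(representative_end, combined_reads)`` sorted by position.
    """
    if not sites:
        return [], None
    ordered = sorted(sites, key=lambda s: s.representative_position)
    groups: list[list[PolyASite]] = [[ordered[0]]]
    for s in ordered[1:]:
        if s.representative_position - groups[-1][-1].representative_position <= radius:
            groups[-1].append(s)
        else:
            groups.append([s])
    merged = []
    for g in groups:
        rep = max(g, key=lambda s: (s.total_reads, -s.representative_position))
        merged.append((rep.representative_position, sum(s.total_reads for s in g)))
    total = sum(c for _, c in merged)
    longest = None
    for end, c in merged:
        if c >= min_fraction * total:
            longest = end
    return merged, longest


@dataclass
class UtrProfile:
    """Tandem 3' UTR isoform ends with normalised tag fractions.

    Positions are nt downstream of the stop codon (i.e. 3' UTR
    coordinates).  ``f(p)`` is the fraction of transcripts whose 3' UTR
    extends strictly beyond position *p*; it starts at 1 and decreases to
    0 past the most distal end.
    """

    ends: list[int]
    fractions: list[float]
    stop_codon: int = 0

    def __post_init__(self) -> None:
        if len(self.ends) != len(self.fractions):
            raise ValueError("ends and fractions must align")
        if self.ends:
            if sorted(self.ends) != list(self.ends):
                order = np.argsort(self.ends)
                self.ends = [self.ends[i] for i in order]
                self.fractions = [self.fractions[i] for i in order]
            total = sum(self.fractions)
            if abs(total - 1.0) > 1e-9:
                if total <= 0:
                    raise ValueError("isoform fractions must sum to a positive value")
                self.fractions = [f / total for f in self.fractions]

    def f(self, position: int) -> float:
        """Fraction of transcript molecules extending beyond *position*."""
        return float(
            sum(frac for end, frac in zip(self.ends, self.fractions)
                if end > position)
        )


def build_profile(
    end_groups: list[tuple[int, float]], stop_codon: int = 0
) -> UtrProfile:
    """Build a UTR profile from (end position, normalised count) groups."""
    if not end_groups:
        raise ValueError("cannot build a profile without isoform ends")
    ends = [e for e, _ in end_groups]
    counts = [c for _, c in end_groups]
    return UtrProfile(ends=ends, fractions=counts, stop_codon=stop_codon)


def dominant_isoform(
    profile: UtrProfile, homogeneity: float = 0.9
) -> int | None:
    """The single dominant isoform end, if one holds >= 90% of the tags."""
    for end, frac in zip(profile.ends, profile.fractions):
        if frac >= homogeneity:
            return end
    return None


def site_weight(profile: UtrProfile, site: SiteMatch) -> float:
    """Fraction of 3' UTR molecules containing the site: ``f(site end)``.

    A site is contained in an isoform when the isoform's 3' end lies at or
    beyond the site's last nucleotide.
    """
    return profile.f(site.end - 1)


@dataclass(frozen=True)
class _StopModel:
    """Per-stop-codon inputs for reference-UTR construction."""

    gene_id: str
    transcript_id: str
    stop_codon: int
    annotated_end: int
    orf_len: int
    intronic: bool = False
    downstream_exon_start: int | None = None


def extend_reference_utrs(
    stop_models: list[_StopModel],
    tags_by_stop: dict[int, list[EndTag]],
    min_intronic_reads: int = 10,
    rep_tag_fraction: float = 0.6,
    radius: int = 30,
    min_fraction: float = 0.01,
) -> tuple[dict[int, int], dict[str, str]]:
    """Reference 3' UTR end per stop codon plus a representative transcript.

    For each unique stop codon the reference 3' UTR is the longest
    supported isoform end from the tag clusters (for stop codons in
    upstream alternative last exons, an intronic cleavage site needs at
    least *min_intronic_reads* reads and may not pass the next annotated
    exon).  Genes with several stop codons pick the representative
    transcript with the longest ORF among those with at least
    *rep_tag_fraction* of the maximum tag count of the gene; when its UTR
    interval overlaps another UTR of the same gene, the transcript with
    the longest UTR wins instead.  Genes without tags keep their
    annotation.
    """
    ref_end: dict[int, int] = {}
    tag_totals: dict[int, float] = {}
    for sm in stop_models:
        tags = tags_by_stop.get(sm.stop_codon, [])
        tag_totals[sm.stop_codon] = sum(t.count for t in tags)
        if not tags:
            ref_end[sm.stop_codon] = sm.annotated_end
            continue
        sites = cluster_tags(tags, radius=radius)
        if sm.intronic:
            sites = [
                s for s in sites
                if s.total_reads >= min_intronic_reads
                and (sm.downstream_exon_start is None
                     or s.representative_position < sm.downstream_exon_start)
            ]
        _, longest = group_ends_and_longest(
            sites, radius=radius, min_fraction=min_fraction
        )
        ref_end[sm.stop_codon] = (
            max(longest, sm.annotated_end) if longest is not None
            else sm.annotated_end
        )

    rep: dict[str, str] = {}
    by_gene: dict[str, list[_StopModel]] = {}
    for sm in stop_models:
        by_gene.setdefault(sm.gene_id, []).append(sm)
    for gene, models in by_gene.items():
        if len(models) == 1:
            rep[gene] = models[0].transcript_id
            continue
        max_tags = max(tag_totals[m.stop_codon] for m in models)
        eligible = [
            m for m in models
            if max_tags == 0 or tag_totals[m.stop_codon] >= rep_tag_fraction * max_tags
        ] or models
        choice = max(eligible, key=lambda m: (m.orf_len, m.transcript_id))
        # overlap rule: if the chosen UTR interval overlaps another UTR of
        # the gene, fall back to the transcript with the longest UTR
        c_lo, c_hi = choice.stop_codon, ref_end[choice.stop_codon]
        overlaps = any(
            m is not choice
            and max(c_lo, m.stop_codon) < min(c_hi, ref_end[m.stop_codon])
            for m in models
        )
        if overlaps:
            choice = max(
                models,
                key=lambda m: (ref_end[m.stop_codon] - m.stop_codon, m.transcript_id),
            )
        rep[gene] = choice.transcript_id
    return ref_end, rep


# exported under its public name
StopModel = _StopModel
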