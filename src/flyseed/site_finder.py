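"""Seed families and canonical seed-matched site discovery.

A miRNA recognises targets mainly through its seed region (nucleotides
2-8).  The six canonical site types are the perfect 6-8-nt Watson-Crick
matches to this region, read 5'->3' on the target:

========== =========================== ======
site type  definition                   length
========== =========================== ======
8mer       match to nt 2-8 + A1             8
7mer-m8    match to nt 2-8                  7
7mer-A1    match to nt 2-7 + A1             7
6mer       match to nt 2-7                  6
offset-6mer match to nt 3-8                 6
6mer-A1    match to nt 2-6 + A1             6
========== =========================== ======

"A1" denotes an adenosine in the target opposite miRNA position 1; it is
recognised by a dedicated Argonaute pocket regardless of the identity of
miRNA nucleotide 1, so it is required to be an A in the *target*, not a
pair to the miRNA.

One genomic locus yields one site: a lower-priority match whose interval
is contained in a higher-priority match at the same locus (e.g. the
7mer-m8 inside every 8mer) is not reported separately.  Priority follows
efficacy: 8mer > 7mer-m8 > 7mer-A1 > 6mer > offset-6mer > 6mer-A1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .seqtools import normalize_rna, revcomp

__all__ = [
    "SiteType",
    "Region",
    "MirnaRecord",
    "SiteMatch",
    "seed_family_of",
    "site_patterns",
    "classify_window",
    "find_sites",
    "count_other_sites",
    "annotate_mirna_isoforms",
    "SITE_TYPE_PRIORITY",
]


class SiteType(str, Enum):
    """The six canonical site types, in decreasing order of efficacy."""

    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"
    SIXMER = "6mer"
    OFFSET_SIXMER = "offset-6mer"
    SIXMER_A1 = "6mer-A1"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Classification priority (highest first) used to resolve overlapping loci.
SITE_TYPE_PRIORITY = [
    SiteType.EIGHTMER,
    SiteType.SEVENMER_M8,
    SiteType.SEVENMER_A1,
    SiteType.SIXMER,
    SiteType.OFFSET_SIXMER,
    SiteType.SIXMER_A1,
]

#: 7-8-nt site types (the effective classes used for scoring / P_CT).
STRONG_TYPES = frozenset(
    {SiteType.EIGHTMER, SiteType.SEVENMER_M8, SiteType.SEVENMER_A1}
)

#: Marginal 6-nt site types.
WEAK_TYPES = frozenset(
    {SiteType.SIXMER, SiteType.OFFSET_SIXMER, SiteType.SIXMER_A1}
)

SITE_TYPE_LENGTH = {
    SiteType.EIGHTMER: 8,
    SiteType.SEVENMER_M8: 7,
    SiteType.SEVENMER_A1: 7,
    SiteType.SIXMER: 6,
    SiteType.OFFSET_SIXMER: 6,
    SiteType.SIXMER_A1: 6,
}


class Region(str, Enum):
    UTR5 = "UTR5"
    ORF = "ORF"
    UTR3 = "UTR3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ConservationClass(str, Enum):
    BILATERIAN = "bilaterian"
    DROSOPHILID = "drosophilid"
    POORLY_CONSERVED = "poorly_conserved"
    OTHER_ANNOTATION = "other_annotation"


def seed_family_of(mature_seq: str) -> str:
    """Seed-family key of a mature miRNA: nucleotides 2-8 (1-based).

    miRNAs sharing nucleotides 2-8 target the same sites and are grouped
    into one family.
    """
    seq = normalize_rna(mature_seq)
    if len(seq) < 8:
        raise ValueError(
            f"mature miRNA must be >= 8 nt to define a seed family, got {len(seq)}"
        )
    return seq[1:8]


@dataclass(frozen=True)
class MirnaRecord:
    """A mature miRNA with its family key (nt 2-8) and conservation class."""

    name: str
    mature_seq: str
    conservation_class: ConservationClass = ConservationClass.POORLY_CONSERVED
    family_key: str = field(init=False)

    def __post_init__(self) -> None:
        seq = normalize_rna(self.mature_seq)
        object.__setattr__(self, "mature_seq", seq)
        object.__setattr__(self, "family_key", seed_family_of(seq))


@dataclass(frozen=True)
class SiteMatch:
    """One canonical seed-matched site in one region of one mRNA.

    Coordinates are 0-based half-open within the region sequence.
    """

    gene_id: str
    region: Region
    start: int
    end: int
    site_type: SiteType
    family_key: str

    def __post_init__(self) -> None:
        expected = SITE_TYPE_LENGTH[self.site_type]
        if self.end - self.start != expected:
            raise ValueError(
                f"{self.site_type.value} site must span {expected} nt, "
                f"got [{self.start}, {self.end})"
            )


def site_patterns(family_key: str) -> dict[SiteType, str]:
    """Target-strand (5'->3') match strings for each canonical site type.

    ``family_key`` is the miRNA's nucleotides 2-8.  The match string for a
    type is the reverse complement of the paired miRNA positions, with an
    explicit 3'-terminal ``A`` for the A1 types.
    """
    fam = normalize_rna(family_key)
    if len(fam) != 7:
        raise ValueError(f"family key must be 7 nt (miRNA nt 2-8), got {fam!r}")
    m2_8 = fam  # miRNA nt 2..8
    m2_7 = fam[:6]
    m3_8 = fam[1:]
    m2_6 = fam[:5]
    return {
        SiteType.EIGHTMER: revcomp(m2_8) + "A",
        SiteType.SEVENMER_M8: revcomp(m2_8),
        SiteType.SEVENMER_A1: revcomp(m2_7) + "A",
        SiteType.SIXMER: revcomp(m2_7),
        SiteType.OFFSET_SIXMER: revcomp(m3_8),
        SiteType.SIXMER_A1: revcomp(m2_6) + "A",
    }


def classify_window(window: str, family_key: str) -> SiteType | None:
    """Classify the locus starting at the first base of *window*.

    Returns the single highest-priority site type whose match string is a
    prefix of *window* (so the caller should pass at least 8 nt of target
    sequence when available), or ``None``.
    """
    window = normalize_rna(window)
    patterns = site_patterns(family_key)
    for site_type in SITE_TYPE_PRIORITY:
        pat = patterns[site_type]
        if window.startswith(pat):
            return site_type
    return None


def _candidate_matches(
    region_seq: str, patterns: dict[SiteType, str]
) -> list[tuple[int, int, SiteType]]:
    out = []
    n = len(region_seq)
    for site_type in SITE_TYPE_PRIORITY:
        pat = patterns[site_type]
        k = len(pat)
        for i in range(n - k + 1):
            if region_seq[i : i + k] == pat:
                out.append((i, i + k, site_type))
    return out


def find_sites(
    region_seq: str,
    family: MirnaRecord | str,
    region: Region = Region.UTR3,
    gene_id: str = "",
) -> list[SiteMatch]:
    """All canonical sites of one seed family in one region sequence.

    Each locus is reported once, at its highest-priority type: a candidate
    match whose interval lies inside a higher-priority candidate's interval
    is suppressed.  Sites are returned sorted by start coordinate.
    """
    seq = normalize_rna(region_seq)
    family_key = family.family_key if isinstance(family, MirnaRecord) else family
    patterns = site_patterns(family_key)
    candidates = _candidate_matches(seq, patterns)

    priority = {t: i for i, t in enumerate(SITE_TYPE_PRIORITY)}
    kept: list[tuple[int, int, SiteType]] = []
    for start, end, site_type in candidates:
        contained = any(
            ks <= start and end <= ke and priority[kt] < priority[site_type]
            for ks, ke, kt in candidates
            if (ks, ke, kt) != (start, end, site_type)
        )
        if not contained:
            kept.append((start, end, site_type))

    kept.sort(key=lambda c: (c[0], priority[c[2]]))
    return [
        SiteMatch(gene_id=gene_id, region=region, start=s, end=e,
                  site_type=t, family_key=family_key)
        for s, e, t in kept
    ]


def count_other_sites(
    utr5: str, orf: str, utr3: str, family: MirnaRecord | str
) -> int:
    """Count of weak canonical sites in an mRNA.

    This is the ``other_sites`` context feature: 8mer sites in the 5' UTR
    and ORF, plus 6mer, offset-6mer and 6mer-A1 sites in the 3' UTR.
    7-8-nt 3' UTR sites are deliberately excluded (they are scored
    directly, not counted here).
    """
    n = 0
    for region_seq, region in ((utr5, Region.UTR5), (orf, Region.ORF)):
        n += sum(
            1
            for s in find_sites(region_seq, family, region)
            if s.site_type is SiteType.EIGHTMER
        )
    n += sum(
        1
        for s in find_sites(utr3, family, Region.UTR3)
        if s.site_type in WEAK_TYPES
    )
    return n


def annotate_mirna_isoforms(
    hairpin_pileup: dict[int, int],
    arm_of: dict[int, str],
    base_name: str = "mir",
    min_fraction: float = 1 / 3,
) -> list[tuple[str, int, int]]:
    """Name abundant 5'-isoforms of a miRNA hairpin from a read pileup.

    *hairpin_pileup* maps read start position -> read count; *arm_of* maps
    start position -> arm label (``"5p"``/``"3p"``).  Starts with at least
    *min_fraction* (default 33%) of the reads of the most abundant start
    are kept.  Isoforms on different arms are suffixed ``-5p``/``-3p``;
    multiple isoforms from the same arm are suffixed ``.1``, ``.2``, ... in
    decreasing abundance.

    Returns ``(name, start, count)`` tuples sorted by decreasing count.
    """
    if any(c < 0 for c in hairpin_pileup.values()):
        raise ValueError("read counts must be non-negative")
    max_count = max(hairpin_pileup.values(), default=0)
    if max_count == 0:
        raise ValueError("all-zero pileup: no reads to annotate isoforms from")

    keep = [
        (start, count)
        for start, count in hairpin_pileup.items()
        if count >= min_fraction * max_count
    ]
    keep.sort(key=lambda sc: (-sc[1], sc[0]))

    per_arm: dict[str, int] = {}
    for start, _ in keep:
        arm = arm_of.get(start, "5p")
        per_arm[arm] = per_arm.get(arm, 0) + 1

    out = []
    seen_on_arm: dict[str, int] = {}
    for start, count in keep:
        arm = arm_of.get(start, "5p")
        seen_on_arm[arm] = seen_on_arm.get(arm, 0) + 1
        if per_arm[arm] == 1:
            name = f"{base_name}-{arm}"
        else:
            name = f"{base_name}.{seen_on_arm[arm]}"
        out.append((name, start, count))
    return out
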