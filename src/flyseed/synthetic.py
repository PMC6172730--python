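"""Synthetic fly-like worlds with planted ground truth.

Every module of the package is testable without downloads: this module
generates short AU-rich 3' UTRs (log-normal lengths, median ~200 nt, as
observed for fly), mature miRNAs, planted canonical sites with effect
sizes following the site-type efficacy hierarchy, substitution-only
alignments evolved along a small insect-like tree with preferential
retention of planted sites, 3'-end tag pileups over tandem isoform ends,
and fold-change matrices combining site effects, isoform weighting,
covariate bias, batch structure and Gaussian noise.  The planted truth
(site coordinates, effects, isoform fractions) is emitted alongside the
data so recovery tests are closed-loop.

All randomness flows from one integer seed through fixed stream indices,
so each sub-generator is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .annotation_io import TranscriptModel
from .conservation import MultipleAlignment, TreeIndex
from .isoform_profiles import EndTag, UtrProfile
from .seqtools import normalize_rna
from .site_finder import (
    SITE_TYPE_LENGTH,
    MirnaRecord,
    Region,
    SiteMatch,
    SiteType,
    find_sites,
    site_patterns,
)

__all__ = ["WorldConfig", "World", "make_world", "evolve_alignment",
           "simulate_fold_changes", "random_utr"]

_BASES = np.array(list("ACGU"))

DEFAULT_TREE = "((dmel:0.2,dsim:0.2):0.3,(dyak:0.4,dana:0.4):0.2,dpse:0.8);"

#: Planted per-site log2 repression by type, following the efficacy
#: hierarchy 8mer > 7mer-m8 > 7mer-A1 > 6mer ~ offset-6mer ~ 6mer-A1.
DEFAULT_EFFECTS = {
    SiteType.EIGHTMER: -0.45,
    SiteType.SEVENMER_M8: -0.30,
    SiteType.SEVENMER_A1: -0.18,
    SiteType.SIXMER: -0.06,
    SiteType.OFFSET_SIXMER: -0.06,
    SiteType.SIXMER_A1: -0.05,
}


@dataclass
class WorldConfig:
    """Parameters of one synthetic world.

    Defaults mirror fly-scale observations: ~200-nt median 3' UTRs,
    ~60% AU content, six transfected miRNAs, repression effects ordered by
    site type, and modest experimental noise.
    """

    n_genes: int = 300
    n_mirnas: int = 6
    utr3_median: float = 202.0
    utr3_sigma: float = 0.55
    utr5_median: float = 120.0
    orf_median: float = 1200.0
    au_content: float = 0.60
    site_probability: float = 0.55
    effects: dict[SiteType, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    noise_sd: float = 0.25
    batch_sd: float = 0.15
    covariate_coef: float = 0.08  # bias per log10 3' UTR length unit
    tree_newick: str = DEFAULT_TREE
    reference_species: str = "dmel"
    substitution_rate: float = 1.0
    conserved_site_retention: float = 0.95
    tag_depth: int = 200
    max_isoforms: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conserved_site_retention <= 1.0:
            raise ValueError("retention must be a probability")
        if any(e > 0 for e in self.effects.values()):
            raise ValueError("repression effect sizes must be <= 0")


@dataclass
class World:
    """A generated world: inputs for every module plus the planted truth."""

    config: WorldConfig
    mirnas: list[MirnaRecord]
    transcripts: list[TranscriptModel]
    sites: pd.DataFrame  # gene_id, mirna, family, region, start, end, site_type, effect
    profiles: dict[str, UtrProfile]
    tags: dict[str, list[EndTag]]
    alignments: dict[str, MultipleAlignment]
    tree: TreeIndex
    fold_changes: pd.DataFrame  # genes x miRNA names

    def site_matches(self, gene_id: str) -> list[SiteMatch]:
        rows = self.sites[self.sites.gene_id == gene_id]
        return [
            SiteMatch(
                gene_id=r.gene_id, region=Region(r.region), start=int(r.start),
                end=int(r.end), site_type=SiteType(r.site_type),
                family_key=r.family,
            )
            for r in rows.itertuples()
        ]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream generator: one root seed, fixed per-purpose stream index."""
    return np.random.default_rng([seed, stream])


def _random_seq(rng: np.random.Generator, length: int, au: float) -> str:
    p = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def random_utr(rng: np.random.Generator, median: float, sigma: float,
               au: float, minimum: int = 30) -> str:
    length = max(minimum, int(round(float(rng.lognormal(math.log(median), sigma)))))
    return _random_seq(rng, length, au)


def _scrub_except(
    seq: str,
    keep: list[tuple[int, int, str]],
    families: list[str],
    rng: np.random.Generator,
    max_iter: int = 500,
) -> str | None:
    """Mutate away every canonical match not sanctioned by *keep*.

    *keep* lists planted ``(start, end, family)`` intervals.  A match is
    sanctioned when its interval lies inside a kept interval of the same
    family (sub-matches of a planted site are suppressed downstream by the
    one-locus-one-site rule).  Violations are destroyed by mutating a base
    outside all kept intervals; returns ``None`` when that is impossible.
    """
    chars = list(seq)
    keep_mask = np.zeros(len(seq), dtype=bool)
    for a, b, _ in keep:
        keep_mask[a:b] = True
    patterns = [
        (fam, pat) for fam in families for pat in site_patterns(fam).values()
    ]
    for _ in range(max_iter):
        text = "".join(chars)
        violation = None
        for fam, pat in patterns:
            start = text.find(pat)
            while start != -1:
                s, e = start, start + len(pat)
                sanctioned = any(
                    a <= s and e <= b and fam == f for a, b, f in keep
                )
                if not sanctioned:
                    violation = (s, e)
                    break
                start = text.find(pat, start + 1)
            if violation:
                break
        if violation is None:
            return text
        s, e = violation
        mutable = [i for i in range(s, e) if not keep_mask[i]]
        if not mutable:
            return None
        pos = mutable[int(rng.integers(len(mutable)))]
        old = chars[pos]
        chars[pos] = [b for b in "ACGU" if b != old][int(rng.integers(3))]
    return None  # pragma: no cover - scrubbing did not converge


def _scrub_sites(seq: str, families: list[str], rng: np.random.Generator) -> str:
    """Mutate away every accidental canonical match to any family."""
    out = _scrub_except(seq, [], families, rng)
    if out is None:  # pragma: no cover - cannot happen without keep intervals
        raise RuntimeError("could not scrub accidental sites")
    return out


def evolve_alignment(
    ref_seq: str,
    tree: TreeIndex,
    rate: float,
    conserved_intervals: list[tuple[int, int]] = (),
    retention: float = 1.0,
    reference: str = "dmel",
    rng: np.random.Generator | int = 0,
) -> MultipleAlignment:
    """Evolve a reference sequence over a tree (substitutions only).

    The tree is traversed outward from the reference leaf; along each edge
    every position substitutes under Jukes-Cantor at ``rate`` x branch
    length.  Positions inside a conserved interval are copied unchanged
    with probability *retention* per interval per edge (otherwise they
    evolve neutrally), emulating purifying selection on planted sites.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    ref_seq = normalize_rna(ref_seq)
    n = len(ref_seq)

    # undirected adjacency over the dendropy tree
    nodes = list(tree.tree.preorder_node_iter())
    adj: dict[int, list[tuple[int, float]]] = {id(x): [] for x in nodes}
    node_of = {id(x): x for x in nodes}
    for node in nodes:
        parent = node.parent_node
        if parent is not None:
            length = node.edge.length or 0.0
            adj[id(node)].append((id(parent), length))
            adj[id(parent)].append((id(node), length))
    ref_leaf = next(
        x for x in nodes
        if x.is_leaf() and x.taxon.label == reference
    )

    conserved_mask = np.zeros(n, dtype=bool)
    for a, b in conserved_intervals:
        conserved_mask[a:b] = True

    def mutate(seq: np.ndarray, t: float) -> np.ndarray:
        p_diff = 0.75 * (1.0 - math.exp(-4.0 * rate * t / 3.0))
        out = seq.copy()
        hit = rng.random(n) < p_diff
        protected = np.zeros(n, dtype=bool)
        for a, b in conserved_intervals:
            if rng.random() < retention:
                protected[a:b] = True
        hit &= ~protected
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = [b for b in "ACGU" if b != out[i]]
            out[i] = choices[int(rng.integers(3))]
        return out

    rows: dict[str, str] = {}
    seq0 = np.array(list(ref_seq))
    stack = [(id(ref_leaf), None, seq0)]
    while stack:
        nid, parent_id, seq = stack.pop()
        node = node_of[nid]
        if node.is_leaf():
            rows[node.taxon.label] = "".join(seq)
        for other, length in adj[nid]:
            if other != parent_id:
                stack.append((other, nid, mutate(seq, length)))
    return MultipleAlignment(rows=rows, reference=reference)


def simulate_fold_changes(
    transcripts: list[TranscriptModel],
    sites: pd.DataFrame,
    profiles: dict[str, UtrProfile],
    mirnas: list[MirnaRecord],
    cfg: WorldConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """log2 fold-change matrix from planted effects plus structured noise.

    Per gene and transfected miRNA: the sum of planted site effects times
    the isoform weight of each site, a covariate bias proportional to
    log10 3' UTR length, a shared rank-one batch component, and Gaussian
    noise.
    """
    gene_ids = [t.gene_id for t in transcripts]
    mat = pd.DataFrame(0.0, index=gene_ids, columns=[m.name for m in mirnas])
    utr3_len = {t.gene_id: len(t.utr3) for t in transcripts}

    for row in sites.itertuples():
        mirna_name = row.mirna
        if mirna_name not in mat.columns:
            continue
        weight = 1.0
        profile = profiles.get(row.gene_id)
        if profile is not None:
            weight = profile.f(int(row.end) - 1)
        mat.loc[row.gene_id, mirna_name] += row.effect * weight

    log_len = np.array([math.log10(utr3_len[g] + 1) for g in gene_ids])
    bias = cfg.covariate_coef * (log_len - log_len.mean())
    batch_gene = rng.normal(0.0, cfg.batch_sd, size=len(gene_ids))
    batch_load = rng.normal(1.0, 0.2, size=len(mirnas))
    noise = rng.normal(0.0, cfg.noise_sd, size=mat.shape)
    mat += bias[:, None] + np.outer(batch_gene, batch_load) + noise
    return mat


def _plant_isoforms(
    utr_len: int, cfg: WorldConfig, rng: np.random.Generator
) -> tuple[UtrProfile, list[EndTag]]:
    n_iso = int(rng.integers(1, cfg.max_isoforms + 1))
    if utr_len < 60:
        n_iso = 1
    ends = sorted(
        rng.choice(np.arange(utr_len // 2, utr_len), size=n_iso, replace=False)
    ) if n_iso > 1 else [utr_len]
    ends = sorted(set(int(e) for e in ends) | {utr_len})
    fracs = rng.dirichlet(np.full(len(ends), 1.5))
    counts = np.maximum(1, np.round(fracs * cfg.tag_depth).astype(int))
    tags = [
        EndTag(position=end, count=int(c), unique_count=max(1, int(c) // 2))
        for end, c in zip(ends, counts)
    ]
    profile = UtrProfile(
        ends=list(ends), fractions=(counts / counts.sum()).tolist()
    )
    return profile, tags


def make_world(cfg: WorldConfig) -> World:
    """Generate a complete synthetic world from one configuration.

    The same seed yields byte-identical output.  Background sequences are
    scrubbed of accidental canonical matches before sites are planted, so
    the truth table lists exactly the sites a scan should find.
    """
    rng_mirna = _rng(cfg.seed, 1)
    rng_seq = _rng(cfg.seed, 2)
    rng_site = _rng(cfg.seed, 3)
    rng_iso = _rng(cfg.seed, 4)
    rng_fc = _rng(cfg.seed, 5)
    rng_aln = _rng(cfg.seed, 6)

    # distinct seed families
    mirnas: list[MirnaRecord] = []
    seen_keys: set[str] = set()
    while len(mirnas) < cfg.n_mirnas:
        seq = _random_seq(rng_mirna, 22, 0.5)
        rec = MirnaRecord(name=f"miR-{len(mirnas) + 1}", mature_seq=seq)
        if rec.family_key in seen_keys:
            continue
        seen_keys.add(rec.family_key)
        mirnas.append(rec)
    families = [m.family_key for m in mirnas]

    site_types = list(SITE_TYPE_LENGTH)
    transcripts: list[TranscriptModel] = []
    site_rows: list[dict] = []
    profiles: dict[str, UtrProfile] = {}
    tags: dict[str, list[EndTag]] = {}
    alignments: dict[str, MultipleAlignment] = {}
    tree = TreeIndex.from_newick(cfg.tree_newick)

    for g in range(cfg.n_genes):
        gene_id = f"G{g:04d}"
        utr5 = _scrub_sites(
            random_utr(rng_seq, cfg.utr5_median, 0.4, cfg.au_content), families, rng_seq
        )
        orf_len = max(150, int(rng_seq.lognormal(math.log(cfg.orf_median), 0.4)))
        orf_len -= orf_len % 3
        orf = _scrub_sites(
            _random_seq(rng_seq, orf_len, 0.45), families, rng_seq
        )
        utr3 = _scrub_sites(
            random_utr(rng_seq, cfg.utr3_median, cfg.utr3_sigma, cfg.au_content),
            families, rng_seq,
        )

        planted: list[tuple[int, int]] = []
        if rng_site.random() < cfg.site_probability:
            mirna = mirnas[int(rng_site.integers(len(mirnas)))]
            site_type = site_types[int(rng_site.integers(len(site_types)))]
            pattern = site_patterns(mirna.family_key)[site_type]
            k = len(pattern)
            if len(utr3) > k + 20:
                for _ in range(5):  # retry if the junction cannot be cleaned
                    start = int(rng_site.integers(10, len(utr3) - k - 10))
                    candidate = utr3[:start] + pattern + utr3[start + k:]
                    cleaned = _scrub_except(
                        candidate, [(start, start + k, mirna.family_key)],
                        families, rng_site,
                    )
                    if cleaned is not None:
                        utr3 = cleaned
                        planted.append((start, start + k))
                        site_rows.append(
                            {
                                "gene_id": gene_id, "mirna": mirna.name,
                                "family": mirna.family_key,
                                "region": Region.UTR3.value,
                                "start": start, "end": start + k,
                                "site_type": site_type.value,
                                "effect": cfg.effects[site_type],
                            }
                        )
                        break

        transcripts.append(
            TranscriptModel(
                gene_id=gene_id, transcript_id=f"{gene_id}.1",
                utr5=utr5, orf=orf, utr3=utr3, stop_codon_pos=len(utr5) + len(orf),
            )
        )
        profiles[gene_id], tags[gene_id] = _plant_isoforms(len(utr3), cfg, rng_iso)
        alignments[gene_id] = evolve_alignment(
            utr3, tree, cfg.substitution_rate, planted,
            cfg.conserved_site_retention, cfg.reference_species, rng_aln,
        )

    sites = pd.DataFrame(
        site_rows,
        columns=["gene_id", "mirna", "family", "region", "start", "end",
                 "site_type", "effect"],
    )
    fold_changes = simulate_fold_changes(
        transcripts, sites, profiles, mirnas, cfg, rng_fc
    )
    return World(
        config=cfg, mirnas=mirnas, transcripts=transcripts, sites=sites,
        profiles=profiles, tags=tags, alignments=alignments, tree=tree,
        fold_changes=fold_changes,
    )


# ---------------------------------------------------------------------------
# File output (all plain text)


def write_world(world: World, outdir: str | Path) -> dict[str, Path]:
    """Write a world to standard formats; returns the paths written."""
    from Bio import AlignIO, SeqIO
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .annotation_io import write_gene_models

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tx_records = [
        SeqRecord(Seq(t.utr5 + t.orf + t.utr3), id=t.transcript_id, description="")
        for t in world.transcripts
    ]
    paths["transcripts_fasta"] = outdir / "transcripts.fa"
    SeqIO.write(tx_records, paths["transcripts_fasta"], "fasta")

    paths["gene_models"] = outdir / "models.gff3"
    write_gene_models(paths["gene_models"], world.transcripts)

    mirna_records = [
        SeqRecord(Seq(m.mature_seq), id=m.name, description="")
        for m in world.mirnas
    ]
    paths["mirnas_fasta"] = outdir / "mirnas.fa"
    SeqIO.write(mirna_records, paths["mirnas_fasta"], "fasta")

    paths["tree"] = outdir / "species.nwk"
    paths["tree"].write_text(world.config.tree_newick + "\n")

    blocks = []
    for gene_id, aln in sorted(world.alignments.items()):
        records = []
        ref_first = [aln.reference] + sorted(
            sp for sp in aln.rows if sp != aln.reference
        )
        for sp in ref_first:
            row = aln.rows[sp]
            rec = SeqRecord(Seq(row), id=f"{sp}.{gene_id}")
            rec.annotations.update(
                {"start": 0, "size": len(row.replace('-', '')),
                 "strand": 1, "srcSize": len(row)}
            )
            records.append(rec)
        blocks.append(MultipleSeqAlignment(records))
    paths["maf"] = outdir / "utr3.maf"
    with open(paths["maf"], "w") as fh:
        AlignIO.write(blocks, fh, "maf")

    paths["tags_bed"] = outdir / "tags.bed"
    with open(paths["tags_bed"], "w") as fh:
        for gene_id, gene_tags in sorted(world.tags.items()):
            for t in gene_tags:
                fh.write(
                    f"{gene_id}\t{t.position}\t{t.position + 1}\t"
                    f"u{t.unique_count}\t{t.count}\t+\n"
                )

    paths["fold_changes"] = outdir / "fold_changes.tsv"
    world.fold_changes.rename_axis("gene_id").to_csv(
        paths["fold_changes"], sep="\t"
    )

    paths["truth_sites"] = outdir / "truth_sites.tsv"
    world.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    return paths
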