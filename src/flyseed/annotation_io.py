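"""Reading gene models and expression tables; representative-transcript choice.

Gene models are consumed as transcript-level FASTA/GFF3 and reduced to one
representative transcript per gene before any downstream analysis.  The
representative transcript is the isoform with the longest ORF (ties broken
by longest 3' UTR, then longest 5' UTR, then transcript id), and its 3' UTR
is replaced by the longest 3' UTR among isoforms sharing the same stop
codon, so that alternative tandem 3' ends are not lost.

Coordinates are 0-based half-open internally; report output is 1-based
inclusive.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqtools import normalize_rna

__all__ = [
    "TranscriptModel",
    "ExpressionRecord",
    "select_representative_transcript",
    "filter_expressed",
    "read_transcript_fasta",
    "write_transcript_fasta",
    "read_gene_models",
    "write_gene_models",
    "read_expression_table",
    "read_alignment_blocks",
]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform split into 5' UTR, ORF and 3' UTR sequences."""

    gene_id: str
    transcript_id: str
    utr5: str
    orf: str
    utr3: str
    stop_codon_pos: int = -1  # genomic 0-based; -1 when unknown
    orf_complete: bool = True

    def __post_init__(self) -> None:
        for attr in ("utr5", "orf", "utr3"):
            object.__setattr__(self, attr, normalize_rna(getattr(self, attr)))
        if self.orf_complete and len(self.orf) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: complete ORF length {len(self.orf)} "
                "not divisible by 3"
            )


@dataclass(frozen=True)
class ExpressionRecord:
    """Mock-transfection expression (FPKM) and log2 fold change for one gene."""

    gene_id: str
    fpkm_mock: float
    fold_change: float = 0.0

    def __post_init__(self) -> None:
        if self.fpkm_mock < 0:
            raise ValueError(f"{self.gene_id}: negative FPKM {self.fpkm_mock}")


def select_representative_transcript(
    models: list[TranscriptModel],
) -> TranscriptModel:
    """Pick one representative isoform for a gene.

    Longest ORF wins; ties break by longest 3' UTR, then longest 5' UTR,
    then lexicographically smallest transcript id (so the choice is a pure
    function of the set, not of input order).  The winner's 3' UTR is then
    replaced by the longest 3' UTR among isoforms sharing its stop codon.
    """
    if not models:
        raise ValueError("no transcripts")
    best = min(
        models,
        key=lambda m: (-len(m.orf), -len(m.utr3), -len(m.utr5), m.transcript_id),
    )
    same_stop = [m for m in models if m.stop_codon_pos == best.stop_codon_pos]
    longest_utr3 = max(same_stop, key=lambda m: (len(m.utr3), m.transcript_id)).utr3
    if longest_utr3 != best.utr3:
        best = replace(best, utr3=longest_utr3)
    return best


def filter_expressed(
    records: list[ExpressionRecord], threshold: float = 5.0
) -> set[str]:
    """Genes whose mock-condition FPKM strictly exceeds *threshold*.

    The default of 5.0 FPKM removes poorly expressed genes whose
    fold-change measurements are too noisy to use.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return {r.gene_id for r in records if r.fpkm_mock > threshold}


# ---------------------------------------------------------------------------
# FASTA / GFF3 / TSV plumbing


def read_transcript_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{id: RNA sequence}`` (T normalised to U)."""
    return {
        rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_transcript_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


_GFF_COLS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attrs",
]


def _attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(
    gff_path: str | Path, genome: dict[str, str]
) -> list[TranscriptModel]:
    """Assemble transcript models from GFF3 features on transcript sequences.

    Features ``five_prime_UTR``, ``CDS`` and ``three_prime_UTR`` are read;
    each must carry ``Parent`` (transcript id) and the transcript carries
    ``gene_id`` via its Parent-less attribute or a ``gene_id`` key.  The
    ``seqid`` column names the sequence in *genome* on which the (1-based,
    inclusive) coordinates live.
    """
    per_tx: dict[str, dict[str, list[tuple[str, int, int]]]] = {}
    tx_gene: dict[str, str] = {}
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            row = dict(zip(_GFF_COLS, fields))
            attrs = _attrs(row["attrs"])
            if row["type"] in {"five_prime_UTR", "CDS", "three_prime_UTR"}:
                tx = attrs.get("Parent", "")
                d = per_tx.setdefault(tx, {"five_prime_UTR": [], "CDS": [],
                                           "three_prime_UTR": []})
                d[row["type"]].append(
                    (row["seqid"], int(row["start"]) - 1, int(row["end"]))
                )
                if "gene_id" in attrs:
                    tx_gene[tx] = attrs["gene_id"]
            elif row["type"] in {"mRNA", "transcript"}:
                tx_gene[attrs.get("ID", "")] = attrs.get(
                    "Parent", attrs.get("gene_id", "")
                )

    models = []
    for tx, feats in sorted(per_tx.items()):
        parts = {}
        stop_pos = -1
        for feat_type, key in (
            ("five_prime_UTR", "utr5"), ("CDS", "orf"), ("three_prime_UTR", "utr3")
        ):
            seq = ""
            for seqid, start, end in sorted(feats[feat_type], key=lambda f: f[1]):
                seq += normalize_rna(genome[seqid])[start:end]
            parts[key] = seq
        if feats["CDS"]:
            stop_pos = max(end for _, _, end in feats["CDS"])
        models.append(
            TranscriptModel(
                gene_id=tx_gene.get(tx, tx),
                transcript_id=tx,
                utr5=parts["utr5"],
                orf=parts["orf"],
                utr3=parts["utr3"],
                stop_codon_pos=stop_pos,
                orf_complete=len(parts["orf"]) % 3 == 0,
            )
        )
    return models


def write_gene_models(
    gff_path: str | Path, models: list[TranscriptModel]
) -> None:
    """Write transcript models as GFF3 with each transcript as its own seqid.

    Coordinates are laid out 5' UTR / CDS / 3' UTR contiguously on the
    transcript sequence (1-based inclusive), which round-trips through
    :func:`read_gene_models` given the transcript FASTA.
    """
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            pos = 0
            fh.write(
                f"{m.transcript_id}\tflyseed\tmRNA\t1\t"
                f"{len(m.utr5) + len(m.orf) + len(m.utr3)}\t.\t+\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for feat_type, seq in (
                ("five_prime_UTR", m.utr5), ("CDS", m.orf), ("three_prime_UTR", m.utr3)
            ):
                if seq:
                    phase = "0" if feat_type == "CDS" else "."
                    fh.write(
                        f"{m.transcript_id}\tflyseed\t{feat_type}\t{pos + 1}\t"
                        f"{pos + len(seq)}\t.\t+\t{phase}\t"
                        f"Parent={m.transcript_id};gene_id={m.gene_id}\n"
                    )
                pos += len(seq)


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a TSV with columns gene_id, fpkm_mock and fold-change column(s).

    With several fold-change columns the first is used; use pandas directly
    for the full matrix.
    """
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fc_cols = [c for c in (reader.fieldnames or [])
                   if c not in {"gene_id", "fpkm_mock"}]
        for row in reader:
            fc = float(row[fc_cols[0]]) if fc_cols else 0.0
            out.append(
                ExpressionRecord(
                    gene_id=row["gene_id"],
                    fpkm_mock=float(row["fpkm_mock"]),
                    fold_change=fc,
                )
            )
    return out


def read_alignment_blocks(
    maf_path: str | Path, reference: str
):
    """Read MAF alignment blocks into per-UTR multiple alignments.

    The reference species must appear first in each block; the block is
    keyed by the reference row's sequence name (``species.utr_id``).
    Returns a dict ``{utr_id: MultipleAlignment}``.
    """
    from .conservation import MultipleAlignment  # local import: avoid cycle

    out = {}
    for block in AlignIO.parse(str(maf_path), "maf"):
        rows: dict[str, str] = {}
        utr_id = None
        lengths = set()
        for rec in block:
            species, _, seq_name = rec.id.partition(".")
            rows[species] = normalize_rna(str(rec.seq))
            lengths.add(len(rec.seq))
            if utr_id is None:
                if species != reference:
                    raise ValueError(
                        f"reference species {reference!r} must be first in "
                        f"each MAF block, found {species!r}"
                    )
                utr_id = seq_name
        if len(lengths) > 1:
            raise ValueError(f"ragged row lengths in MAF block {utr_id!r}")
        if reference not in rows:
            raise ValueError(f"reference row absent from block {utr_id!r}")
        out[utr_id] = MultipleAlignment(
            rows=rows, reference=reference, region_label=utr_id or ""
        )
    return out
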