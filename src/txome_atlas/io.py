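"""Readers and writers for FASTA / GFF3 / GTF / BED junction / TSV files.

Every reader converts file coordinates to the internal 0-based half-open
convention; every writer converts back. GFF3 and GTF are 1-based inclusive,
BED is already 0-based half-open. Attribute-column parsing is delegated to
:mod:`gffutils` (which auto-detects the GFF3 vs GTF dialect); this module
only validates coordinates and groups features into models.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .core import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    Genome,
    SpliceJunction,
    TranscriptModel,
)


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_sequence(genome: Genome, interval: GenomicInterval, strand: str = "+") -> str:
    """Sequence of ``interval``; minus strand returns the reverse complement."""
    if interval.chrom not in genome:
        raise KeyError(f"sequence {interval.chrom!r} not in genome")
    chrom_seq = genome[interval.chrom]
    if interval.end > len(chrom_seq):
        raise ValueError(
            f"interval {interval.chrom}:[{interval.start},{interval.end}) exceeds "
            f"sequence length {len(chrom_seq)}"
        )
    sub = chrom_seq[interval.start : interval.end]
    return reverse_complement(sub) if strand == "-" else sub


# ---------------------------------------------------------------------------
# GFF3 / GTF

def _iter_features(path: str | Path):
    """Yield (line_number, gffutils Feature) for data lines, validated."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end {end} < start {start}")
            if fields[6] not in {"+", "-", "."}:
                raise ParseError(f"{path}:{lineno}: unknown strand {fields[6]!r}")
            yield lineno, feature_from_line(line)


def _to_interval(feature, strand: str | None = None) -> GenomicInterval:
    # GFF/GTF 1-based inclusive -> 0-based half-open.
    return GenomicInterval(
        feature.seqid, feature.start - 1, feature.end, strand or feature.strand
    )


def _first_attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read CDS-only gene models from GFF3 (or GTF).

    CDS features are grouped by Parent / gene_id / ID into one model per gene.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    order: list[str] = []
    for lineno, feat in _iter_features(path):
        if feat.featuretype != "CDS":
            continue
        gene_id = _first_attr(feat, "Parent", "gene_id", "ID")
        if gene_id is None:
            raise ParseError(f"{path}:{lineno}: CDS feature without Parent/gene_id")
        if gene_id not in exons:
            exons[gene_id] = []
            order.append(gene_id)
            strands[gene_id] = feat.strand
        exons[gene_id].append(_to_interval(feat))
    return [
        GeneModel(gene_id, strands[gene_id], tuple(sorted(exons[gene_id], key=lambda e: e.start)))
        for gene_id in order
    ]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\ttxome_atlas\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, e in enumerate(g.cds_exons, start=1):
                fh.write(
                    f"{g.chrom}\ttxome_atlas\tCDS\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


def read_transcripts(path: str | Path, tissue: str | None = None) -> list[TranscriptModel]:
    """Read transcripts from GTF exon features grouped by transcript_id.

    Tissues of observation come from a ``tissues`` attribute (comma-separated)
    when present, else from the ``tissue`` argument.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    strands: dict[str, str] = {}
    tissues: dict[str, set[str]] = {}
    order: list[str] = []
    for lineno, feat in _iter_features(path):
        if feat.featuretype != "exon":
            continue
        tid = _first_attr(feat, "transcript_id")
        if tid is None:
            raise ParseError(f"{path}:{lineno}: exon feature without transcript_id")
        if tid not in exons:
            exons[tid] = []
            order.append(tid)
            strands[tid] = feat.strand
            tissues[tid] = set()
        exons[tid].append(_to_interval(feat))
        if "tissues" in feat.attributes:
            # gffutils may split comma-separated values into a list already
            for val in feat.attributes["tissues"]:
                tissues[tid].update(t for t in val.split(",") if t)
        if tissue:
            tissues[tid].add(tissue)
    return [
        TranscriptModel(
            tid,
            strands[tid],
            tuple(sorted(exons[tid], key=lambda e: e.start)),
            frozenset(tissues[tid]),
        )
        for tid in order
    ]


def write_transcripts(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            tiss = ",".join(sorted(t.tissues_observed))
            for i, e in enumerate(t.exons, start=1):
                attrs = (
                    f'gene_id "{t.transcript_id}"; transcript_id "{t.transcript_id}"; '
                    f'exon_number "{i}"; tissues "{tiss}";'
                )
                fh.write(
                    f"{t.chrom}\ttxome_atlas\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Junction BED (BED12 with two flanking blocks, or 6-column intron dialect)

def read_junctions(
    path: str | Path,
    tissue: str | None = None,
    support_matrix: str | Path | None = None,
) -> list[SpliceJunction]:
    """Read splice junctions from a BED-style file.

    Dialect is auto-detected by column count: 12 columns are treated as BED12
    whose two blocks flank the intron; 6 columns as a direct intron-interval
    record. Per-tissue read support comes from a sidecar support matrix
    (TSV: junction name x tissue) when given, else the score column is
    attached to ``tissue`` (default ``"pooled"``). Duplicate junction records
    have their supports summed per tissue.
    """
    support_df = None
    if support_matrix is not None:
        support_df = pd.read_csv(support_matrix, sep="\t", index_col=0)
    default_tissue = tissue or "pooled"
    junctions: dict[tuple[str, int, int], SpliceJunction] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) == 12:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name, score, strand = fields[3], fields[4], fields[5]
                n_blocks = int(fields[9])
                if n_blocks != 2:
                    raise ParseError(
                        f"{path}:{lineno}: BED12 junction must have exactly 2 blocks, "
                        f"got {n_blocks}"
                    )
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                intron_start = chrom_start + starts[0] + sizes[0]
                intron_end = chrom_start + starts[1]
            elif len(fields) >= 3 and len(fields) <= 6:
                fields = fields + ["", "0", "."][len(fields) - 3 :]
                chrom, intron_start, intron_end = fields[0], int(fields[1]), int(fields[2])
                name, score, strand = fields[3], fields[4] or "0", fields[5] or "."
            else:
                raise ParseError(
                    f"{path}:{lineno}: ambiguous junction dialect "
                    f"({len(fields)} columns; expected 3-6 or 12)"
                )
            if intron_end <= intron_start:
                raise ParseError(f"{path}:{lineno}: empty or inverted intron interval")
            if strand not in {"+", "-", "."}:
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            key = (chrom, intron_start, intron_end)
            if support_df is not None and name in support_df.index:
                support = {t: int(c) for t, c in support_df.loc[name].items()}
            else:
                support = {default_tissue: int(float(score))}
            if key in junctions:
                existing = junctions[key].support
                for t, c in support.items():
                    existing[t] = existing.get(t, 0) + c
            else:
                junctions[key] = SpliceJunction(
                    GenomicInterval(chrom, intron_start, intron_end, strand),
                    support=dict(support),
                    inferred_strand=strand,
                    name=name or f"jx_{chrom}_{intron_start}_{intron_end}",
                )
    return list(junctions.values())


def write_junctions_bed12(
    junctions: Sequence[SpliceJunction], path: str | Path, flank: int = 20
) -> None:
    """Write junctions as BED12, one record per junction, blocks flanking the
    intron; score = summed read support across tissues."""
    with open(path, "w") as fh:
        for j in junctions:
            iv = j.intron
            chrom_start = max(0, iv.start - flank)
            chrom_end = iv.end + flank
            left = iv.start - chrom_start
            total = sum(j.support.values())
            block_starts = f"0,{iv.end - chrom_start}"
            fh.write(
                f"{iv.chrom}\t{chrom_start}\t{chrom_end}\t{j.name}\t{total}\t"
                f"{j.inferred_strand}\t{chrom_start}\t{chrom_end}\t0\t2\t"
                f"{left},{flank}\t{block_starts}\n"
            )


def write_support_matrix(
    junctions: Sequence[SpliceJunction], tissues: Sequence[str], path: str | Path
) -> None:
    rows = {j.name: [j.support.get(t, 0) for t in tissues] for j in junctions}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues))
    df.index.name = "junction"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Expression TSV (long format: gene, tissue, fpkm, ci_lo, ci_hi)

def read_expression(path: str | Path) -> ExpressionMatrix:
    table = pd.read_csv(path, sep="\t")
    return ExpressionMatrix.from_long(table)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.to_long().to_csv(path, sep="\t", index=False, float_format="%.10g")
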