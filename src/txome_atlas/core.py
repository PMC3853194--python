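"""Core genomic data types shared across the pipeline.

All coordinates are 0-based half-open (BED-like) on the forward genomic
strand; conversion from/to the 1-based inclusive GFF/GTF convention happens
exactly once, at the I/O boundary (:mod:`txome_atlas.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _check_exon_chain(exons: tuple[GenomicInterval, ...], owner: str) -> None:
    if not exons:
        raise ValueError(f"{owner}: at least one exon required")
    chroms = {e.chrom for e in exons}
    if len(chroms) != 1:
        raise ValueError(f"{owner}: exons span multiple sequences {sorted(chroms)}")
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ValueError(
                f"{owner}: exons not sorted/disjoint: "
                f"[{a.start},{a.end}) then [{b.start},{b.end})"
            )


@dataclass(frozen=True)
class GeneModel:
    """A CDS-only annotated locus: ordered, disjoint coding exons.

    The reference annotation emulated here carries no UTR features, so the
    exon chain *is* the CDS and introns are the gaps between consecutive
    coding exons.
    """

    gene_id: str
    strand: str
    cds_exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        object.__setattr__(self, "cds_exons", tuple(self.cds_exons))
        _check_exon_chain(self.cds_exons, f"gene {self.gene_id}")

    @property
    def chrom(self) -> str:
        return self.cds_exons[0].chrom

    @property
    def start(self) -> int:
        return self.cds_exons[0].start

    @property
    def end(self) -> int:
        return self.cds_exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.cds_exons, self.cds_exons[1:])
        )

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.cds_exons)


@dataclass(frozen=True)
class TranscriptModel:
    """An assembled transcript: exon chain plus the tissues it was seen in."""

    transcript_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    tissues_observed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "tissues_observed", frozenset(self.tissues_observed))
        _check_exon_chain(self.exons, f"transcript {self.transcript_id}")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"transcript {self.transcript_id}: bad strand")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def mature_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Genomic (start, end) pairs of the gaps between consecutive exons."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))


@dataclass
class SpliceJunction:
    """One intron interval with per-tissue read support.

    ``intron`` runs from the first intronic base to one past the last, so the
    border dinucleotides are ``seq[start:start+2]`` and ``seq[end-2:end]``.
    """

    intron: GenomicInterval
    support: dict[str, int] = field(default_factory=dict)
    motif: str | None = None
    inferred_strand: str = "."
    name: str = ""
    #: filled by splice_analysis.filter_junctions: tissues whose read
    #: support meets the per-tissue detection threshold
    tissues_detected: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.intron) < 4:
            raise ValueError(
                f"junction {self.intron.chrom}:{self.intron.start}-{self.intron.end}: "
                "intron shorter than 4 bp cannot hold border dinucleotides"
            )
        for tissue, count in self.support.items():
            if count < 0:
                raise ValueError(f"negative support {count} in tissue {tissue}")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.intron.chrom, self.intron.start, self.intron.end)


#: AS event type codes: intron retention, exon skipping, alternative
#: 5'/3' splice site (donor / acceptor).
AS_TYPES = ("IR", "ES", "A5SS", "A3SS")


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing event anchored to a gene.

    ``coords`` is the anchor on the genome: the retained intron for IR, the
    skipped exon for ES, and the alternative junction for A5SS/A3SS (the
    annotated partner junction is in ``partner``).
    """

    event_type: str
    gene_id: str
    chrom: str
    coords: tuple[int, int]
    tissues_detected: frozenset[str] = frozenset()
    partner: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.event_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.event_type!r}")

    @property
    def breadth(self) -> int:
        return len(self.tissues_detected)


class ExpressionMatrix:
    """Gene x tissue FPKM grid with 95% confidence-interval bounds.

    Wraps three aligned DataFrames (``fpkm``, ``ci_lo``, ``ci_hi``) indexed by
    gene with one column per tissue. Downstream callers read expressed flags
    from ``ci_lo`` and tissue-specificity from ``fpkm``.
    """

    def __init__(self, fpkm: pd.DataFrame, ci_lo: pd.DataFrame, ci_hi: pd.DataFrame):
        if not (fpkm.index.equals(ci_lo.index) and fpkm.index.equals(ci_hi.index)):
            raise ValueError("fpkm/ci_lo/ci_hi gene indices differ")
        if not (
            fpkm.columns.equals(ci_lo.columns) and fpkm.columns.equals(ci_hi.columns)
        ):
            raise ValueError("fpkm/ci_lo/ci_hi tissue columns differ")
        if fpkm.shape[1] < 2:
            raise ValueError("at least two tissues required")
        if fpkm.isna().any().any() or ci_lo.isna().any().any():
            raise ValueError("missing expression values are not imputed; fix input")
        if (fpkm < 0).any().any() or (ci_lo < 0).any().any():
            raise ValueError("negative FPKM or CI bound")
        if ((ci_lo - fpkm) > 1e-9).any().any() or ((fpkm - ci_hi) > 1e-9).any().any():
            raise ValueError("require ci_lo <= fpkm <= ci_hi")
        self.fpkm = fpkm
        self.ci_lo = ci_lo
        self.ci_hi = ci_hi

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.fpkm.columns)

    @property
    def n_tissues(self) -> int:
        return self.fpkm.shape[1]

    def row(self, gene_id: str) -> pd.Series:
        if gene_id not in self.fpkm.index:
            raise KeyError(f"gene {gene_id} not in expression matrix")
        return self.fpkm.loc[gene_id]

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "ExpressionMatrix":
        """Build from a long table with columns gene, tissue, fpkm, ci_lo, ci_hi."""
        required = {"gene", "tissue", "fpkm", "ci_lo", "ci_hi"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"long expression table missing columns {sorted(missing)}")
        piv = {
            col: table.pivot(index="gene", columns="tissue", values=col)
            for col in ("fpkm", "ci_lo", "ci_hi")
        }
        return cls(piv["fpkm"], piv["ci_lo"], piv["ci_hi"])

    def to_long(self) -> pd.DataFrame:
        out = []
        for col, df in (("fpkm", self.fpkm), ("ci_lo", self.ci_lo), ("ci_hi", self.ci_hi)):
            long = df.stack().rename(col)
            out.append(long)
        res = pd.concat(out, axis=1).reset_index()
        res.columns = ["gene", "tissue", "fpkm", "ci_lo", "ci_hi"]
        return res.sort_values(["gene", "tissue"]).reset_index(drop=True)


def group_exons(
    exons: Iterable[GenomicInterval],
) -> tuple[GenomicInterval, ...]:
    """Sort exon intervals by genomic start for chain construction."""
    return tuple(sorted(exons, key=lambda e: (e.chrom, e.start, e.end)))


Genome = Mapping[str, str]
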