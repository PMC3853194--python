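"""Synthetic multi-tissue transcriptome with planted, truth-tabled features.

The generator emits a toy genome plus the four downstream inputs the
pipeline consumes — CDS-only gene models (GFF3), per-tissue assembled
transcripts (GTF), splice junctions with per-tissue read support (BED12 +
support matrix), and a gene x tissue FPKM table with 95% CI bounds — while
recording every planted feature in a :class:`TruthTable` so that each
pipeline stage can be scored for exact recovery.

Planted feature classes mirror a CDS-only plant annotation refined by
RNA-seq: transcripts extending the CDS at both ends (UTRs, some carrying a
uORF), intergenic low-overlap transcripts (novel transcribed regions),
junction evidence for the four alternative-splicing event types with
canonical splice motifs, and expression profiles spanning housekeeping,
graded, single-tissue-specific and silent genes.

Sequence content is uniform-random A/C/G/T with splice motifs and
start/stop codons overwritten at planted positions; regions whose reading
matters (5'-UTRs, novel-transcript bodies) are rewritten over the {C,G,T}
alphabet so that no open reading frame other than the planted one can occur
on either strand (an ATG needs an A on the forward reading and a T on the
reverse reading).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .core import GeneModel, GenomicInterval, SpliceJunction, TranscriptModel, ExpressionMatrix
from . import io as aio

DEFAULT_TISSUES = ("callus", "root", "stem", "leaf", "flower", "silique")

#: codons over {C,G,T}: cannot contain ATG and cannot be a stop codon.
_SAFE_ALPHABET = "CGT"


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    """Parameters of the stated synthetic world.

    Defaults give ~200 genes across the six surveyed tissues with
    {IR: 40, ES: 20, A5SS: 20, A3SS: 20} planted splicing events, 50 novel
    transcribed regions and 100 uORF-carrying genes at zero junction noise.
    """

    n_genes: int = 200
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    exons_per_gene: tuple[int, int] = (2, 8)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (60, 400)
    as_events: dict[str, int] = field(
        default_factory=lambda: {"IR": 40, "ES": 20, "A5SS": 20, "A3SS": 20}
    )
    n_ntrs: int = 50
    n_utr_genes: int = 150
    n_uorfs: int = 100
    utr5_length: tuple[int, int] = (60, 400)
    utr3_length: tuple[int, int] = (60, 400)
    junction_noise_rate: float = 0.0
    ir_prefer_short_introns: bool = True
    frac_housekeeping: float = 0.15
    frac_tissue_specific: float = 0.15
    frac_silent: float = 0.10
    baseline_support: tuple[int, int] = (10, 60)
    alt_support: tuple[int, int] = (5, 30)
    intergenic_length: tuple[int, int] = (2500, 4000)
    chrom_name: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_ntrs, self.n_utr_genes, self.n_uorfs]
        if any(c < 0 for c in counts) or any(c < 0 for c in self.as_events.values()):
            raise ConfigError("all counts must be non-negative")
        if len(self.tissues) < 2:
            raise ConfigError("need at least 2 tissues (tau undefined below that)")
        if self.intron_length[0] < 4:
            raise ConfigError(
                "intron_length minimum below 4 bp cannot hold border dinucleotides"
            )
        unknown = set(self.as_events) - {"IR", "ES", "A5SS", "A3SS"}
        if unknown:
            raise ConfigError(f"unknown AS event types requested: {sorted(unknown)}")
        if sum(self.as_events.values()) > self.n_genes:
            raise ConfigError("more AS events requested than genes (one event per gene)")
        if self.n_utr_genes > self.n_genes:
            raise ConfigError("n_utr_genes exceeds n_genes")
        if self.n_uorfs > self.n_utr_genes:
            raise ConfigError("n_uorfs exceeds the number of UTR-extended genes")
        if not 0.0 <= self.junction_noise_rate <= 1.0:
            raise ConfigError("junction_noise_rate must be in [0, 1]")
        if self.n_ntrs > self.n_genes:
            raise ConfigError("n_ntrs exceeds the number of intergenic gaps")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("tissues", "exons_per_gene", "exon_length", "intron_length",
                    "utr5_length", "utr3_length", "baseline_support", "alt_support",
                    "intergenic_length"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PlantedEvent:
    gene_id: str
    event_type: str
    coords: tuple[int, int]
    tissues: frozenset[str]

    def to_json(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "event_type": self.event_type,
            "coords": list(self.coords),
            "tissues": sorted(self.tissues),
        }


@dataclass
class TruthTable:
    """Ground truth of every planted feature, keyed by emitted identifiers."""

    ntr_ids: list[str] = field(default_factory=list)
    ntr_coding: dict[str, bool] = field(default_factory=dict)
    as_events: list[PlantedEvent] = field(default_factory=list)
    utr5: dict[str, int] = field(default_factory=dict)
    utr3: dict[str, int] = field(default_factory=dict)
    uorfs: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    expression_class: dict[str, str] = field(default_factory=dict)
    transcript_labels: dict[str, str] = field(default_factory=dict)

    def event_set(self) -> set[tuple[str, str, tuple[int, int]]]:
        return {(e.gene_id, e.event_type, e.coords) for e in self.as_events}

    def to_json(self) -> dict:
        return {
            "ntr_ids": self.ntr_ids,
            "ntr_coding": self.ntr_coding,
            "as_events": [e.to_json() for e in self.as_events],
            "utr5": self.utr5,
            "utr3": self.utr3,
            "uorfs": {g: [list(u) for u in us] for g, us in self.uorfs.items()},
            "expression_class": self.expression_class,
            "transcript_labels": self.transcript_labels,
        }

    @classmethod
    def from_json(cls, data: dict) -> "TruthTable":
        return cls(
            ntr_ids=list(data["ntr_ids"]),
            ntr_coding=dict(data["ntr_coding"]),
            as_events=[
                PlantedEvent(
                    e["gene_id"], e["event_type"], tuple(e["coords"]),
                    frozenset(e["tissues"]),
                )
                for e in data["as_events"]
            ],
            utr5={g: int(v) for g, v in data["utr5"].items()},
            utr3={g: int(v) for g, v in data["utr3"].items()},
            uorfs={g: [tuple(u) for u in us] for g, us in data["uorfs"].items()},
            expression_class=dict(data["expression_class"]),
            transcript_labels=dict(data["transcript_labels"]),
        )


@dataclass
class Annotation:
    """Toy genome (mutable during feature planting) plus its gene models."""

    genome: dict[str, bytearray]
    genes: list[GeneModel]

    def genome_str(self) -> dict[str, str]:
        return {c: bytes(s).decode() for c, s in self.genome.items()}


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # independent deterministic stream per generation stage
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    """n codons over {C,G,T}: no in-frame stop, no ATG on either strand."""
    return _random_seq(rng, 3 * n, _SAFE_ALPHABET)


def _write(genome: bytearray, start: int, seq: str) -> None:
    genome[start : start + len(seq)] = seq.encode()


def _revcomp(seq: str) -> str:
    return aio.reverse_complement(seq)


# ---------------------------------------------------------------------------
# Stage 1: genome + CDS-only annotation

def generate_annotation(config: SimConfig) -> Annotation:
    """Lay out multi-exon CDS-only gene models on a random genome.

    Every CDS is codon-complete (starts ATG, ends TAA, length divisible by
    3) and every intron is written with canonical borders (GT..AG on the
    coding strand) except for a ``junction_noise_rate`` fraction, whose
    borders are scrambled to a non-canonical dinucleotide pair.
    """
    rng = _rng(config, 1)
    chrom = config.chrom_name
    parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []

    def emit(seq: str) -> int:
        nonlocal cursor
        parts.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    lo_g, hi_g = config.intergenic_length
    for i in range(config.n_genes):
        emit(_random_seq(rng, int(rng.integers(lo_g, hi_g + 1))))
        gene_id = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = [
            max(9, 3 * int(rng.integers(config.exon_length[0] // 3,
                                        config.exon_length[1] // 3 + 1)))
            for _ in range(n_exons)
        ]
        intron_lens = [
            int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
            for _ in range(n_exons - 1)
        ]
        cds_len = sum(exon_lens)
        mature = "ATG" + _safe_codons(rng, cds_len // 3 - 2) + "TAA"
        genomic_cds = mature if strand == "+" else _revcomp(mature)
        # split the genomic-orientation CDS across exons, introns between
        exons: list[GenomicInterval] = []
        offset = 0
        for k, elen in enumerate(exon_lens):
            estart = emit(genomic_cds[offset : offset + elen])
            offset += elen
            exons.append(GenomicInterval(chrom, estart, estart + elen, strand))
            if k < n_exons - 1:
                ilen = intron_lens[k]
                iseq = list(_random_seq(rng, ilen))
                if rng.random() < config.junction_noise_rate:
                    donor, acceptor = "CC", "GG"  # non-canonical
                else:
                    donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
                iseq[0:2] = donor
                iseq[-2:] = acceptor
                emit("".join(iseq))
        genes.append(GeneModel(gene_id, strand, tuple(exons)))
    emit(_random_seq(rng, int(rng.integers(lo_g, hi_g + 1))))
    return Annotation(genome={chrom: bytearray("".join(parts).encode())}, genes=genes)


# ---------------------------------------------------------------------------
# Stage 2: planted transcripts, junctions, truth table

#: margin kept between a planted intergenic transcript and flanking genes;
#: larger than the maximal UTR extension so novel loci never touch them.
_NTR_MARGIN = 600


def plant_features(
    annotation: Annotation, config: SimConfig
) -> tuple[list[TranscriptModel], list[SpliceJunction], TruthTable]:
    """Plant NTRs, UTR extensions, uORFs and AS-event evidence.

    Mutates ``annotation.genome`` in place (UTR rewrite, uORF insertion,
    alternative splice-site motifs) and returns the assembled transcripts,
    the junction set and the truth table. Junction evidence follows the
    detector contracts downstream: every annotated intron yields a junction
    supported in all tissues; each planted event adds the extra junction
    (ES/A5SS/A3SS) or the intron-spanning transcript (IR) restricted to the
    event's tissue subset.
    """
    rng = _rng(config, 2)
    truth = TruthTable()
    chrom = config.chrom_name
    genome = annotation.genome[chrom]
    genes = annotation.genes
    tissues = list(config.tissues)
    transcripts: list[TranscriptModel] = []
    junctions: dict[tuple[str, int, int], SpliceJunction] = {}
    n_jx = 0

    def random_tissue_subset() -> frozenset[str]:
        k = int(rng.integers(1, len(tissues) + 1))
        return frozenset(rng.choice(tissues, size=k, replace=False).tolist())

    def add_junction(start: int, end: int, strand: str,
                     support: dict[str, int]) -> SpliceJunction:
        nonlocal n_jx
        key = (chrom, start, end)
        if key in junctions:
            for t, c in support.items():
                junctions[key].support[t] = junctions[key].support.get(t, 0) + c
            return junctions[key]
        n_jx += 1
        j = SpliceJunction(
            GenomicInterval(chrom, start, end, strand),
            support=dict(support),
            inferred_strand=strand,
            name=f"jx{n_jx:05d}",
        )
        junctions[key] = j
        return j

    # --- baseline junctions: one per annotated intron, supported everywhere
    lo_b, hi_b = config.baseline_support
    for g in genes:
        for intr in g.introns:
            support = {t: int(rng.integers(lo_b, hi_b + 1)) for t in tissues}
            add_junction(intr.start, intr.end, g.strand, support)

    # --- UTR extensions + uORFs ------------------------------------------
    utr_gene_idx = sorted(
        rng.choice(len(genes), size=config.n_utr_genes, replace=False).tolist()
    )
    uorf_gene_idx = set(
        rng.choice(utr_gene_idx, size=config.n_uorfs, replace=False).tolist()
    ) if config.n_uorfs else set()

    def plant_utr(g: GeneModel, utr5: int, utr3: int, with_uorf: bool) -> None:
        utr5_seq = _random_seq(rng, utr5, _SAFE_ALPHABET)
        utr3_seq = _random_seq(rng, utr3, _SAFE_ALPHABET)
        if with_uorf:
            k_codons = int(rng.integers(4, 17))  # 12..48 nt including the stop
            length = 3 * k_codons
            offset = int(rng.integers(0, utr5 - length + 1))
            uorf = "ATG" + _safe_codons(rng, k_codons - 2) + "TAA"
            utr5_seq = utr5_seq[:offset] + uorf + utr5_seq[offset + length:]
            truth.uorfs.setdefault(g.gene_id, []).append((offset, length))
        if g.strand == "+":
            if utr5:
                _write(genome, g.start - utr5, utr5_seq)
            if utr3:
                _write(genome, g.end, utr3_seq)
        else:
            if utr5:
                _write(genome, g.end, _revcomp(utr5_seq))
            if utr3:
                _write(genome, g.start - utr3, _revcomp(utr3_seq))

    for gi, g in enumerate(genes):
        if gi in set(utr_gene_idx):
            utr5 = int(rng.integers(config.utr5_length[0], config.utr5_length[1] + 1))
            utr3 = int(rng.integers(config.utr3_length[0], config.utr3_length[1] + 1))
            plant_utr(g, utr5, utr3, gi in uorf_gene_idx)
        else:
            utr5 = utr3 = 0
        truth.utr5[g.gene_id] = utr5
        truth.utr3[g.gene_id] = utr3
        left, right = (utr5, utr3) if g.strand == "+" else (utr3, utr5)
        exons = list(g.cds_exons)
        first, last = exons[0], exons[-1]
        exons[0] = GenomicInterval(chrom, first.start - left, first.end, g.strand)
        exons[-1] = GenomicInterval(chrom, exons[-1].start if len(exons) > 1 else exons[0].start,
                                    last.end + right, g.strand)
        if len(exons) == 1:
            exons[0] = GenomicInterval(chrom, first.start - left, last.end + right, g.strand)
        tid = f"T_{g.gene_id}"
        transcripts.append(
            TranscriptModel(tid, g.strand, tuple(exons), random_tissue_subset())
        )
        truth.transcript_labels[tid] = "complete"

    # --- AS events -------------------------------------------------------
    lo_a, hi_a = config.alt_support
    pool = list(range(len(genes)))
    rng.shuffle(pool)
    used: set[int] = set()

    def take_gene(predicate) -> GeneModel:
        for idx in pool:
            if idx in used:
                continue
            if predicate(genes[idx]):
                used.add(idx)
                return genes[idx]
        raise GenerationError("no eligible gene left for requested AS event")

    def alt_support_subset(subset: frozenset[str]) -> dict[str, int]:
        return {t: int(rng.integers(lo_a, hi_a + 1)) for t in sorted(subset)}

    for _ in range(config.as_events.get("IR", 0)):
        g = take_gene(lambda g: len(g.cds_exons) >= 2)
        introns = g.introns
        if config.ir_prefer_short_introns:
            intr = min(introns, key=len)
            i = introns.index(intr)
        else:
            i = int(rng.integers(0, len(introns)))
            intr = introns[i]
        subset = random_tissue_subset()
        # transcript with exons i and i+1 fused across the retained intron
        exons = list(g.cds_exons)
        fused = GenomicInterval(chrom, exons[i].start, exons[i + 1].end, g.strand)
        new_exons = exons[:i] + [fused] + exons[i + 2:]
        tid = f"T_{g.gene_id}_IR"
        transcripts.append(TranscriptModel(tid, g.strand, tuple(new_exons), subset))
        truth.transcript_labels[tid] = "partial"
        truth.as_events.append(
            PlantedEvent(g.gene_id, "IR", (intr.start, intr.end), subset)
        )

    for _ in range(config.as_events.get("ES", 0)):
        g = take_gene(lambda g: len(g.cds_exons) >= 3)
        introns = g.introns
        i = int(rng.integers(1, len(g.cds_exons) - 1))  # internal exon index
        subset = random_tissue_subset()
        skip_start, skip_end = introns[i - 1].start, introns[i].end
        add_junction(skip_start, skip_end, g.strand, alt_support_subset(subset))
        exon = g.cds_exons[i]
        truth.as_events.append(
            PlantedEvent(g.gene_id, "ES", (exon.start, exon.end), subset)
        )

    def plant_alt_ss(event_type: str) -> None:
        g = take_gene(
            lambda g: len(g.cds_exons) >= 2 and max(len(i) for i in g.introns) >= 24
        )
        introns = [i for i in g.introns if len(i) >= 24]
        intr = introns[int(rng.integers(0, len(introns)))]
        d = int(rng.integers(6, min(len(intr) - 10, 40) + 1))
        subset = random_tissue_subset()
        # shift the donor (A5SS) or acceptor (A3SS) into the intron on the
        # coding strand, writing canonical borders at the new site
        shift_left_end = (event_type == "A5SS") == (g.strand == "+")
        if shift_left_end:
            alt = (intr.start + d, intr.end)
            motif = "GT" if g.strand == "+" else "CT"
            _write(genome, alt[0], motif)
        else:
            alt = (intr.start, intr.end - d)
            motif = "AG" if g.strand == "+" else "AC"
            _write(genome, alt[1] - 2, motif)
        add_junction(alt[0], alt[1], g.strand, alt_support_subset(subset))
        truth.as_events.append(PlantedEvent(g.gene_id, event_type, alt, subset))

    for _ in range(config.as_events.get("A5SS", 0)):
        plant_alt_ss("A5SS")
    for _ in range(config.as_events.get("A3SS", 0)):
        plant_alt_ss("A3SS")

    # --- novel transcribed regions ---------------------------------------
    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for g in genes:
        gaps.append((prev_end, g.start))
        prev_end = g.end
    gaps.append((prev_end, len(genome)))
    wide = [gap for gap in gaps if gap[1] - gap[0] >= 2 * _NTR_MARGIN + 400]
    if config.n_ntrs > len(wide):
        raise GenerationError("not enough intergenic room for requested NTRs")
    chosen = rng.choice(len(wide), size=config.n_ntrs, replace=False)
    for k, gap_i in enumerate(sorted(chosen.tolist())):
        lo, hi = wide[gap_i]
        ntr_id = f"NTR{k + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = k % 2 == 0
        if coding:
            n_aa = int(rng.integers(110, 161))  # ORF > 100 aa
            mature = "ATG" + _safe_codons(rng, n_aa - 1) + "TAA"
            seq = mature if strand == "+" else _revcomp(mature)
        else:
            length = int(rng.integers(300, min(901, hi - lo - 2 * _NTR_MARGIN)))
            seq = _random_seq(rng, length, _SAFE_ALPHABET)
            if strand == "-":
                seq = _revcomp(seq)
        start = lo + _NTR_MARGIN
        _write(genome, start, seq)
        transcripts.append(
            TranscriptModel(
                ntr_id, strand,
                (GenomicInterval(chrom, start, start + len(seq), strand),),
                random_tissue_subset(),
            )
        )
        truth.ntr_ids.append(ntr_id)
        truth.ntr_coding[ntr_id] = coding
        truth.transcript_labels[ntr_id] = "novel"

    # --- junction noise ---------------------------------------------------
    if config.junction_noise_rate > 0:
        for j in junctions.values():
            if rng.random() < config.junction_noise_rate:
                j.support = {t: int(rng.integers(0, 3)) for t in j.support}

    # --- expression classes ----------------------------------------------
    order = rng.permutation(len(genes))
    n_hk = round(config.frac_housekeeping * len(genes))
    n_ts = round(config.frac_tissue_specific * len(genes))
    n_si = round(config.frac_silent * len(genes))
    for rank, gi in enumerate(order.tolist()):
        gid = genes[gi].gene_id
        if rank < n_hk:
            truth.expression_class[gid] = "housekeeping"
        elif rank < n_hk + n_ts:
            tissue = tissues[rank % len(tissues)]
            truth.expression_class[gid] = f"tissue_specific:{tissue}"
        elif rank < n_hk + n_ts + n_si:
            truth.expression_class[gid] = "silent"
        else:
            truth.expression_class[gid] = "graded"

    return transcripts, list(junctions.values()), truth


# ---------------------------------------------------------------------------
# Stage 3: expression

def simulate_expression(
    annotation: Annotation, truth: TruthTable, config: SimConfig
) -> ExpressionMatrix:
    """Draw FPKM values per expression class, with Poisson-count-driven CIs.

    The 95% CI lower bound is ``max(0, fpkm * (1 - 1.96 / sqrt(c + 1)))``
    with ``c`` a simulated fragment count; only its sign (zero vs positive)
    is consumed downstream. Housekeeping genes exceed FPKM 50 in every
    tissue, tissue-specific genes are nonzero in exactly one tissue, graded
    genes vary in (5, 40] everywhere, silent genes are zero everywhere.
    """
    if len(config.tissues) < 2:
        raise ConfigError("need at least 2 tissues")
    rng = _rng(config, 3)
    tissues = list(config.tissues)
    rows_fpkm, rows_lo, rows_hi = [], [], []
    gene_ids = [g.gene_id for g in annotation.genes]
    for gid in gene_ids:
        cls = truth.expression_class.get(gid, "graded")
        if cls == "housekeeping":
            base = rng.uniform(60, 400)
            fpkm = base * (1 + rng.uniform(-0.15, 0.15, size=len(tissues)))
        elif cls.startswith("tissue_specific:"):
            tissue = cls.split(":", 1)[1]
            fpkm = np.zeros(len(tissues))
            fpkm[tissues.index(tissue)] = rng.uniform(20, 120)
        elif cls == "silent":
            fpkm = np.zeros(len(tissues))
        else:
            fpkm = rng.uniform(5.5, 40, size=len(tissues))
        counts = np.where(fpkm > 0, np.maximum(3, rng.poisson(fpkm * 20)), 0)
        width = 1.96 / np.sqrt(counts + 1)
        rows_fpkm.append(fpkm)
        rows_lo.append(np.maximum(0.0, fpkm * (1 - width)))
        rows_hi.append(fpkm * (1 + width))
    import pandas as pd

    mk = lambda rows: pd.DataFrame(np.array(rows), index=gene_ids, columns=tissues)
    return ExpressionMatrix(mk(rows_fpkm), mk(rows_lo), mk(rows_hi))


# ---------------------------------------------------------------------------
# One-call dataset

@dataclass
class SimulatedDataset:
    config: SimConfig
    annotation: Annotation
    transcripts: list[TranscriptModel]
    junctions: list[SpliceJunction]
    expression: ExpressionMatrix
    truth: TruthTable

    @property
    def genome(self) -> dict[str, str]:
        return self.annotation.genome_str()

    def per_tissue_transcripts(self) -> dict[str, list[TranscriptModel]]:
        """View as the per-tissue assembled sets the merger consumes."""
        out: dict[str, list[TranscriptModel]] = {t: [] for t in self.config.tissues}
        for tr in self.transcripts:
            for t in tr.tissues_observed:
                out[t].append(
                    TranscriptModel(tr.transcript_id, tr.strand, tr.exons, frozenset({t}))
                )
        return out


def simulate_dataset(config: SimConfig, outdir: str | Path | None = None) -> SimulatedDataset:
    """Run all three generation stages; optionally write every output file."""
    annotation = generate_annotation(config)
    transcripts, junctions, truth = plant_features(annotation, config)
    expression = simulate_expression(annotation, truth, config)
    ds = SimulatedDataset(config, annotation, transcripts, junctions, expression, truth)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "gene_models": outdir / "gene_models.gff3",
        "transcripts": outdir / "transcripts.gtf",
        "junctions": outdir / "junctions.bed",
        "junction_support": outdir / "junction_support.tsv",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "sim_config.yaml",
    }
    aio.write_genome(ds.genome, paths["genome"])
    aio.write_gene_models(ds.annotation.genes, paths["gene_models"])
    aio.write_transcripts(ds.transcripts, paths["transcripts"])
    aio.write_junctions_bed12(ds.junctions, paths["junctions"])
    aio.write_support_matrix(ds.junctions, list(ds.config.tissues), paths["junction_support"])
    aio.write_expression(ds.expression, paths["expression"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth.to_json(), fh, indent=1, sort_keys=True)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(ds.config).items()},
            fh, sort_keys=True,
        )
    return paths
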