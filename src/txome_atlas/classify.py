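"""Transcript merging and reconciliation against CDS-only gene models.

Per-tissue assembled transcripts are merged into a non-redundant set
(identical intron chains collapse, overlapping mono-exon transcripts union),
then each merged transcript is labeled against the annotation:

``complete``
    the transcript covers every CDS base of some gene and its intron chain,
    restricted to the CDS span, equals the gene's intron chain — i.e. a
    length-complete representation of the annotated coding structure;
``partial``
    any other exonic overlap with a gene model;
``novel``
    no exonic overlap with any gene model on either strand — a novel
    transcribed region (NTR).

Novel transcripts are screened for coding potential with a six-frame
longest-ORF scan (the transcribed strand of an NTR is unknown); an ORF
longer than 100 amino acids flags the NTR as likely protein-coding.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core import GeneModel, GenomicInterval, TranscriptModel, Genome
from .io import extract_sequence, reverse_complement

OVERLAP_LABELS = ("complete", "partial", "novel")

#: NTRs with an ORF longer than this many amino acids are called coding.
CODING_AA_THRESHOLD = 100

_STOPS = {"TAA", "TAG", "TGA"}


# ---------------------------------------------------------------------------
# Merging

def merge_transcripts(
    transcript_sets: Iterable[Iterable[TranscriptModel]],
) -> list[TranscriptModel]:
    """Merge per-tissue transcript sets into a non-redundant final set.

    Multi-exon transcripts with identical intron chains (same chrom and
    strand) collapse into one record whose terminal exons are the union of
    the inputs' terminal exons. Mono-exon transcripts on the same strand
    overlapping by >= 1 bp collapse to their union interval (transitively).
    ``tissues_observed`` is the union; the merged identifier is the
    lexicographically smallest constituent identifier.
    """
    multi: dict[tuple, list[TranscriptModel]] = defaultdict(list)
    mono: dict[tuple[str, str], list[TranscriptModel]] = defaultdict(list)
    for tset in transcript_sets:
        for t in tset:
            if len(t.exons) > 1:
                multi[(t.chrom, t.strand, t.intron_chain)].append(t)
            else:
                mono[(t.chrom, t.strand)].append(t)

    merged: list[TranscriptModel] = []
    for (chrom, strand, chain), members in multi.items():
        start = min(t.start for t in members)
        end = max(t.end for t in members)
        bounds = [start] + [x for pair in chain for x in pair] + [end]
        exons = tuple(
            GenomicInterval(chrom, bounds[i], bounds[i + 1], strand)
            for i in range(0, len(bounds), 2)
        )
        merged.append(
            TranscriptModel(
                min(t.transcript_id for t in members),
                strand,
                exons,
                frozenset().union(*(t.tissues_observed for t in members)),
            )
        )
    for (chrom, strand), members in mono.items():
        members = sorted(members, key=lambda t: (t.start, t.end, t.transcript_id))
        cluster: list[TranscriptModel] = []
        cluster_end = -1

        def flush() -> None:
            if not cluster:
                return
            merged.append(
                TranscriptModel(
                    min(t.transcript_id for t in cluster),
                    strand,
                    (
                        GenomicInterval(
                            chrom,
                            min(t.start for t in cluster),
                            max(t.end for t in cluster),
                            strand,
                        ),
                    ),
                    frozenset().union(*(t.tissues_observed for t in cluster)),
                )
            )

        for t in members:
            if cluster and t.start < cluster_end:
                cluster.append(t)
                cluster_end = max(cluster_end, t.end)
            else:
                flush()
                cluster = [t]
                cluster_end = t.end
        flush()
    merged.sort(key=lambda t: (t.chrom, t.start, t.end, t.transcript_id))
    return merged


# ---------------------------------------------------------------------------
# Overlap classification

def _covers(exons: Sequence[GenomicInterval], target: GenomicInterval) -> bool:
    """True if the (sorted, disjoint) exons jointly cover every base of target."""
    pos = target.start
    for e in exons:
        if e.end <= pos:
            continue
        if e.start > pos:
            return False
        pos = min(target.end, e.end)
        if pos >= target.end:
            return True
    return pos >= target.end


def _is_complete(t: TranscriptModel, g: GeneModel) -> bool:
    if t.strand != g.strand or t.chrom != g.chrom:
        return False
    if not all(_covers(t.exons, e) for e in g.cds_exons):
        return False
    restricted = tuple(
        ic for ic in t.intron_chain if ic[0] >= g.start and ic[1] <= g.end
    )
    return restricted == tuple((i.start, i.end) for i in g.introns)


def _exonic_overlap_bp(t: TranscriptModel, g: GeneModel) -> int:
    total = 0
    for te in t.exons:
        for ge in g.cds_exons:
            total += max(0, min(te.end, ge.end) - max(te.start, ge.start))
    return total


def classify_transcript_overlap(
    transcript: TranscriptModel,
    genes: Sequence[GeneModel],
    antisense_novel: bool = False,
) -> tuple[str, str | None]:
    """Label one transcript against the gene models.

    Returns ``(label, gene_id)``; ``gene_id`` is None for novel transcripts.
    With ``antisense_novel=True`` a transcript whose only exonic overlap is
    antisense is labeled novel rather than partial.
    """
    same_strand: list[tuple[int, GeneModel]] = []
    anti_strand: list[tuple[int, GeneModel]] = []
    for g in genes:
        if g.chrom != transcript.chrom:
            continue
        bp = _exonic_overlap_bp(transcript, g)
        if bp <= 0:
            continue
        (same_strand if g.strand == transcript.strand else anti_strand).append((bp, g))
    for _, g in sorted(same_strand, key=lambda x: (-x[0], x[1].gene_id)):
        if _is_complete(transcript, g):
            return "complete", g.gene_id
    if same_strand:
        bp, g = max(same_strand, key=lambda x: (x[0], x[1].gene_id))
        return "partial", g.gene_id
    if anti_strand and not antisense_novel:
        bp, g = max(anti_strand, key=lambda x: (x[0], x[1].gene_id))
        return "partial", g.gene_id
    return "novel", None


# ---------------------------------------------------------------------------
# Longest-ORF scan

@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame over all six frames of a sequence.

    ``start``/``end`` are half-open positions on the *input* (forward)
    sequence including the stop codon; ``aa`` counts residues from the
    initiator Met to the last sense codon (the stop codon is excluded).
    """

    start: int | None
    end: int | None
    strand: str | None
    aa: int

    @property
    def coding_flag(self) -> bool:
        return self.aa > CODING_AA_THRESHOLD


def _scan_frames(seq: str) -> list[tuple[int, int]]:
    """All maximal ATG..stop ORFs of ``seq`` (forward frames only), as
    half-open (start, end) including the stop codon."""
    orfs = []
    n = len(seq)
    for frame in range(3):
        open_start: int | None = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in _STOPS:
                if open_start is not None:
                    orfs.append((open_start, p + 3))
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = p
    return orfs


def find_longest_orf(sequence: str) -> OrfResult:
    """Six-frame longest-ORF scan over an ACGTN nucleotide string.

    An ORF is an ATG followed by in-frame sense codons up to the first
    in-frame stop, all wholly inside the sequence. Ties break toward the
    plus strand, then the smallest start. No ORF yields ``aa == 0``.
    """
    sequence = sequence.upper()
    n = len(sequence)
    best: OrfResult = OrfResult(None, None, None, 0)
    for strand, seq in (("+", sequence), ("-", reverse_complement(sequence))):
        for s, e in _scan_frames(seq):
            aa = (e - s) // 3 - 1
            if strand == "-":
                s, e = n - e, n - s
            candidate = OrfResult(s, e, strand, aa)
            if aa > best.aa or (
                aa == best.aa
                and best.strand == "-"
                and strand == "+"
            ):
                best = candidate
    return best


@dataclass(frozen=True)
class NtrRecord:
    """Coding-potential call for one novel transcribed region."""

    transcript_id: str
    longest_orf_aa: int
    coding_flag: bool


def ntr_coding_calls(
    novel_transcripts: Iterable[TranscriptModel], genome: Genome
) -> list[NtrRecord]:
    records = []
    for t in novel_transcripts:
        mature = "".join(extract_sequence(genome, e) for e in t.exons)
        orf = find_longest_orf(mature)
        records.append(NtrRecord(t.transcript_id, orf.aa, orf.coding_flag))
    return records


def classify_transcripts(
    merged: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    genome: Genome | None = None,
    antisense_novel: bool = False,
) -> "pd.DataFrame":
    """Label every merged transcript; ORF-scan the novel ones if a genome
    is supplied. Returns a DataFrame with one row per transcript."""
    import pandas as pd

    rows = []
    for t in merged:
        label, gene_id = classify_transcript_overlap(t, genes, antisense_novel)
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "label": label,
                "gene_id": gene_id,
                "longest_orf_aa": pd.NA,
                "coding_flag": pd.NA,
            }
        )
    df = pd.DataFrame(rows)
    if genome is not None and len(df):
        novel_ids = set(df.loc[df.label == "novel", "transcript_id"])
        records = ntr_coding_calls(
            [t for t in merged if t.transcript_id in novel_ids], genome
        )
        by_id = {r.transcript_id: r for r in records}
        for i, row in df.iterrows():
            rec = by_id.get(row.transcript_id)
            if rec is not None:
                df.at[i, "longest_orf_aa"] = rec.longest_orf_aa
                df.at[i, "coding_flag"] = rec.coding_flag
    return df
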