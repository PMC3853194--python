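"""UTR boundary definition from length-complete transcripts, uORF scan,
and UTR-length comparisons across gene categories.

The reference annotation is CDS-only, so untranslated regions are defined
by comparing a transcript labeled *complete* for a gene against that gene's
CDS limits: the 5'-UTR is the mature (spliced) transcript upstream of the
CDS start on the coding strand, the 3'-UTR downstream of the CDS end.
Upstream ORFs (uORFs) are ATG-initiated, in-frame-stop-terminated ORFs of
10-50 nt (stop codon included) lying entirely within the 5'-UTR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, TranscriptModel, Genome
from .io import extract_sequence

#: uORF length window in nucleotides, stop codon included. Effective
#: lengths are the multiples of 3 inside the window: 12, 15, ..., 48.
UORF_MIN_NT = 10
UORF_MAX_NT = 50

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class UtrAnnotation:
    """Mature-coordinate UTR lengths for one gene."""

    gene_id: str
    utr5_len: int
    utr3_len: int


@dataclass(frozen=True)
class Uorf:
    """One upstream ORF: offset from the 5' mature transcript end of its
    5'-UTR, and nucleotide length including the stop codon."""

    gene_id: str
    offset: int
    length_nt: int


def _mature_offset(transcript: TranscriptModel, gpos: int) -> int:
    """Number of exonic bases genomically left of ``gpos``."""
    total = 0
    for e in transcript.exons:
        total += max(0, min(gpos, e.end) - e.start)
    return total


def define_utrs(transcript: TranscriptModel, gene: GeneModel) -> UtrAnnotation | None:
    """UTR lengths of ``gene`` from a transcript that is complete for it.

    Lengths are measured in mature (spliced) coordinates and are
    strand-aware. Returns None (an explicit "undefined" result, not zero)
    when the transcript does not fully contain the CDS with a matching
    intron chain — UTRs cannot be called from partial evidence.
    """
    from .classify import _is_complete

    if not _is_complete(transcript, gene):
        return None
    mature_len = transcript.mature_length
    left = _mature_offset(transcript, gene.start)
    right = mature_len - _mature_offset(transcript, gene.end)
    if gene.strand == "+":
        utr5, utr3 = left, right
    else:
        utr5, utr3 = right, left
    return UtrAnnotation(gene.gene_id, utr5, utr3)


def mature_sequence(transcript: TranscriptModel, genome: Genome) -> str:
    """Spliced transcript sequence on the coding strand."""
    forward = "".join(extract_sequence(genome, e) for e in transcript.exons)
    if transcript.strand == "-":
        from .io import reverse_complement

        return reverse_complement(forward)
    return forward


def utr5_sequence(
    transcript: TranscriptModel, gene: GeneModel, genome: Genome
) -> str | None:
    ann = define_utrs(transcript, gene)
    if ann is None:
        return None
    return mature_sequence(transcript, genome)[: ann.utr5_len]


def scan_uorfs(utr5_seq: str, gene_id: str = "") -> list[Uorf]:
    """All uORFs in a 5'-UTR mature sequence (coding strand).

    Every ATG starts a candidate; it must reach its first in-frame stop
    wholly inside the UTR and the total length (stop included) must fall in
    [10, 50] nt. Overlapping uORFs are all reported.
    """
    seq = utr5_seq.upper()
    found: list[Uorf] = []
    for p in range(len(seq) - 2):
        if seq[p : p + 3] != "ATG":
            continue
        q = p
        while q + 3 <= len(seq):
            if seq[q : q + 3] in _STOPS:
                length = q + 3 - p
                if UORF_MIN_NT <= length <= UORF_MAX_NT:
                    found.append(Uorf(gene_id, p, length))
                break
            q += 3
    return found


def annotate_utrs(
    complete_pairs: Sequence[tuple[TranscriptModel, GeneModel]],
    genome: Genome | None = None,
) -> pd.DataFrame:
    """UTR table (gene_id, utr5_len, utr3_len, n_uorfs) for complete
    transcript/gene pairs; uORFs are scanned when a genome is supplied."""
    rows = []
    for transcript, gene in complete_pairs:
        ann = define_utrs(transcript, gene)
        if ann is None:
            continue
        n_uorfs: int | None = None
        uorfs: list[Uorf] = []
        if genome is not None:
            seq = mature_sequence(transcript, genome)[: ann.utr5_len]
            uorfs = scan_uorfs(seq, gene.gene_id)
            n_uorfs = len(uorfs)
        rows.append(
            {
                "gene_id": ann.gene_id,
                "utr5_len": ann.utr5_len,
                "utr3_len": ann.utr3_len,
                "n_uorfs": n_uorfs,
                "uorfs": [(u.offset, u.length_nt) for u in uorfs],
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "utr5_len", "utr3_len", "n_uorfs", "uorfs"]
    )


def compare_utr_by_category(
    lengths: Mapping[str, int] | pd.Series,
    categories: Mapping[str, Sequence[str] | str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category two-sided Wilcoxon rank-sum of UTR lengths vs all UTRs.

    Each category's member lengths are compared against the full background
    of lengths (category included, mirroring a category-vs-total design).
    Categories significant at ``alpha`` are flagged "longer" or "shorter"
    by their median relative to the background median. Categories with
    fewer than 2 observations are skipped with a warning.
    """
    lengths = pd.Series(dict(lengths), dtype=float)
    background = lengths.to_numpy()
    bg_median = float(np.median(background))
    cat_members: dict[str, list[str]] = {}
    for gene, cats in categories.items():
        if isinstance(cats, str):
            cats = [cats]
        for c in cats:
            cat_members.setdefault(c, []).append(gene)
    rows = []
    for cat in sorted(cat_members):
        members = [g for g in cat_members[cat] if g in lengths.index]
        if len(members) < 2:
            warnings.warn(f"category {cat!r} has <2 observations; skipped")
            continue
        sample = lengths.loc[members].to_numpy()
        res = stats.mannwhitneyu(
            sample, background, alternative="two-sided", method="auto"
        )
        p = float(res.pvalue)
        med = float(np.median(sample))
        if p < alpha and med > bg_median:
            direction = "longer"
        elif p < alpha and med < bg_median:
            direction = "shorter"
        else:
            direction = "none"
        rows.append(
            {
                "category": cat,
                "n": len(members),
                "median": med,
                "background_median": bg_median,
                "direction": direction,
                "p_value": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["category", "n", "median", "background_median", "direction", "p_value"],
    )
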