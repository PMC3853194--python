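"""Splice-junction filtering, motif typing, known/novel classification and
alternative-splicing event detection.

Junction support is thresholded *per tissue* (no cross-tissue pooling): a
junction is detected in a tissue when its read support there reaches the
minimum (default 3), and retained overall when detected in at least one
tissue. Border dinucleotides type each junction (GT-AG, GC-AG, AT-AC are
canonical) and simultaneously infer the splicing strand, since a minus
strand GT-AG intron reads CT..AC on the forward genome.

Event detection consumes junctions, merged transcripts and gene models:

* IR  — an intron (annotated or junction-defined) wholly inside a single
  exon of a merged transcript at the locus, while its spliced junction is
  also detected: both isoforms are in evidence.
* ES  — a junction running from the donor of annotated intron i to the
  acceptor of intron i+1, skipping the internal exon between them.
* A5SS / A3SS — two junctions at a locus sharing the acceptor (A5SS) or
  the donor (A3SS) on the coding strand while the other end differs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ASEvent, GeneModel, Genome, SpliceJunction, TranscriptModel
from .io import extract_sequence, reverse_complement

MIN_SUPPORT = 3

#: canonical splice border dinucleotide pairs on the splicing strand
CANONICAL_MOTIFS = ("GT-AG", "GC-AG", "AT-AC")


def filter_junctions(
    junctions: Iterable[SpliceJunction], min_support: int = MIN_SUPPORT
) -> list[SpliceJunction]:
    """Apply the per-tissue detection threshold.

    Each junction's ``tissues_detected`` is set to the tissues whose
    support is >= ``min_support`` in that tissue alone; junctions detected
    nowhere are dropped. Counts are never pooled across tissues.
    """
    kept = []
    for j in junctions:
        detected = frozenset(
            t for t, c in j.support.items() if c >= min_support
        )
        if detected:
            kept.append(replace(j, tissues_detected=detected))
    return kept


def junction_motif(
    junction: SpliceJunction, genome: Genome, gene_strand: str | None = None
) -> tuple[str, str]:
    """Border motif and inferred strand of one junction.

    The motif is the first two plus last two intron bases on the splicing
    strand. A forward read matching a canonical pair implies (+); its
    reverse complement (e.g. genomic CT..AC for a minus-strand GT-AG)
    implies (-). Non-canonical borders take the strand of the overlapping
    gene when given (else the junction's own strand) and report the
    genomic-forward dinucleotides as-is.
    """
    iv = junction.intron
    seq = extract_sequence(genome, iv)
    donor, acceptor = seq[:2], seq[-2:]
    forward = f"{donor}-{acceptor}"
    if forward in CANONICAL_MOTIFS:
        return forward, "+"
    reverse = f"{reverse_complement(acceptor)}-{reverse_complement(donor)}"
    if reverse in CANONICAL_MOTIFS:
        return reverse, "-"
    strand = gene_strand or junction.inferred_strand or "."
    return forward, strand


def annotate_motifs(
    junctions: Sequence[SpliceJunction],
    genome: Genome,
    genes: Sequence[GeneModel] = (),
) -> list[SpliceJunction]:
    """Fill ``motif`` and ``inferred_strand`` on every junction."""
    spans = [(g.chrom, g.start, g.end, g.strand) for g in genes]
    out = []
    for j in junctions:
        host = next(
            (
                s
                for c, a, b, s in spans
                if c == j.intron.chrom and a <= j.intron.start and j.intron.end <= b
            ),
            None,
        )
        motif, strand = junction_motif(j, genome, host)
        out.append(replace(j, motif=motif, inferred_strand=strand))
    return out


def motif_census(junctions: Sequence[SpliceJunction]) -> pd.DataFrame:
    counts = defaultdict(int)
    for j in junctions:
        counts[j.motif or "NA"] += 1
    total = sum(counts.values())
    rows = [
        {"motif": m, "count": c, "fraction": c / total if total else 0.0}
        for m, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["motif", "count", "fraction"])


def classify_junctions(
    junctions: Sequence[SpliceJunction], genes: Sequence[GeneModel]
) -> dict[tuple[str, int, int], str]:
    """Known vs novel per junction: known iff the intron interval exactly
    equals an annotated intron of some gene model."""
    annotated = {
        (i.chrom, i.start, i.end) for g in genes for i in g.introns
    }
    return {
        j.key: ("known" if j.key in annotated else "novel") for j in junctions
    }


# ---------------------------------------------------------------------------
# AS event detection

def _assign_to_genes(
    junctions: Sequence[SpliceJunction], genes: Sequence[GeneModel]
) -> tuple[dict[str, list[SpliceJunction]], list[SpliceJunction]]:
    """Junctions wholly inside a gene span, per gene; the rest are orphans."""
    by_gene: dict[str, list[SpliceJunction]] = {g.gene_id: [] for g in genes}
    orphans: list[SpliceJunction] = []
    for j in junctions:
        hosts = [
            g
            for g in genes
            if g.chrom == j.intron.chrom
            and g.start <= j.intron.start
            and j.intron.end <= g.end
        ]
        if not hosts:
            orphans.append(j)
        for g in hosts:
            by_gene[g.gene_id].append(j)
    return by_gene, orphans


def detect_as_events(
    junctions: Sequence[SpliceJunction],
    transcripts: Sequence[TranscriptModel],
    genes: Sequence[GeneModel],
    min_support: int = MIN_SUPPORT,
) -> tuple[list[ASEvent], list[SpliceJunction]]:
    """Detect IR / ES / A5SS / A3SS events per gene locus.

    Returns ``(events, orphan_junctions)``. Junctions are filtered first if
    they do not yet carry detection flags. A junction explained as an ES of
    a whole internal exon is not additionally paired into alternative
    splice-site events. ``tissues_detected`` of an event intersects the
    detection tissues of its defining evidence (both junctions of an
    A5SS/A3SS pair; junction and spanning transcript for IR).
    """
    if any(not j.tissues_detected for j in junctions):
        junctions = filter_junctions(junctions, min_support)
    by_gene, orphans = _assign_to_genes(junctions, genes)
    tr_by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
    for t in transcripts:
        tr_by_chrom[t.chrom].append(t)

    events: list[ASEvent] = []
    for g in genes:
        jxs = by_gene[g.gene_id]
        if not jxs and not tr_by_chrom.get(g.chrom):
            continue
        jx_by_key = {j.key: j for j in jxs}
        introns = g.introns
        annotated_keys = {(i.chrom, i.start, i.end) for i in introns}

        # --- exon skipping: donor of intron i to acceptor of intron i+1
        es_keys: set[tuple[str, int, int]] = set()
        for i in range(len(introns) - 1):
            key = (g.chrom, introns[i].start, introns[i + 1].end)
            j = jx_by_key.get(key)
            if j is None:
                continue
            es_keys.add(key)
            exon = g.cds_exons[i + 1]
            events.append(
                ASEvent(
                    "ES", g.gene_id, g.chrom, (exon.start, exon.end),
                    j.tissues_detected,
                )
            )

        # --- alternative 5'/3' splice sites: shared end, differing end
        pair_pool = [j for j in jxs if j.key not in es_keys]
        for a_idx in range(len(pair_pool)):
            for b_idx in range(a_idx + 1, len(pair_pool)):
                a, b = pair_pool[a_idx], pair_pool[b_idx]
                share_start = a.intron.start == b.intron.start
                share_end = a.intron.end == b.intron.end
                if share_start == share_end:  # neither or both (identical)
                    continue
                if share_end:
                    # shared right end: acceptor on +, donor on -
                    event_type = "A5SS" if g.strand == "+" else "A3SS"
                else:
                    event_type = "A3SS" if g.strand == "+" else "A5SS"
                novel = [j for j in (a, b) if j.key not in annotated_keys]
                anchor = novel[0] if len(novel) == 1 else min(
                    (a, b), key=lambda j: (j.intron.start, j.intron.end)
                )
                partner = b if anchor is a else a
                events.append(
                    ASEvent(
                        event_type, g.gene_id, g.chrom,
                        (anchor.intron.start, anchor.intron.end),
                        a.tissues_detected & b.tissues_detected,
                        partner=(partner.intron.start, partner.intron.end),
                    )
                )

        # --- intron retention: intron inside one exon of a local transcript
        local_tr = [
            t
            for t in tr_by_chrom.get(g.chrom, [])
            if t.strand == g.strand and t.start < g.end and g.start < t.end
        ]
        candidates: dict[tuple[str, int, int], None] = {}
        for i in introns:
            candidates[(i.chrom, i.start, i.end)] = None
        for j in jxs:
            candidates[j.key] = None
        for chrom, s, e in candidates:
            j = jx_by_key.get((chrom, s, e))
            if j is None:
                continue
            spanning = [
                t
                for t in local_tr
                if any(ex.start < s and e < ex.end for ex in t.exons)
            ]
            if not spanning:
                continue
            tr_tissues = frozenset().union(*(t.tissues_observed for t in spanning))
            tissues = (
                j.tissues_detected & tr_tissues if tr_tissues else j.tissues_detected
            )
            events.append(ASEvent("IR", g.gene_id, g.chrom, (s, e), tissues))

    return events, orphans


# ---------------------------------------------------------------------------
# Summaries

def tissue_breadth(
    items: Sequence[ASEvent] | Sequence[SpliceJunction], k: int = 2
) -> tuple[pd.Series, dict[str, int]]:
    """Per-item tissue breadth plus shared-by summary.

    ``breadth`` is the number of tissues in which the item's defining
    evidence is detected. The summary reports both readings of "shared by
    more than two tissues": at least k tissues and strictly more than k.
    """
    breadths = pd.Series(
        {i: len(getattr(it, "tissues_detected")) for i, it in enumerate(items)},
        dtype=int,
    )
    summary = {
        "total": int(len(breadths)),
        f"breadth_ge_{k}": int((breadths >= k).sum()),
        f"breadth_gt_{k}": int((breadths > k).sum()),
    }
    return breadths, summary


@dataclass(frozen=True)
class IntronSizeStats:
    mean_retained: float
    mean_all: float
    p_value: float
    n_retained: int
    n_all: int


def intron_size_stats(
    ir_events: Sequence[ASEvent], genes: Sequence[GeneModel]
) -> IntronSizeStats:
    """Mean retained-intron vs all-annotated-intron length (bp) with a
    two-sided Wilcoxon rank-sum p-value."""
    retained = [e.coords[1] - e.coords[0] for e in ir_events if e.event_type == "IR"]
    all_lengths = [len(i) for g in genes for i in g.introns]
    if not retained or not all_lengths:
        raise ValueError("need at least one retained and one annotated intron")
    if retained == all_lengths or (
        sorted(retained) == sorted(all_lengths)
    ):
        p = 1.0
    else:
        p = float(
            stats.mannwhitneyu(
                retained, all_lengths, alternative="two-sided", method="auto"
            ).pvalue
        )
    return IntronSizeStats(
        float(np.mean(retained)), float(np.mean(all_lengths)), p,
        len(retained), len(all_lengths),
    )


def event_table(events: Sequence[ASEvent]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": e.gene_id,
            "event_type": e.event_type,
            "chrom": e.chrom,
            "start": e.coords[0],
            "end": e.coords[1],
            "breadth": e.breadth,
            "tissues": ",".join(sorted(e.tissues_detected)),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=["gene_id", "event_type", "chrom", "start", "end", "breadth", "tissues"],
    )


def as_summary_table(events: Sequence[ASEvent], k: int = 2) -> pd.DataFrame:
    """Per-type event counts, genes with events, and shared-event counts —
    the shape of the study's per-type AS summary table."""
    rows = []
    order = ["IR", "A3SS", "A5SS", "ES"]
    for t in order + ["Total"]:
        sub = [e for e in events if t == "Total" or e.event_type == t]
        rows.append(
            {
                "as_type": t,
                "events": len(sub),
                "genes": len({e.gene_id for e in sub}),
                f"shared_ge_{k}_tissues": sum(1 for e in sub if e.breadth >= k),
                f"shared_gt_{k}_tissues": sum(1 for e in sub if e.breadth > k),
            }
        )
    return pd.DataFrame(rows)
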