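"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive expected results by exhaustive enumeration and
never call the implementation paths they check.
"""

from __future__ import annotations

import itertools
from math import comb

import pytest
from hypothesis import settings

from txome_atlas.core import GeneModel, GenomicInterval, SpliceJunction, TranscriptModel
from txome_atlas.report import run_pipeline
from txome_atlas.synthetic import SimConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# Fixtures

SMALL_CONFIG = dict(
    n_genes=40,
    n_ntrs=10,
    n_utr_genes=30,
    n_uorfs=20,
    as_events={"IR": 6, "ES": 3, "A5SS": 3, "A3SS": 3},
)


@pytest.fixture(scope="session")
def small_dataset():
    """Noiseless 40-gene synthetic dataset with planted truth."""
    return simulate_dataset(SimConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    ds = small_dataset
    return run_pipeline(
        ds.genome,
        ds.annotation.genes,
        ds.per_tissue_transcripts(),
        ds.junctions,
        ds.expression,
    )


@pytest.fixture
def toy_locus():
    """Plus-strand 3-exon gene: exons [0,100), [200,300), [400,500);
    introns I1=[100,200), I2=[300,400); genome with canonical borders."""
    gene = GeneModel(
        "GX",
        "+",
        (
            GenomicInterval("c", 0, 100, "+"),
            GenomicInterval("c", 200, 300, "+"),
            GenomicInterval("c", 400, 500, "+"),
        ),
    )
    seq = list("A" * 600)
    for intron in gene.introns:
        seq[intron.start : intron.start + 2] = "GT"
        seq[intron.end - 2 : intron.end] = "AG"
    return gene, {"c": "".join(seq)}


def make_junction(chrom, start, end, support, strand="+", name=""):
    return SpliceJunction(
        GenomicInterval(chrom, start, end, strand),
        support=dict(support),
        inferred_strand=strand,
        name=name or f"jx_{start}_{end}",
    )


def make_transcript(tid, strand, exons, tissues=(), chrom="c"):
    return TranscriptModel(
        tid,
        strand,
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        frozenset(tissues),
    )


# ---------------------------------------------------------------------------
# Oracles

def hypergeom_upper_tail(k: int, n: int, K: int, M: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(M, K, n) by exhaustive enumeration
    over all 2x2 tables with the fixed margins."""
    total = comb(M, n)
    p = 0.0
    for x in range(k, min(n, K) + 1):
        if n - x > M - K:
            continue
        p += comb(K, x) * comb(M - K, n - x) / total
    return p


def bh_step_up(p_values):
    """Hand evaluation of the Benjamini-Hochberg step-up rule."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = running
    return q


def brute_force_as_events(junctions, transcripts, gene):
    """Enumerate AS events at one locus by checking every junction pair and
    every junction/exon containment directly (no shared code with the
    detector). Junctions must already carry ``tissues_detected``."""
    introns = [(i.start, i.end) for i in gene.introns]
    in_gene = [
        j
        for j in junctions
        if j.intron.chrom == gene.chrom
        and gene.start <= j.intron.start
        and j.intron.end <= gene.end
    ]
    events = set()

    # exon skipping: exact donor of intron i, acceptor of intron i+1
    es_intervals = set()
    for i in range(len(introns) - 1):
        span = (introns[i][0], introns[i + 1][1])
        for j in in_gene:
            if (j.intron.start, j.intron.end) == span:
                exon = gene.cds_exons[i + 1]
                events.add(("ES", (exon.start, exon.end), j.tissues_detected))
                es_intervals.add(span)

    # alternative splice sites: all unordered pairs sharing exactly one end
    pool = [j for j in in_gene if (j.intron.start, j.intron.end) not in es_intervals]
    for a, b in itertools.combinations(pool, 2):
        sa, ea = a.intron.start, a.intron.end
        sb, eb = b.intron.start, b.intron.end
        if (sa == sb) == (ea == eb):
            continue
        if ea == eb:
            etype = "A5SS" if gene.strand == "+" else "A3SS"
        else:
            etype = "A3SS" if gene.strand == "+" else "A5SS"
        annotated = set(introns)
        novel = [j for j in (a, b) if (j.intron.start, j.intron.end) not in annotated]
        anchor = (
            novel[0]
            if len(novel) == 1
            else min((a, b), key=lambda j: (j.intron.start, j.intron.end))
        )
        events.add(
            (
                etype,
                (anchor.intron.start, anchor.intron.end),
                a.tissues_detected & b.tissues_detected,
            )
        )

    # intron retention: every candidate intron against every transcript exon
    candidates = set(introns) | {(j.intron.start, j.intron.end) for j in in_gene}
    for s, e in candidates:
        junction = next(
            (j for j in in_gene if (j.intron.start, j.intron.end) == (s, e)), None
        )
        if junction is None:
            continue
        spanning = [
            t
            for t in transcripts
            if t.strand == gene.strand
            and t.chrom == gene.chrom
            and t.start < gene.end
            and gene.start < t.end
            and any(ex.start < s and e < ex.end for ex in t.exons)
        ]
        if not spanning:
            continue
        tr_tissues = frozenset().union(*(t.tissues_observed for t in spanning))
        tissues = junction.tissues_detected & tr_tissues if tr_tissues else junction.tissues_detected
        events.add(("IR", (s, e), tissues))
    return events
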