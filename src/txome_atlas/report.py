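"""End-to-end pipeline orchestration and the summary report.

``run_pipeline`` executes the stages in dependency order — transcript
merging, overlap classification, NTR coding calls, UTR/uORF annotation,
expression-atlas statistics, junction filtering/typing and AS event
detection — and assembles an :class:`AtlasReport` whose every percentage
records the integer pair it was computed from, so the report's arithmetic
is reproducible line by line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import atlas as atlas_mod
from . import classify as classify_mod
from . import splicing as splicing_mod
from . import utr as utr_mod
from .core import ExpressionMatrix, GeneModel, Genome, SpliceJunction, TranscriptModel
from .synthetic import SimConfig, SimulatedDataset, simulate_dataset


def percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal, the report's print style."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator in percentage")
    value = Decimal(numerator) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summary_ratios(pairs: Mapping[str, tuple[int, int]]) -> dict[str, dict]:
    """Formatted percentages for named (numerator, denominator) pairs.

    Each entry echoes its integer pair so the printed value can be checked
    by hand: ``{"name": {"numerator": a, "denominator": b, "percent": p}}``.
    """
    out = {}
    for name, (num, den) in pairs.items():
        out[name] = {
            "numerator": int(num),
            "denominator": int(den),
            "percent": percent(num, den),
        }
    return out


@dataclass
class AtlasReport:
    """Per-stage summary counts plus derived percentages."""

    transcripts: dict = field(default_factory=dict)
    utr: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    junctions: dict = field(default_factory=dict)
    as_events: dict = field(default_factory=dict)
    ratios: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = []
        for section in ("transcripts", "utr", "expression", "junctions", "as_events"):
            lines.append(f"[{section}]")
            for key, value in getattr(self, section).items():
                lines.append(f"  {key} = {value}")
        lines.append("[ratios]")
        for name, entry in self.ratios.items():
            lines.append(
                f"  {name} = {entry['percent']}% "
                f"({entry['numerator']}/{entry['denominator']})"
            )
        return "\n".join(lines) + "\n"


@dataclass
class PipelineResult:
    merged: list[TranscriptModel]
    classification: pd.DataFrame
    utr_table: pd.DataFrame
    events: list
    orphan_junctions: list[SpliceJunction]
    junction_status: dict
    motif_census: pd.DataFrame
    as_summary: pd.DataFrame
    newick: str | None
    report: AtlasReport

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)
        self.utr_table.drop(columns=["uorfs"]).to_csv(
            outdir / "utr.tsv", sep="\t", index=False
        )
        splicing_mod.event_table(self.events).to_csv(
            outdir / "as_events.tsv", sep="\t", index=False
        )
        self.as_summary.to_csv(outdir / "as_summary.tsv", sep="\t", index=False)
        self.motif_census.to_csv(outdir / "motif_census.tsv", sep="\t", index=False)
        status_rows = [
            {"chrom": c, "start": s, "end": e, "status": st}
            for (c, s, e), st in sorted(self.junction_status.items())
        ]
        pd.DataFrame(status_rows).to_csv(
            outdir / "junction_status.tsv", sep="\t", index=False
        )
        if self.newick is not None:
            (outdir / "tissue_dendrogram.nwk").write_text(self.newick + "\n")
        (outdir / "report.json").write_text(self.report.to_json() + "\n")
        (outdir / "report.txt").write_text(self.report.to_text())


def run_pipeline(
    genome: Genome,
    genes: Sequence[GeneModel],
    per_tissue_transcripts: Mapping[str, Sequence[TranscriptModel]],
    junctions: Sequence[SpliceJunction],
    expression: ExpressionMatrix,
    min_support: int = splicing_mod.MIN_SUPPORT,
    breadth_k: int = 2,
    tau_threshold: float = atlas_mod.TAU_THRESHOLD,
) -> PipelineResult:
    """Run every downstream stage on loaded (or simulated) inputs."""
    genes = list(genes)

    # 1. merge per-tissue transcripts
    merged = classify_mod.merge_transcripts(per_tissue_transcripts.values())

    # 2. overlap classification + NTR coding calls
    classification = classify_mod.classify_transcripts(merged, genes, genome)
    label_counts = classification["label"].value_counts().to_dict()
    n_novel = int(label_counts.get("novel", 0))
    novel_coding = classification.loc[
        (classification.label == "novel") & (classification.coding_flag == True)  # noqa: E712
    ]

    # 3. UTRs and uORFs from complete transcripts
    gene_by_id = {g.gene_id: g for g in genes}
    complete_pairs = []
    merged_by_id = {t.transcript_id: t for t in merged}
    for _, row in classification.iterrows():
        if row.label == "complete":
            complete_pairs.append((merged_by_id[row.transcript_id], gene_by_id[row.gene_id]))
    utr_table = utr_mod.annotate_utrs(complete_pairs, genome)
    n_uorf_genes = int((utr_table["n_uorfs"] > 0).sum()) if len(utr_table) else 0

    # 4. expression atlas
    expr_summary = atlas_mod.atlas_summary(expression, tau_threshold)
    newick = None
    try:
        newick = atlas_mod.cluster_tissues(expression)
    except ValueError:
        pass  # too few tissues or constitutive genes; dendrogram skipped

    # 5. junctions and AS events
    filtered = splicing_mod.filter_junctions(junctions, min_support)
    typed = splicing_mod.annotate_motifs(filtered, genome, genes)
    status = splicing_mod.classify_junctions(typed, genes)
    n_known = sum(1 for s in status.values() if s == "known")
    events, orphans = splicing_mod.detect_as_events(typed, merged, genes, min_support)
    as_summary = splicing_mod.as_summary_table(events, breadth_k)
    canonical = sum(
        1 for j in typed if j.motif in splicing_mod.CANONICAL_MOTIFS
    )
    gtag = sum(1 for j in typed if j.motif == "GT-AG")

    multi_exon_genes = [g for g in genes if len(g.cds_exons) >= 2]
    as_genes = {e.gene_id for e in events}

    report = AtlasReport(
        transcripts={
            "merged": len(merged),
            **{k: int(v) for k, v in sorted(label_counts.items())},
            "novel_coding_orf_gt_100aa": int(len(novel_coding)),
        },
        utr={
            "genes_with_utr_call": int(len(utr_table)),
            "genes_with_uorf": n_uorf_genes,
        },
        expression=expr_summary,
        junctions={
            "retained": len(typed),
            "known": n_known,
            "novel": len(typed) - n_known,
            "gt_ag": gtag,
            "canonical": canonical,
            "orphans": len(orphans),
        },
        as_events={
            row["as_type"]: int(row["events"])
            for _, row in as_summary.iterrows()
        }
        | {
            "genes_with_as": len(as_genes),
            "intron_containing_genes": len(multi_exon_genes),
        },
    )
    pairs: dict[str, tuple[int, int]] = {}
    if len(merged):
        pairs["novel_of_merged"] = (n_novel, len(merged))
    if multi_exon_genes:
        pairs["as_genes_of_intron_containing"] = (len(as_genes), len(multi_exon_genes))
    if expr_summary["n_genes"]:
        pairs["expressed_of_annotated"] = (
            expr_summary["expressed_genes"], expr_summary["n_genes"]
        )
    if typed:
        pairs["gt_ag_of_retained"] = (gtag, len(typed))
    report.ratios = summary_ratios(pairs)

    return PipelineResult(
        merged=merged,
        classification=classification,
        utr_table=utr_table,
        events=events,
        orphan_junctions=orphans,
        junction_status=status,
        motif_census=splicing_mod.motif_census(typed),
        as_summary=as_summary,
        newick=newick,
        report=report,
    )


def run_synthetic_pipeline(
    config: SimConfig | None = None, outdir: str | Path | None = None
) -> tuple[SimulatedDataset, PipelineResult]:
    """Simulate a dataset with planted truth and run the full pipeline on it."""
    config = config or SimConfig()
    ds = simulate_dataset(config, outdir)
    result = run_pipeline(
        ds.genome,
        ds.annotation.genes,
        ds.per_tissue_transcripts(),
        ds.junctions,
        ds.expression,
    )
    if outdir is not None:
        result.write(Path(outdir) / "pipeline")
    return ds, result


def recovered_expression_classes(
    expression: ExpressionMatrix, tau_threshold: float = atlas_mod.TAU_THRESHOLD
) -> dict[str, str]:
    """Reconstruct each gene's expression class from the matrix alone.

    silent: expressed nowhere; housekeeping: FPKM > 50 everywhere;
    tissue_specific:<t>: tau >= threshold, assigned tissue t; else graded.
    """
    flags = atlas_mod.expressed_flags(expression)
    housekeeping = set(atlas_mod.find_housekeeping(expression))
    specific = atlas_mod.find_tissue_specific(expression, tau_threshold)
    out: dict[str, str] = {}
    for gene in expression.genes:
        if not flags.loc[gene].any():
            out[gene] = "silent"
        elif gene in housekeeping:
            out[gene] = "housekeeping"
        elif gene in specific:
            out[gene] = f"tissue_specific:{specific[gene]}"
        else:
            out[gene] = "graded"
    return out
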