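"""Expression-atlas statistics over a gene x tissue FPKM matrix.

A gene is *expressed* in a tissue when the lower bound of the 95%
confidence interval of its FPKM is greater than zero, and *constitutive*
when expressed in every surveyed tissue. Expression tiers follow fixed
FPKM cutoffs (low <= 5 < medium <= 50 < high). Tissue specificity uses the
Yanai et al. index

    tau_i = sum_j (1 - S_ij / S_i,max) / (n - 1)

with ``n`` tissues and ``S_ij`` the FPKM of gene i in tissue j: 0 for a
uniformly expressed (housekeeping-like) gene, 1 for a single-tissue gene.
Tissue relatedness is summarized by average-linkage clustering of
1 - Pearson correlation between log2(FPKM + 1) tissue columns, restricted
to constitutively expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import ExpressionMatrix

#: FPKM tier boundaries: low <= LOW_MAX < medium <= MED_MAX < high
TIER_LOW_MAX = 5.0
TIER_MED_MAX = 50.0

HOUSEKEEPING_FPKM = 50.0
TAU_THRESHOLD = 0.9


def expressed_flags(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Boolean gene x tissue table: CI lower bound strictly positive."""
    return matrix.ci_lo > 0


def call_expressed(matrix: ExpressionMatrix, gene_id: str, tissue: str) -> bool:
    if gene_id not in matrix.ci_lo.index:
        raise KeyError(f"gene {gene_id} not in expression matrix")
    if tissue not in matrix.ci_lo.columns:
        raise KeyError(f"tissue {tissue} not in expression matrix")
    value = matrix.ci_lo.at[gene_id, tissue]
    if pd.isna(value):
        raise ValueError(f"missing CI bound for {gene_id}/{tissue}")
    return bool(value > 0)


def constitutive_genes(matrix: ExpressionMatrix) -> list[str]:
    """Genes expressed (ci_lo > 0) in every tissue."""
    flags = expressed_flags(matrix)
    return list(flags.index[flags.all(axis=1)])


def classify_tier(fpkm: float) -> str:
    """Expression tier of a single FPKM value: low / medium / high."""
    if fpkm < 0 or np.isnan(fpkm):
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    if fpkm <= TIER_LOW_MAX:
        return "low"
    if fpkm <= TIER_MED_MAX:
        return "medium"
    return "high"


def tier_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene x tissue tier labels (vectorized :func:`classify_tier`)."""
    if (matrix.fpkm < 0).any().any():
        raise ValueError("negative FPKM in matrix")
    values = matrix.fpkm.to_numpy()
    tiers = np.where(values <= TIER_LOW_MAX, "low",
                     np.where(values <= TIER_MED_MAX, "medium", "high"))
    return pd.DataFrame(tiers, index=matrix.fpkm.index, columns=matrix.fpkm.columns)


@dataclass(frozen=True)
class TauResult:
    gene_id: str
    tau: float
    argmax_tissue: str


def compute_tau(fpkm: pd.Series | np.ndarray, gene_id: str = "") -> TauResult:
    """Tissue-specificity index of one gene's per-tissue FPKM vector.

    Requires >= 2 tissues and a positive maximum; an all-zero profile has no
    defined specificity and raises. Ties in the maximum resolve to the
    first tissue.
    """
    if isinstance(fpkm, pd.Series):
        names = list(fpkm.index.astype(str))
        values = fpkm.to_numpy(dtype=float)
    else:
        values = np.asarray(fpkm, dtype=float)
        names = [str(i) for i in range(len(values))]
    n = len(values)
    if n < 2:
        raise ValueError("tau undefined for fewer than 2 tissues")
    if (values < 0).any():
        raise ValueError("negative FPKM")
    smax = values.max()
    if smax <= 0:
        raise ValueError(f"tau undefined for all-zero expression (gene {gene_id!r})")
    tau = float(np.sum(1.0 - values / smax) / (n - 1))
    return TauResult(gene_id, tau, names[int(values.argmax())])


def tau_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene tau and argmax tissue; all-zero genes are omitted."""
    rows = []
    for gene_id, row in matrix.fpkm.iterrows():
        if row.max() <= 0:
            continue
        res = compute_tau(row, gene_id)
        rows.append({"gene_id": gene_id, "tau": res.tau,
                     "argmax_tissue": res.argmax_tissue})
    return pd.DataFrame(rows, columns=["gene_id", "tau", "argmax_tissue"])


def find_housekeeping(
    matrix: ExpressionMatrix, threshold: float = HOUSEKEEPING_FPKM
) -> list[str]:
    """Highly and stably expressed genes: FPKM strictly above ``threshold``
    in every tissue."""
    mask = (matrix.fpkm > threshold).all(axis=1)
    return list(matrix.fpkm.index[mask])


def find_tissue_specific(
    matrix: ExpressionMatrix, tau_threshold: float = TAU_THRESHOLD
) -> dict[str, str]:
    """Genes with tau >= threshold that are expressed in their argmax
    tissue, assigned to that tissue."""
    flags = expressed_flags(matrix)
    out: dict[str, str] = {}
    for gene_id, row in matrix.fpkm.iterrows():
        if row.max() <= 0:
            continue
        res = compute_tau(row, gene_id)
        if res.tau >= tau_threshold and bool(flags.at[gene_id, res.argmax_tissue]):
            out[gene_id] = res.argmax_tissue
    return out


# ---------------------------------------------------------------------------
# Tissue clustering

def tissue_distance_matrix(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> pd.DataFrame:
    """1 - Pearson correlation between log2(FPKM + 1) tissue columns."""
    fpkm = matrix.fpkm if genes is None else matrix.fpkm.loc[genes]
    if fpkm.shape[0] < 2:
        raise ValueError("need >= 2 genes to correlate tissue columns")
    logged = np.log2(fpkm.to_numpy(dtype=float) + 1.0)
    sd = logged.std(axis=0)
    for i, tissue in enumerate(fpkm.columns):
        if sd[i] == 0:
            raise ValueError(
                f"tissue {tissue!r} has constant expression; correlation undefined"
            )
    corr = np.corrcoef(logged, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # clip rounding noise around exact co-/anti-correlation
    dist[np.abs(dist) < 1e-12] = 0.0
    dist[np.abs(dist - 2.0) < 1e-12] = 2.0
    return pd.DataFrame(dist, index=fpkm.columns, columns=fpkm.columns)


def _tree_to_newick(node, labels: list[str], parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    children = sorted(
        (node.left, node.right),
        key=lambda child: min(labels[i] for i in child.pre_order(lambda x: x.id)),
    )
    inner = ",".join(_tree_to_newick(c, labels, node.dist) for c in children)
    return f"({inner}):{length:.6g}"


def cluster_tissues(
    matrix: ExpressionMatrix, genes: list[str] | None = None
) -> str:
    """Average-linkage dendrogram of tissues as a newick string.

    By default clusters on the constitutively expressed genes (the paper
    logic: correlation of tissues over genes active everywhere). Leaf order
    is made deterministic by sorting children on their smallest tissue name.
    """
    if genes is None:
        genes = constitutive_genes(matrix)
    if len(genes) < 2:
        raise ValueError("need >= 2 constitutive genes to cluster tissues")
    dist = tissue_distance_matrix(matrix, genes)
    if dist.shape[0] < 3:
        raise ValueError("need >= 3 tissues to build a dendrogram")
    condensed = squareform(dist.to_numpy(), checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    tree = hierarchy.to_tree(linkage)
    labels = list(dist.columns)
    return _tree_to_newick(tree, labels, tree.dist) + ";"


def atlas_summary(matrix: ExpressionMatrix, tau_threshold: float = TAU_THRESHOLD) -> dict:
    """Headline atlas counts used by the pipeline report."""
    flags = expressed_flags(matrix)
    expressed_any = flags.any(axis=1)
    return {
        "n_genes": int(matrix.fpkm.shape[0]),
        "n_tissues": int(matrix.fpkm.shape[1]),
        "expressed_genes": int(expressed_any.sum()),
        "constitutive_genes": int(flags.all(axis=1).sum()),
        "housekeeping_genes": len(find_housekeeping(matrix)),
        "tissue_specific_genes": len(find_tissue_specific(matrix, tau_threshold)),
    }
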