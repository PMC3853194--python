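"""Category over-representation testing with BH false-discovery control.

For a study set of n genes drawn from a background of M genes, a category
with K background members and k study hits forms the 2x2 table

    [[k, n - k], [K - k, M - n - K + k]]

The test follows the rule used in the source analysis pipeline: when the
minimum *expected* cell count N of that table is <= 5 the one-sided
Fisher's exact test (hypergeometric upper tail, over-representation) is
used, otherwise a Pearson chi-square with 1 df. P-values across categories
are adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: chi-square validity cutoff on the minimum expected cell count
EXPECTED_COUNT_CUTOFF = 5.0


@dataclass(frozen=True)
class EnrichmentResult:
    category_id: str
    k: int
    n: int
    K: int
    M: int
    p_value: float
    q_value: float
    test_used: str
    min_expected: float


def _validate_counts(k: int, n: int, K: int, M: int) -> None:
    if min(k, n, K, M) < 0:
        raise ValueError("counts must be non-negative")
    if k > n or k > K or n > M or K > M:
        raise ValueError(
            f"inconsistent counts k={k}, n={n}, K={K}, M={M}: "
            "require k <= min(n, K) and n, K <= M"
        )
    if M - n - K + k < 0:
        raise ValueError(f"inconsistent counts: background cell negative (k={k}, n={n}, K={K}, M={M})")


def enrichment_test(k: int, n: int, K: int, M: int) -> tuple[float, str]:
    """Over-representation p-value for k study hits of a K-member category.

    Returns ``(p_value, test_used)`` where ``test_used`` is ``"fisher"``
    (one-sided hypergeometric upper tail) when the minimum expected cell
    count is <= 5, else ``"chisq"`` (Pearson, 1 df, no continuity
    correction).
    """
    _validate_counts(k, n, K, M)
    table = np.array([[k, n - k], [K - k, M - n - K + k]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / M
    min_expected = float(expected.min())
    if min_expected <= EXPECTED_COUNT_CUTOFF:
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        return min(1.0, p), "fisher"
    chi2 = stats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue), "chisq"


def min_expected_count(k: int, n: int, K: int, M: int) -> float:
    _validate_counts(k, n, K, M)
    table = np.array([[k, n - k], [K - k, M - n - K + k]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / M
    return float(expected.min())


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving.

    q_(i) = min over j >= i of p_(j) * m / j, mapped back to input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    gene_to_categories: Mapping[str, Sequence[str] | str],
) -> pd.DataFrame:
    """Enrichment of every category among the study genes, sorted by q.

    Study genes outside the background are ignored; categories are flat
    labels (no ontology structure).
    """
    background_set = set(background)
    study_set = set(study) & background_set
    M, n = len(background_set), len(study_set)
    if M == 0:
        raise ValueError("empty background")
    members: dict[str, set[str]] = {}
    for gene, cats in gene_to_categories.items():
        if gene not in background_set:
            continue
        if isinstance(cats, str):
            cats = [cats]
        for c in cats:
            members.setdefault(c, set()).add(gene)
    rows = []
    for cat in sorted(members):
        K = len(members[cat])
        k = len(members[cat] & study_set)
        p, test_used = enrichment_test(k, n, K, M)
        rows.append(
            {
                "category_id": cat,
                "k": k,
                "n": n,
                "K": K,
                "M": M,
                "p_value": p,
                "test_used": test_used,
                "min_expected": min_expected_count(k, n, K, M),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["category_id", "k", "n", "K", "M", "p_value", "test_used", "min_expected"],
    )
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["q_value", "p_value", "category_id"]).reset_index(drop=True)
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
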