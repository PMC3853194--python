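"""Expressed/constitutive calls, tiers, the tau index and tissue clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from txome_atlas.atlas import (
    call_expressed,
    classify_tier,
    cluster_tissues,
    compute_tau,
    constitutive_genes,
    find_housekeeping,
    find_tissue_specific,
    tissue_distance_matrix,
)
from txome_atlas.core import ExpressionMatrix

TISSUES = ["callus", "root", "stem", "leaf", "flower", "silique"]


def make_matrix(rows: dict[str, list[float]], ci_lo=None) -> ExpressionMatrix:
    fpkm = pd.DataFrame.from_dict(rows, orient="index", columns=TISSUES, dtype=float)
    lo = fpkm * 0.5 if ci_lo is None else pd.DataFrame.from_dict(
        ci_lo, orient="index", columns=TISSUES, dtype=float
    )
    return ExpressionMatrix(fpkm, lo, fpkm * 2 + 1)


class TestExpressedCalls:
    def test_positive_ci_lower_bound_is_expressed(self):
        m = make_matrix({"g": [2.0] * 6}, {"g": [0.4] * 6})
        assert call_expressed(m, "g", "root")

    def test_zero_lower_bound_not_expressed(self):
        m = make_matrix({"g": [0.3] * 6}, {"g": [0.0] * 6})
        assert not call_expressed(m, "g", "root")

    def test_constitutive_requires_all_tissues(self):
        m = make_matrix(
            {"a": [2.0] * 6, "b": [2.0] * 6},
            {"a": [0.5] * 6, "b": [0.5] * 5 + [0.0]},
        )
        assert constitutive_genes(m) == ["a"]

    def test_missing_gene_or_tissue_errors(self):
        m = make_matrix({"g": [1.0] * 6})
        with pytest.raises(KeyError):
            call_expressed(m, "absent", "root")
        with pytest.raises(KeyError):
            call_expressed(m, "g", "petal")


class TestTiers:
    @pytest.mark.parametrize(
        "fpkm,tier",
        [
            (0.0, "low"),
            (5.0, "low"),        # boundary: lowly means FPKM <= 5
            (5.01, "medium"),
            (50.0, "medium"),    # boundary: medium means 5 < FPKM <= 50
            (50.01, "high"),
            (1e6, "high"),
        ],
    )
    def test_boundaries(self, fpkm, tier):
        assert classify_tier(fpkm) == tier

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_tier(-0.1)

    @given(st.floats(min_value=0, max_value=1e9, allow_nan=False))
    def test_partition(self, fpkm):
        assert classify_tier(fpkm) in {"low", "medium", "high"}


class TestTau:
    def test_uniform_profile_zero(self):
        assert compute_tau([5, 5, 5, 5, 5, 5]).tau == 0.0

    def test_one_hot_profile_one(self):
        res = compute_tau(pd.Series([0, 0, 0, 0, 0, 9], index=TISSUES))
        assert res.tau == 1.0
        assert res.argmax_tissue == "silique"

    def test_hand_case(self):
        # (10,5,0,0,0,0): (0 + 0.5 + 4x1)/5 = 0.9
        assert compute_tau([10, 5, 0, 0, 0, 0]).tau == pytest.approx(0.9, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            compute_tau([0.0, 0.0, 0.0])

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError, match="2 tissues"):
            compute_tau([5.0])

    @given(
        st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=2, max_size=12)
    )
    def test_bounds(self, values):
        if max(values) <= 0:
            values[0] = 1.0
        tau = compute_tau(values).tau
        assert 0.0 <= tau <= 1.0 + 1e-12

    def test_monotone_decrease_when_second_tissue_rises(self):
        taus = [compute_tau([9.0, x, 0, 0, 0, 0]).tau for x in (0.0, 1.0, 4.0, 9.0)]
        assert all(a > b for a, b in zip(taus, taus[1:]))


class TestHousekeeping:
    def test_above_threshold_everywhere_included(self):
        m = make_matrix({"g": [51, 60, 70, 80, 90, 55]})
        assert find_housekeeping(m) == ["g"]

    def test_exactly_threshold_excluded(self):
        m = make_matrix({"g": [51, 60, 70, 80, 90, 50]})
        assert find_housekeeping(m) == []

    def test_empty_matrix(self):
        fpkm = pd.DataFrame(columns=TISSUES, dtype=float)
        m = ExpressionMatrix(fpkm, fpkm.copy(), fpkm.copy())
        assert find_housekeeping(m) == []


class TestTissueSpecific:
    def test_one_hot_assigned_to_its_tissue(self):
        m = make_matrix({"g": [0, 0, 0, 40, 0, 0]})
        assert find_tissue_specific(m) == {"g": "leaf"}

    def test_uniform_unassigned(self):
        m = make_matrix({"g": [10] * 6})
        assert find_tissue_specific(m) == {}

    def test_threshold_one_requires_strict_one_hot(self):
        m = make_matrix({"a": [0, 0, 0, 40, 0, 0], "b": [1, 0, 0, 40, 0, 0]})
        assert find_tissue_specific(m, tau_threshold=1.0) == {"a": "leaf"}

    def test_not_expressed_in_argmax_excluded(self):
        m = make_matrix(
            {"g": [0, 0, 0, 40, 0, 0]},
            ci_lo={"g": [0, 0, 0, 0, 0, 0]},
        )
        assert find_tissue_specific(m) == {}

    def test_planted_classes_recovered(self, small_dataset):
        ds = small_dataset
        specific = find_tissue_specific(ds.expression)
        expected = {
            g: c.split(":", 1)[1]
            for g, c in ds.truth.expression_class.items()
            if c.startswith("tissue_specific:")
        }
        assert specific == expected
        hk = set(find_housekeeping(ds.expression))
        assert hk == {
            g for g, c in ds.truth.expression_class.items() if c == "housekeeping"
        }


class TestClustering:
    def _matrix(self, cols: dict[str, np.ndarray]) -> ExpressionMatrix:
        fpkm = pd.DataFrame(cols).abs()
        fpkm.index = [f"g{i}" for i in range(len(fpkm))]
        return ExpressionMatrix(fpkm, fpkm * 0.5, fpkm * 2)

    def test_identical_columns_distance_zero_merged_first(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 50, 30)
        y = rng.uniform(1, 50, 30)
        m = self._matrix({"A": x, "B": x, "C": y, "D": y * 3 + rng.uniform(0, 5, 30)})
        d = tissue_distance_matrix(m, genes=list(m.fpkm.index))
        assert d.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        newick = cluster_tissues(m, genes=list(m.fpkm.index))
        assert "(A:0,B:0)" in newick.replace(" ", "")

    def test_anticorrelated_distance_two(self):
        x = np.linspace(1, 10, 20)
        fpkm = pd.DataFrame({"A": 2.0**x, "B": 2.0 ** (11 - x), "C": 2.0**x})
        fpkm.index = [f"g{i}" for i in range(20)]
        m = ExpressionMatrix(fpkm, fpkm * 0.5, fpkm * 2)
        # log2(fpkm+1) of A and B are near-perfectly anticorrelated
        d = tissue_distance_matrix(m, genes=list(fpkm.index))
        assert d.loc["A", "B"] == pytest.approx(2.0, abs=0.01)

    def test_planted_block_topology_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(5, 50, size=(60, 3))
        jitter = lambda col: base[:, col] * (1 + rng.normal(0, 0.02, 60))
        m = self._matrix(
            {
                "A": jitter(0), "B": jitter(0),
                "D": jitter(1), "E": jitter(1),
                "F": base[:, 2] * (1 + rng.normal(0, 0.4, 60)),
            }
        )
        newick = cluster_tissues(m, genes=list(m.fpkm.index))
        stripped = "".join(ch for ch in newick if ch.isalpha() or ch in "(),")
        assert "(A,B)" in stripped
        assert "(D,E)" in stripped

    def test_constant_column_error_names_tissue(self):
        rng = np.random.default_rng(2)
        m = self._matrix(
            {"A": rng.uniform(1, 9, 10), "B": rng.uniform(1, 9, 10),
             "C": np.full(10, 7.0)}
        )
        with pytest.raises(ValueError, match="'C'"):
            cluster_tissues(m, genes=list(m.fpkm.index))

    def test_synthetic_dendrogram_contains_all_tissues(self, small_pipeline):
        newick = small_pipeline.newick
        assert newick is not None and newick.endswith(";")
        for tissue in TISSUES:
            assert tissue in newick
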