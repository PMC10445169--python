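import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pasmatch.errors import ValidationError
from pasmatch.mirna import (
    MiRNACountMatrix,
    VolcanoClass,
    classify_volcano,
    classify_volcano_table,
    count_expressed,
    relative_abundance,
    top_n,
)

# Published top-ten DE tables for the OCCC-with-endometriosis contrast,
# used as shuffled inputs for the ranking operation.
DOWN_TABLE = [
    ("hsa-miR-143-3p", -2.81, 6.61e-09),
    ("hsa-miR-127-3p", -1.91, 1.41e-08),
    ("hsa-let-7c-5p", -3.09, 2.11e-04),
    ("hsa-miR-99a-5p", -3.57, 1.16e-03),
    ("hsa-miR-27b-3p", -1.80, 2.87e-03),
    ("hsa-miR-199a-3p", -2.38, 3.86e-03),
    ("hsa-miR-199b-3p", -2.38, 3.86e-03),
    ("hsa-miR-146b-5p", -2.12, 1.18e-02),
    ("hsa-miR-199a-5p", -2.18, 1.31e-02),
    ("hsa-miR-23b-3p", -1.60, 4.23e-02),
]
UP_TABLE = [
    ("hsa-miR-10a-5p", 4.37, 2.43e-18),
    ("hsa-miR-141-3p", 4.67, 1.31e-15),
    ("hsa-miR-30a-5p", 2.87, 1.37e-12),
    ("hsa-miR-183-5p", 4.62, 4.90e-06),
    ("hsa-miR-30d-5p", 1.63, 1.44e-05),
    ("hsa-miR-30c-5p", 1.98, 2.39e-05),
    ("hsa-miR-182-5p", 3.77, 4.94e-04),
    ("hsa-miR-98-5p", 1.39, 2.87e-03),
    ("hsa-miR-148b-3p", 1.02, 6.38e-03),
    ("hsa-miR-191-5p", 1.24, 6.87e-03),
]


def de_frame(rows):
    return pd.DataFrame(rows, columns=["feature_id", "log2_fold_change", "p_adj"])


def counts_matrix(data, groups):
    frame = pd.DataFrame(data)
    return MiRNACountMatrix(counts=frame, groups=pd.Series(groups))


class TestRelativeAbundance:
    def test_single_mirna_is_everything(self):
        mat = counts_matrix({"s1": [100]}, {"s1": "g"})
        mat.counts.index = ["miR-A"]
        pct = relative_abundance(mat, "g")
        assert pct["miR-A"] == pytest.approx(100.0)

    def test_pooled_arithmetic(self):
        # miR-A [50, 150] over group totals [200, 300] -> 200/500 = 40%
        mat = counts_matrix({"s1": [50, 150], "s2": [150, 150]}, {"s1": "g", "s2": "g"})
        mat.counts.index = ["miR-A", "miR-B"]
        pct = relative_abundance(mat, "g")
        assert pct["miR-A"] == pytest.approx(40.0)

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        mat = counts_matrix(
            {f"s{i}": rng.integers(0, 500, size=12) for i in range(4)},
            {f"s{i}": "g" for i in range(4)},
        )
        assert relative_abundance(mat, "g").sum() == pytest.approx(100.0, abs=1e-9)
        assert relative_abundance(mat, "g", mode="mean_fraction").sum() == pytest.approx(100.0, abs=1e-9)

    def test_uniform_library_scaling_invariance(self):
        rng = np.random.default_rng(1)
        raw = rng.integers(1, 100, size=(6, 3))
        mat = counts_matrix({f"s{i}": raw[:, i] for i in range(3)}, {f"s{i}": "g" for i in range(3)})
        scaled = counts_matrix({f"s{i}": raw[:, i] * 7 for i in range(3)}, {f"s{i}": "g" for i in range(3)})
        pd.testing.assert_series_equal(relative_abundance(mat, "g"), relative_abundance(scaled, "g"))

    def test_nonuniform_scaling_changes_pooled_composition(self):
        raw = np.array([[10, 90], [90, 10]])
        mat = counts_matrix({"s1": raw[:, 0], "s2": raw[:, 1]}, {"s1": "g", "s2": "g"})
        skew = counts_matrix({"s1": raw[:, 0] * 10, "s2": raw[:, 1]}, {"s1": "g", "s2": "g"})
        assert not np.allclose(relative_abundance(mat, "g"), relative_abundance(skew, "g"))

    def test_empty_group_errors(self):
        mat = counts_matrix({"s1": [5]}, {"s1": "g"})
        with pytest.raises(ValidationError):
            relative_abundance(mat, "other")


class TestCountExpressed:
    def test_all_zero_matrix(self):
        mat = counts_matrix({"s1": [0, 0], "s2": [0, 0]}, {"s1": "g", "s2": "g"})
        assert count_expressed(mat) == 0

    def test_everything_expressed(self):
        mat = counts_matrix({"s1": [1, 0], "s2": [0, 3]}, {"s1": "g", "s2": "g"})
        assert count_expressed(mat) == 2

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        data = rng.poisson(0.5, size=(40, 6))
        mat = counts_matrix({f"s{i}": data[:, i] for i in range(6)}, {f"s{i}": "g" for i in range(6)})
        for min_count in (1, 2, 5):
            brute = sum(1 for row in data if any(c >= min_count for c in row))
            assert count_expressed(mat, min_count) == brute

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            counts_matrix({"s1": [-1]}, {"s1": "g"})


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc, p, expected",
        [
            (4.37, 2.43e-18, VolcanoClass.SIG_AND_LARGE),  # most upregulated species
            (0.2, 0.5, VolcanoClass.NEITHER),
            (0.5, 0.01, VolcanoClass.SIG_ONLY),
            (2.0, 0.5, VolcanoClass.LARGE_ONLY),
            (-1.01, 0.049, VolcanoClass.SIG_AND_LARGE),
            (1.0, 0.04, VolcanoClass.SIG_ONLY),  # |lfc| must strictly exceed 1
            (1.5, 0.05, VolcanoClass.LARGE_ONLY),  # p must be strictly below 0.05
        ],
    )
    def test_quadrants(self, lfc, p, expected):
        assert classify_volcano(lfc, p) is expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            classify_volcano(np.nan, 0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-10, 10), st.floats(0, 1)),
            min_size=1,
            max_size=30,
        )
    )
    def test_classes_partition_any_table(self, rows):
        table = de_frame([(f"f{i}", lfc, p) for i, (lfc, p) in enumerate(rows)])
        annotated = classify_volcano_table(table)
        assert len(annotated) == len(table)
        assert set(annotated["volcano_class"]) <= {c.value for c in VolcanoClass}


class TestTopN:
    def test_shuffled_down_table_ranks_mir143_first(self):
        rng = np.random.default_rng(3)
        rows = list(DOWN_TABLE)
        rng.shuffle(rows)
        top = top_n(de_frame(rows), "down", n=10)
        assert top.loc[0, "feature_id"] == "hsa-miR-143-3p"
        assert top.loc[0, "log2_fold_change"] == pytest.approx(-2.81)
        # the tied 199a-3p/199b-3p pair keeps a deterministic id order
        tied = top[top["p_adj"] == 3.86e-03]["feature_id"].tolist()
        assert tied == ["hsa-miR-199a-3p", "hsa-miR-199b-3p"]

    def test_shuffled_up_table_ranks_mir10a_first(self):
        rng = np.random.default_rng(4)
        rows = list(UP_TABLE)
        rng.shuffle(rows)
        top = top_n(de_frame(rows), "up", n=10)
        assert top.loc[0, "feature_id"] == "hsa-miR-10a-5p"
        assert top.loc[0, "p_adj"] == pytest.approx(2.43e-18)

    def test_empty_table_gives_empty_result(self):
        assert top_n(de_frame([]), "up", n=5).empty

    def test_direction_filters_sign_and_significance(self):
        rows = [("up_sig", 2.0, 0.01), ("down_sig", -2.0, 0.01), ("up_ns", 2.0, 0.5)]
        top = top_n(de_frame(rows), "up", n=5)
        assert top["feature_id"].tolist() == ["up_sig"]
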