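import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cupsig as cs
from cupsig.matrices import CountMatrix, ExpressionMatrix


def write(tmp_path, text, name="m.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadCountMatrix:
    def test_parses_shape_and_values(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\ts2\nA\t1\t2\nB\t3\t4\nC\t5\t6\n")
        cm = cs.read_count_matrix(p)
        assert cm.shape == (3, 2)
        assert cm.counts.loc["B", "s2"] == 4

    def test_duplicate_gene_raises(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\nMYC\t1\nMYC\t2\n")
        with pytest.raises(ValueError, match="duplicate gene.*MYC"):
            cs.read_count_matrix(p)

    def test_duplicate_sample_raises(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\ts1\nA\t1\t2\n")
        with pytest.raises(ValueError, match="duplicate sample"):
            cs.read_count_matrix(p)

    def test_negative_count_reports_coordinates(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\ts2\nA\t1\t2\nB\t-1\t4\n")
        with pytest.raises(ValueError, match="'B'.*'s1'"):
            cs.read_count_matrix(p)

    def test_non_integer_count_rejected(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\nA\t1.5\n")
        with pytest.raises(ValueError, match="nonnegative integers"):
            cs.read_count_matrix(p)

    def test_dup_pct_column_split_off(self, tmp_path):
        p = write(tmp_path, "gene_id\ts1\tdup_pct\nA\t1\t5\nB\t2\t30\n")
        cm = cs.read_count_matrix(p)
        assert cm.shape == (2, 1)
        assert cm.dup_pct.loc["B"] == 30

    def test_roundtrip_exact(self, tmp_path, tiny_counts):
        cm = CountMatrix(tiny_counts, pd.Series([1.0, 2.0, 3.0], index=tiny_counts.index))
        out = tmp_path / "out.tsv"
        cs.write_count_matrix(cm, out)
        back = cs.read_count_matrix(out)
        pd.testing.assert_frame_equal(back.counts, cm.counts, check_names=False)
        pd.testing.assert_series_equal(back.dup_pct, cm.dup_pct, check_names=False)


class TestCpmNormalize:
    def test_proportions_times_1e6(self, tiny_counts):
        em = cs.cpm_normalize(CountMatrix(tiny_counts))
        assert em.unit == "CPM"
        np.testing.assert_allclose(em.values["s1"], [250000, 750000, 0])
        np.testing.assert_allclose(em.values.sum(axis=0), [1e6, 1e6])

    def test_equal_counts_give_uniform_cpm(self):
        df = pd.DataFrame({"s": [7] * 5}, index=list("abcde"))
        em = cs.cpm_normalize(CountMatrix(df))
        np.testing.assert_allclose(em.values["s"], [2e5] * 5)

    def test_zero_total_sample_named(self):
        df = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            cs.cpm_normalize(CountMatrix(df))

    def test_idempotent_on_cpm(self, tiny_counts):
        em = cs.cpm_normalize(CountMatrix(tiny_counts))
        again = cs.cpm_normalize(em)
        pd.testing.assert_frame_equal(again.values, em.values)


class TestQcFilter:
    def make(self, means, n_samples=2):
        df = pd.DataFrame(
            {f"s{j}": means for j in range(n_samples)},
            index=[f"g{i}" for i in range(len(means))],
        )
        return ExpressionMatrix(df, "CPM")

    def test_low_mean_removed_boundary_kept(self):
        em = self.make([4.0, 5.0, 6.0])
        with pytest.warns(UserWarning, match="dup_pct"):
            out = cs.filter_genes_qc(em)
        assert list(out.gene_ids) == ["g1", "g2"]  # mean 4.0 < 5 removed, 5.0 kept

    def test_dup_pct_boundary_strictly_greater_removed(self):
        em = self.make([10.0, 10.0, 10.0])
        dup = pd.Series([20.0, 20.0001, 5.0], index=em.gene_ids)
        out = cs.filter_genes_qc(em, dup)
        assert list(out.gene_ids) == ["g0", "g2"]

    def test_disjoint_criteria_leave_survivors(self):
        # 10 genes: 3 fail the CPM rule, 3 others fail the dup rule, 4 survive
        means = [1.0, 2.0, 3.0] + [10.0] * 7
        em = self.make(means)
        dup = pd.Series([0, 0, 0, 25, 30, 40, 10, 10, 10, 10.0], index=em.gene_ids)
        out = cs.filter_genes_qc(em, dup)
        assert list(out.gene_ids) == ["g6", "g7", "g8", "g9"]

    def test_idempotent(self):
        em = self.make([1.0, 10.0, 20.0])
        dup = pd.Series([0.0, 0.0, 0.0], index=em.gene_ids)
        once = cs.filter_genes_qc(em, dup)
        twice = cs.filter_genes_qc(once, dup)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_all_removed_raises(self):
        em = self.make([0.1, 0.2])
        with pytest.raises(ValueError, match="empty matrix after QC"):
            cs.filter_genes_qc(em, pd.Series([0.0, 0.0], index=em.gene_ids))

    def test_requires_cpm_unit(self, tiny_counts):
        with pytest.raises(ValueError, match="CPM"):
            cs.filter_genes_qc(ExpressionMatrix(tiny_counts.astype(float), "counts"))


class TestLowExpressionFilter:
    def test_strict_mean_rule(self):
        df = pd.DataFrame({"s1": [0.5, 1.0, 2.0]}, index=["a", "b", "c"])
        out = cs.filter_low_expression(ExpressionMatrix(df, "CPM"))
        assert list(out.gene_ids) == ["b", "c"]

    def test_zero_threshold_is_identity(self):
        df = pd.DataFrame({"s1": [0.0, 1.0]}, index=["a", "b"])
        out = cs.filter_low_expression(ExpressionMatrix(df, "CPM"), cpm_min=0)
        assert list(out.gene_ids) == ["a", "b"]


class TestAverageReplicates:
    def test_mean_and_partition(self):
        df = pd.DataFrame(
            np.array([[2.0, 4.0, 1.0, 5.0, 7.0, 9.0]]),
            index=["g"],
            columns=[f"s{i}" for i in range(6)],
        )
        ann = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "replicate_of": ["A", "A", "", "B", "B", "B"],
            }
        )
        out = cs.average_replicates(ExpressionMatrix(df, "CPM"), ann)
        assert out.shape == (1, 3)
        assert out.values.loc["g", "A"] == 3.0
        assert out.values.loc["g", "s2"] == 1.0  # singleton keeps its value
        assert out.values.loc["g", "B"] == 7.0

    def test_missing_annotation_raises(self):
        df = pd.DataFrame({"s1": [1.0]}, index=["g"])
        ann = pd.DataFrame({"sample_id": ["other"], "replicate_of": [""]})
        with pytest.raises(ValueError, match="without annotation"):
            cs.average_replicates(ExpressionMatrix(df, "CPM"), ann)


class TestZscore:
    def test_three_point_example(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        z = cs.zscore(ExpressionMatrix(df, "logCPM"))
        np.testing.assert_allclose(z.values.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_gene_dropped_with_warning(self):
        df = pd.DataFrame(
            [[1.0, 2.0], [5.0, 5.0]], index=["var", "flat"], columns=["a", "b"]
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            z = cs.zscore(ExpressionMatrix(df, "logCPM"))
        assert list(z.gene_ids) == ["var"]

    def test_single_sample_raises(self):
        df = pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="at least 2 samples"):
            cs.zscore(ExpressionMatrix(df, "logCPM"), axis="gene")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(2, 8), st.integers(2, 8), st.integers(0, 2**31 - 1))
    def test_axis_moments_property(self, n_genes, n_samples, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)],
        )
        for axis, ax in (("gene", 1), ("sample", 0)):
            z = cs.zscore(ExpressionMatrix(df, "logCPM"), axis=axis).values
            np.testing.assert_allclose(z.mean(axis=ax), 0.0, atol=1e-12)
            np.testing.assert_allclose(z.std(axis=ax, ddof=1), 1.0, atol=1e-9)


class TestGmt:
    def test_parse_and_sizes(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tg1\tg2\nS2\tother\tg3\n")
        coll = cs.read_gmt(p)
        assert coll.names == ["S1", "S2"]
        assert len(coll["S1"]) == 2

    def test_member_dedup_warns(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tg1\tg1\n")
        with pytest.warns(UserWarning, match="de-duplicated"):
            coll = cs.read_gmt(p)
        assert len(coll["S1"]) == 1

    def test_short_line_reports_number(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\tdesc\tg1\nS2\tonlydesc\n")
        with pytest.raises(ValueError, match=":2:"):
            cs.read_gmt(p)

    def test_duplicate_name_raises(self, tmp_path):
        p = tmp_path / "c.gmt"
        p.write_text("S1\td\tg1\nS1\td\tg2\n")
        with pytest.raises(ValueError, match="duplicate set name"):
            cs.read_gmt(p)

    def test_roundtrip(self, tmp_path):
        coll = cs.GeneSetCollection(
            [cs.GeneSet("A", ("g2", "g1"), "d1"), cs.GeneSet("B", ("g3",), "d2")]
        )
        p = tmp_path / "out.gmt"
        cs.write_gmt(coll, p)
        back = cs.read_gmt(p)
        assert back["A"].members == ("g2", "g1")
        assert back["B"].description == "d2"
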