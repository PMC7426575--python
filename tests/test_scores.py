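"""Signature scores, percentile classes, CYT, subgroup summaries, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import immunecycle as ic
from conftest import random_raw_matrix
from immunecycle.scores import benjamini_hochberg, exact_mannwhitney


def matrix_from(dict_of_rows):
    df = pd.DataFrame(dict_of_rows).T.astype(float)
    df.columns = [f"S{i}" for i in range(df.shape[1])]
    return ic.ExpressionMatrix(df, state="raw")


class TestSignatureScore:
    def test_two_gene_mean(self):
        expr = matrix_from({"A": [2.0], "B": [4.0]})
        sig = ic.GeneSignature("x", ("A", "B"))
        assert ic.signature_score(expr, sig).iloc[0] == 3.0

    def test_single_gene_identity(self):
        expr = matrix_from({"A": [2.0, 5.0], "B": [9.0, 9.0]})
        sig = ic.GeneSignature("x", ("A",))
        np.testing.assert_array_equal(
            ic.signature_score(expr, sig).to_numpy(), [2.0, 5.0])

    def test_matches_loop_oracle(self, rng):
        expr = random_raw_matrix(rng, n_genes=100, n_samples=20)
        genes = tuple(rng.choice(expr.gene_ids, size=30, replace=False))
        score = ic.signature_score(expr, ic.GeneSignature("x", genes))
        for j, s in enumerate(expr.sample_ids):
            total = 0.0
            for g in genes:
                total += expr.values.loc[g, s]
            assert abs(score.loc[s] - total / len(genes)) < 1e-12

    def test_gene_order_permutation_invariant(self, rng):
        expr = random_raw_matrix(rng, n_genes=10, n_samples=5)
        genes = list(expr.gene_ids[:6])
        a = ic.signature_score(expr, ic.GeneSignature("x", tuple(genes)))
        b = ic.signature_score(expr, ic.GeneSignature("x", tuple(genes[::-1])))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_zero_overlap_rejected(self):
        expr = matrix_from({"A": [1.0]})
        with pytest.raises(ValueError, match="no genes"):
            ic.signature_score(expr, ic.GeneSignature("x", ("Z",)))


class TestPercentileClasses:
    def test_linear_interpolation_cutoffs(self):
        score = pd.Series(np.arange(1.0, 11.0))
        classes = ic.percentile_classes(score, hi=70, lo=30)
        # sorting oracle: hi cut = 7.3, lo cut = 3.7 by linear interpolation
        assert (classes[score > 7.3] == "high").all()
        assert (classes[score < 3.7] == "low").all()
        assert (classes[(score >= 3.7) & (score <= 7.3)] == "mid").all()

    def test_constant_vector_all_mid(self):
        classes = ic.percentile_classes(pd.Series([4.0] * 5), hi=70, lo=30)
        assert (classes == "mid").all()

    def test_equal_cutoffs_rejected(self):
        with pytest.raises(ValueError):
            ic.percentile_classes(pd.Series([1.0, 2.0]), hi=50, lo=50)


class TestCytolyticActivity:
    @pytest.mark.parametrize("gzma,prf1,expected", [
        (0.0, 0.0, 0.0),          # pseudocount identity
        (3.0, 3.0, 3.0),          # geometric mean of equal values
        (1.0, 7.0, 3.0),          # sqrt(2*8) - 1
    ])
    def test_closed_form_values(self, gzma, prf1, expected):
        expr = matrix_from({"GZMA": [gzma], "PRF1": [prf1]})
        assert ic.cytolytic_activity(expr).iloc[0] == pytest.approx(
            expected, abs=1e-12)

    def test_scale_equivariance_in_large_value_limit(self):
        expr1 = matrix_from({"GZMA": [1e6], "PRF1": [4e6]})
        expr2 = matrix_from({"GZMA": [2e6], "PRF1": [8e6]})
        cyt1 = ic.cytolytic_activity(expr1).iloc[0]
        cyt2 = ic.cytolytic_activity(expr2).iloc[0]
        assert cyt2 / cyt1 == pytest.approx(2.0, rel=1e-5)

    def test_missing_gene_rejected(self):
        with pytest.raises(ValueError, match="PRF1"):
            ic.cytolytic_activity(matrix_from({"GZMA": [1.0]}))


class TestSubgroupSummary:
    def make_table(self, values):
        table = ic.ScoreTable(sample_ids=[f"S{i}" for i in range(len(values))])
        table.add("score", np.asarray(values, dtype=float))
        return table

    def test_two_point_symmetric_case(self):
        table = self.make_table([0.0, 0.0, 2.0, 2.0])
        groups = pd.Series([1, 1, 2, 2], index=table.sample_ids)
        out = ic.subgroup_summary(table, groups)
        np.testing.assert_allclose(out.loc["score"].to_numpy(), [-1.0, 1.0])

    def test_weighted_sum_is_zero(self, rng):
        table = ic.ScoreTable(sample_ids=[f"S{i}" for i in range(30)])
        table.add("a", rng.normal(size=30))
        table.add("b", rng.uniform(0, 5, size=30))
        groups = pd.Series(rng.choice([1, 2, 3], size=30),
                           index=table.sample_ids)
        out = ic.subgroup_summary(table, groups)
        sizes = groups.value_counts().sort_index().to_numpy()
        for name in ("a", "b"):
            assert abs((out.loc[name].to_numpy() * sizes).sum()) < 1e-9

    def test_matches_loop_oracle(self, rng):
        n = 24
        vals = rng.normal(size=n)
        table = ic.ScoreTable(sample_ids=[f"S{i}" for i in range(n)])
        table.add("score", vals)
        labels = rng.choice([1, 2, 3], size=n)
        groups = pd.Series(labels, index=table.sample_ids)
        out = ic.subgroup_summary(table, groups)
        z = (vals - vals.mean()) / vals.std(ddof=0)
        for lev in (1, 2, 3):
            members = [z[i] for i in range(n) if labels[i] == lev]
            assert abs(out.loc["score", lev] - np.mean(members)) < 1e-12


class TestCompareGroups:
    def test_identical_groups_exact_mannwhitney_p_one(self):
        values = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                           index=list("abcdef"))
        cmp_ = ic.compare_groups(values, ["a", "b", "c"], ["d", "e", "f"],
                                 method="mann_whitney_u")
        assert cmp_.p_value == pytest.approx(1.0)

    def test_fully_separated_triplets_enumeration(self):
        values = pd.Series([1, 2, 3, 4, 5, 6], index=list("abcdef"),
                           dtype=float)
        cmp_ = ic.compare_groups(values, ["a", "b", "c"], ["d", "e", "f"],
                                 method="mann_whitney_u")
        assert cmp_.statistic == 0.0
        assert cmp_.p_value == pytest.approx(2 / 20)

    def test_exact_handles_ties(self):
        u, p = exact_mannwhitney([1.0, 1.0, 2.0], [1.0, 2.0, 2.0])
        assert 0.0 <= p <= 1.0

    def test_label_swap_invariance(self, rng):
        values = pd.Series(rng.normal(size=12),
                           index=[f"S{i}" for i in range(12)])
        a, b = values.index[:5], values.index[5:]
        for method in ("welch_t", "mann_whitney_u"):
            p1 = ic.compare_groups(values, a, b, method=method).p_value
            p2 = ic.compare_groups(values, b, a, method=method).p_value
            assert p1 == pytest.approx(p2, abs=1e-12)

    def test_asymptotic_path_used_for_large_groups(self, rng):
        values = pd.Series(rng.normal(size=20),
                           index=[f"S{i}" for i in range(20)])
        cmp_ = ic.compare_groups(values, values.index[:10], values.index[10:],
                                 method="mann_whitney_u")
        assert 0.0 <= cmp_.p_value <= 1.0

    def test_preconditions(self, rng):
        values = pd.Series(rng.normal(size=6), index=list("abcdef"))
        with pytest.raises(ValueError, match="overlap"):
            ic.compare_groups(values, ["a", "b"], ["b", "c"])
        with pytest.raises(ValueError, match="empty"):
            ic.compare_groups(values, ["a"], [])
        with pytest.raises(ValueError, match=">= 2"):
            ic.compare_groups(values, ["a"], ["b", "c"], method="welch_t")

    def test_pooled_variance_flag(self, rng):
        values = pd.Series(rng.normal(size=10),
                           index=[f"S{i}" for i in range(10)])
        cmp_ = ic.compare_groups(values, values.index[:5], values.index[5:],
                                 pooled_variance=True)
        assert cmp_.statistic_name == "student_t"


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.03, 0.5, 0.8])
    q = benjamini_hochberg(p)
    assert (q >= p - 1e-15).all() and (q <= 1.0).all()
    assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()


class TestFractionTable:
    def test_valid_table_roundtrip(self, tmp_path):
        df = pd.DataFrame({"CD8": [0.2, 0.3], "NK": [0.1, 0.2]},
                          index=pd.Index(["S1", "S2"], name="sample_id"))
        path = tmp_path / "frac.tsv"
        df.to_csv(path, sep="\t")
        out = ic.read_fraction_table(path)
        pd.testing.assert_frame_equal(out, df)

    def test_out_of_range_rows_rejected(self, tmp_path):
        df = pd.DataFrame({"CD8": [0.2, 1.3]},
                          index=pd.Index(["S1", "S2"], name="sample_id"))
        path = tmp_path / "frac.tsv"
        df.to_csv(path, sep="\t")
        with pytest.raises(ValueError, match="S2"):
            ic.read_fraction_table(path)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.01, max_value=100), min_size=3,
                max_size=10, unique=True))
def test_percentile_classes_partition_property(xs):
    classes = ic.percentile_classes(pd.Series(xs), hi=70, lo=30)
    assert set(classes.unique()) <= {"high", "low", "mid"}
    assert len(classes) == len(xs)
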