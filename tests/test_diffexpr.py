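"""Filtering, imputation, normalization and the permutation-FDR t-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hismethyl import synth
from hismethyl.diffexpr import (
    AbundanceMatrix,
    ImputationParams,
    filter_valid,
    impute_downshift,
    log2_transform,
    permutation_fdr_ttest,
    quantile_normalize,
    ttest_s0,
    volcano_table,
)


def matrix_from(values, n_a=3, n_b=3, mode="lfq"):
    samples = [f"a_{i}" for i in range(1, n_a + 1)] + [
        f"b_{i}" for i in range(1, n_b + 1)
    ]
    design = {s: ("condA" if s.startswith("a") else "condB", int(s[-1])) for s in samples}
    data = pd.DataFrame(
        values, columns=samples, index=[f"P{i}" for i in range(len(values))]
    )
    return AbundanceMatrix(data, design, mode)


class TestFilterValid:
    def test_single_observation_per_condition_removed(self):
        m = matrix_from([[1.0, np.nan, np.nan, 2.0, np.nan, np.nan]])
        assert len(filter_valid(m).data) == 0

    def test_fully_observed_kept(self):
        m = matrix_from([[1.0, 2, 3, 4, 5, 6]])
        assert len(filter_valid(m).data) == 1

    def test_matches_row_scan_oracle(self, rng):
        values = rng.uniform(1, 10, size=(1000, 6))
        mask = rng.random((1000, 6)) < 0.45
        values[mask] = np.nan
        m = matrix_from(values)
        kept = set(filter_valid(m).data.index)
        oracle = set()
        for i, row in enumerate(values):
            if (np.sum(~np.isnan(row[:3])) >= 2) or (np.sum(~np.isnan(row[3:])) >= 2):
                oracle.add(f"P{i}")
        assert kept == oracle

    def test_idempotent(self, rng):
        values = rng.uniform(1, 10, size=(200, 6))
        values[rng.random((200, 6)) < 0.5] = np.nan
        m = filter_valid(matrix_from(values))
        assert filter_valid(m).data.equals(m.data)


class TestLog2Transform:
    def test_values_and_missing(self):
        m = matrix_from([[8.0, 1.0, np.nan, 4.0, 2.0, 16.0]])
        out = log2_transform(m).data.iloc[0]
        assert out.iloc[0] == 3.0 and out.iloc[1] == 0.0
        assert np.isnan(out.iloc[2])

    def test_nonpositive_value_named_in_error(self):
        m = matrix_from([[8.0, -1.0, 2.0, 4.0, 2.0, 16.0]])
        with pytest.raises(ValueError, match="P0"):
            log2_transform(m)


class TestImputeDownshift:
    def test_no_missing_is_identity(self):
        m = matrix_from([[8.0, 1.0, 3.0, 4.0, 2.0, 16.0]])
        assert impute_downshift(m).data.equals(m.data)

    def test_observed_cells_never_altered(self, rng):
        values = rng.normal(25, 2, size=(500, 6))
        values[rng.random((500, 6)) < 0.3] = np.nan
        m = matrix_from(values)
        out = impute_downshift(m, ImputationParams(seed=1))
        observed = ~np.isnan(values)
        assert np.array_equal(out.data.to_numpy()[observed], values[observed])
        assert not out.data.isna().any().any()

    def test_moments_match_downshifted_normal(self, rng):
        """Imputed values follow Normal(mean - 1.8 SD, 0.3 SD) per sample."""
        n = 200_000
        observed = rng.normal(25.0, 2.0, n)
        col = np.concatenate([observed, np.full(n, np.nan)])
        values = np.column_stack([col] + [np.full(2 * n, 20.0)] * 5)
        m = matrix_from(values)
        out = impute_downshift(m, ImputationParams(seed=2))
        imputed = out.data.iloc[n:, 0].to_numpy()
        mu, sd = observed.mean(), observed.std(ddof=1)
        assert imputed.mean() == pytest.approx(mu - 1.8 * sd, rel=0.01)
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.01)

    def test_same_seed_identical_output(self, rng):
        values = rng.normal(25, 2, size=(100, 6))
        values[rng.random((100, 6)) < 0.3] = np.nan
        m = matrix_from(values)
        a = impute_downshift(m, ImputationParams(seed=3))
        b = impute_downshift(m, ImputationParams(seed=3))
        assert a.data.equals(b.data)

    def test_sample_with_too_few_observations_rejected(self):
        values = np.array([[np.nan, 2, 3, 4, 5, 6], [np.nan, 2, 3, 4, 5, 6],
                           [1.0, 2, 3, 4, 5, 6]])
        values[2, 0] = np.nan
        with pytest.raises(ValueError, match="fewer than 2"):
            impute_downshift(matrix_from(values))


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = [3.0, 1.0, 2.0]
        m = matrix_from(np.column_stack([col] * 6), mode="tmt")
        out = quantile_normalize(m)
        assert np.allclose(out.data.to_numpy(), m.data.to_numpy())

    def test_hand_example(self):
        m = matrix_from(
            np.column_stack([[1.0, 2, 3]] * 3 + [[4.0, 5, 6]] * 3), mode="tmt"
        )
        out = quantile_normalize(m).data
        for col in out:
            assert list(out[col]) == [2.5, 3.5, 4.5]

    def test_sorted_columns_identical_after(self, rng):
        m = matrix_from(rng.uniform(0, 100, size=(50, 6)), mode="tmt")
        out = quantile_normalize(m).data.to_numpy()
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, 6):
            assert np.allclose(sorted_cols[:, j], sorted_cols[:, 0])

    def test_ranks_preserved_within_columns(self, rng):
        vals = rng.uniform(0, 100, size=(30, 6))
        m = matrix_from(vals, mode="tmt")
        out = quantile_normalize(m).data.to_numpy()
        for j in range(6):
            assert np.array_equal(np.argsort(out[:, j]), np.argsort(vals[:, j]))


class TestTtest:
    def test_s0_zero_matches_hand_computed_t(self, rng):
        a = rng.normal(10, 1, size=(5, 3))
        b = rng.normal(9, 1, size=(5, 3))
        t, p = ttest_s0(a, b, s0=0.0)
        ref = stats.ttest_ind(a, b, axis=1)
        assert np.allclose(t, ref.statistic, atol=1e-10)
        assert np.allclose(p, ref.pvalue, atol=1e-10)

    def test_identical_groups_give_zero_t(self):
        a = np.tile([[5.0, 6.0, 7.0]], (4, 1))
        t, p = ttest_s0(a, a.copy(), s0=0.1)
        assert np.allclose(t, 0.0)


class TestPermutationFdr:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(0)
        base = rng.normal(25, 1, size=(100, 3))
        m = matrix_from(np.hstack([base, base]))
        res = permutation_fdr_ttest(m, ("condA", "condB"), seed=0)
        assert not res.table["significant"].any()

    def test_planted_effect_recovered_with_fdr_control(self):
        m, truth = synth.simulate_abundance_matrix(
            n_proteins=1000, n_upregulated=50, effect_size=2.0, seed=101
        )
        m = impute_downshift(
            log2_transform(filter_valid(m)), ImputationParams(seed=101)
        )
        res = permutation_fdr_ttest(m, ("cellulose", "glucose"), seed=101)
        called = set(
            res.table.index[res.table["significant"] & (res.table["log2fc"] > 0)]
        )
        planted = truth.upregulated_set & set(res.table.index)
        recall = len(called & planted) / len(planted)
        fdr = len(called - truth.upregulated_set) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr <= 0.1

    def test_small_design_warns_and_enumerates(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(25, 1, size=(50, 4)), n_a=2, n_b=2)
        with pytest.warns(UserWarning, match="distinct label assignments"):
            res = permutation_fdr_ttest(m, ("condA", "condB"), seed=1)
        assert res.n_perm_used == 6  # C(4, 2)

    def test_missing_values_rejected(self):
        vals = np.full((3, 6), 25.0)
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            permutation_fdr_ttest(matrix_from(vals), ("condA", "condB"))


class TestVolcanoTable:
    def test_sorted_by_p_with_neg_log10(self):
        rng = np.random.default_rng(2)
        a = rng.normal(25, 1, size=(50, 4))
        b = rng.normal(25, 1, size=(50, 4))
        b[:5] += 3
        m = matrix_from(np.hstack([a, b]), n_a=4, n_b=4)
        res = permutation_fdr_ttest(m, ("condA", "condB"), seed=2)
        v = volcano_table(res)
        assert list(v["p"]) == sorted(v["p"])
        assert np.allclose(v["neg_log10_p"], -np.log10(v["p"]))
        assert v["significant"].sum() <= len(v)
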