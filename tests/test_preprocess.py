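"""Filtering and normalization contracts."""

import numpy as np
import pandas as pd
import pytest

from coexnet import preprocess


def _df(arr, genes=None, samples=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=samples)


class TestCPM:
    def test_definition(self):
        counts = _df([[500], [999500]])
        out = preprocess.cpm(counts)
        assert out.iloc[0, 0] == pytest.approx(500.0)

    def test_two_gene_sample(self):
        out = preprocess.cpm(_df([[30], [70]]))
        assert list(out.iloc[:, 0]) == pytest.approx([300000.0, 700000.0])

    def test_column_sums_are_1e6(self, rng):
        counts = _df(rng.integers(0, 1000, size=(50, 8)) + 1)
        out = preprocess.cpm(counts)
        assert out.sum(axis=0).to_numpy() == pytest.approx(np.full(8, 1e6))

    def test_all_zero_sample_names_offender(self):
        counts = _df([[1, 0], [2, 0]], samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            preprocess.cpm(counts)

    def test_duplicate_gene_rejected(self):
        counts = _df([[1], [2]], genes=["g", "g"])
        with pytest.raises(ValueError, match="duplicate"):
            preprocess.cpm(counts)


class TestLowExpressionFilter:
    def _mat(self, n_low: int):
        """One gene low (CPM < 1) in exactly n_low of 14 samples."""
        lib = 1_000_000
        row = [0] * n_low + [10] * (14 - n_low)
        filler = [lib] * 14
        return _df([row, filler], genes=["probe", "filler"])

    def test_boundary_12_of_14_removed(self):
        # ceil(0.8 * 14) = 12 low samples trigger removal
        out = preprocess.filter_low_expression(self._mat(12))
        assert "probe" not in out.index

    def test_boundary_11_of_14_kept(self):
        out = preprocess.filter_low_expression(self._mat(11))
        assert "probe" in out.index

    def test_all_zero_gene_removed(self):
        out = preprocess.filter_low_expression(self._mat(14))
        assert list(out.index) == ["filler"]

    def test_high_everywhere_kept_order_preserved(self):
        counts = _df([[100] * 5, [200] * 5, [300] * 5], genes=["a", "b", "c"])
        out = preprocess.filter_low_expression(counts)
        assert list(out.index) == ["a", "b", "c"]

    def test_bad_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            preprocess.filter_low_expression(self._mat(0), fraction=0.0)

    def test_idempotent(self, rng):
        counts = _df(rng.integers(0, 50, size=(60, 14)))
        counts = counts.loc[counts.sum(axis=1) > 0]
        once = preprocess.filter_low_expression(counts)
        twice = preprocess.filter_low_expression(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSizeFactors:
    def test_doubled_sample(self, rng):
        base = rng.integers(10, 1000, size=(200, 1))
        counts = _df(np.hstack([base, base * 2]), samples=["A", "B"])
        sf = preprocess.estimate_size_factors(counts)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2))
        assert sf["B"] == pytest.approx(np.sqrt(2))

    def test_hand_toy_median_of_ratios(self):
        # 5 genes, 2 samples; ratios to the geometric-mean reference worked
        # out by hand: sample ratios are (c1/sqrt(c1*c2), c2/sqrt(c1*c2)) per
        # gene, i.e. sqrt(c1/c2) and sqrt(c2/c1); medians over genes below.
        c1 = np.array([100, 200, 400, 800, 1600])
        c2 = np.array([400, 200, 400, 200, 1600])
        counts = _df(np.column_stack([c1, c2]), samples=["s1", "s2"])
        ratios1 = np.sqrt(c1 / c2)  # [0.5, 1, 1, 2, 1]
        ratios2 = np.sqrt(c2 / c1)
        exp1, exp2 = np.median(ratios1), np.median(ratios2)
        geo = np.sqrt(exp1 * exp2)
        sf = preprocess.estimate_size_factors(counts)
        assert sf["s1"] == pytest.approx(exp1 / geo)
        assert sf["s2"] == pytest.approx(exp2 / geo)

    def test_identical_samples(self):
        counts = _df(np.tile([[10], [20], [30]], (1, 4)))
        sf = preprocess.estimate_size_factors(counts)
        assert sf.to_numpy() == pytest.approx(np.ones(4))

    def test_single_sample(self):
        sf = preprocess.estimate_size_factors(_df([[5], [10]]))
        assert sf.to_numpy() == pytest.approx([1.0])

    def test_no_common_gene_errors(self):
        counts = _df([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="filter"):
            preprocess.estimate_size_factors(counts)


class TestVST:
    def test_zero_count_maps_to_zero(self):
        out = preprocess.vst_transform(_df([[0, 7]]), pd.Series([1.0, 1.0], index=["s0", "s1"]))
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(3.0)  # log2(8)

    def test_doubling_sf_halves_prelog(self):
        counts = _df([[8, 8]])
        one = preprocess.vst_transform(counts, pd.Series([1.0, 1.0], index=["s0", "s1"]))
        two = preprocess.vst_transform(counts, pd.Series([2.0, 2.0], index=["s0", "s1"]))
        assert 2 ** two.iloc[0, 0] - 1 == pytest.approx((2 ** one.iloc[0, 0] - 1) / 2)

    def test_monotone_in_counts(self, rng):
        counts = _df(np.sort(rng.integers(0, 500, size=(20, 1)), axis=0))
        out = preprocess.vst_transform(counts, pd.Series([1.0], index=["s0"]))
        assert (np.diff(out.to_numpy()[:, 0]) >= 0).all()


class TestDispersionFilter:
    def test_ordered_cvs_exact_removal(self, rng):
        # 10 genes with strictly increasing CV: quantile 0.2 removes the 2 smallest
        rows = []
        for i in range(10):
            base = 100.0
            noise = np.linspace(-1, 1, 8) * (i + 1)
            rows.append(base + noise)
        norm = _df(np.array(rows))
        out = preprocess.filter_low_dispersion(norm, 0.2)
        assert list(out.index) == [f"g{i}" for i in range(2, 10)]

    def test_constant_gene_removed(self, rng):
        arr = rng.normal(10, 2, size=(9, 6))
        arr = np.vstack([arr, np.full(6, 10.0)])
        out = preprocess.filter_low_dispersion(_df(arr), 0.2)
        assert "g9" not in out.index

    def test_quantile_zero_identity(self, rng):
        norm = _df(rng.normal(10, 1, size=(10, 5)))
        pd.testing.assert_frame_equal(preprocess.filter_low_dispersion(norm, 0.0), norm)

    def test_constant_matrix_warns_removes_none(self):
        norm = _df(np.full((6, 4), 3.0))
        with pytest.warns(UserWarning, match="tie"):
            out = preprocess.filter_low_dispersion(norm, 0.2)
        assert out.shape == norm.shape


class TestCovariateAdjustment:
    @staticmethod
    def _meta(n, sexes):
        return pd.DataFrame({"tissue": ["t"] * n, "condition": ["CON"] * n,
                             "sex": sexes}, index=[f"s{i}" for i in range(n)])

    def test_pure_sex_effect_removed(self):
        sexes = ["M", "F"] * 3
        norm = _df([[1.0 if s == "M" else 0.0 for s in sexes]])
        out = preprocess.adjust_covariate(norm, self._meta(6, sexes))
        male = out.iloc[0, ::2].mean()
        female = out.iloc[0, 1::2].mean()
        assert male == pytest.approx(female)
        assert out.iloc[0].mean() == pytest.approx(0.5)  # grand mean restored

    def test_orthogonal_covariate_noop(self, rng):
        sexes = ["M", "F"] * 10
        # each adjacent M/F pair shares a value, so sex group means are equal
        vals = np.repeat(rng.normal(5, 1, size=(4, 10)), 2, axis=1)
        norm = _df(vals)
        out = preprocess.adjust_covariate(norm, self._meta(20, sexes))
        assert np.allclose(out.to_numpy(), norm.to_numpy())

    def test_planted_effect_recovered_then_removed(self, rng):
        n = 42
        sexes = (["M", "F"] * 21)
        male = np.array([s == "M" for s in sexes], dtype=float)
        effect = 0.5
        norm = _df(rng.normal(8, 1, size=(30, n)) + effect * male)
        # OLS oracle: the fitted group-mean difference estimates the effect
        est = (norm.to_numpy()[:, male == 1].mean(axis=1)
               - norm.to_numpy()[:, male == 0].mean(axis=1))
        # averaged over the 30 fixture genes the OLS estimate pins the effect
        assert abs(est.mean() - effect) < 0.1
        out = preprocess.adjust_covariate(norm, self._meta(n, sexes))
        diff = (out.to_numpy()[:, male == 1].mean(axis=1)
                - out.to_numpy()[:, male == 0].mean(axis=1))
        assert np.abs(diff).max() < 1e-10

    def test_single_level_warns(self, rng):
        norm = _df(rng.normal(size=(3, 4)))
        with pytest.warns(UserWarning, match="single level"):
            out = preprocess.adjust_covariate(norm, self._meta(4, ["M"] * 4))
        pd.testing.assert_frame_equal(out, norm)


def test_normalize_counts_strategies(small_dataset):
    counts, metadata, _ = small_dataset
    pooled = preprocess.normalize_counts(counts, metadata, strategy="pooled")
    per_t = preprocess.normalize_counts(counts, metadata, strategy="per-tissue")
    assert set(pooled) == {"pooled"}
    assert set(per_t) == set(metadata["tissue"])
    for nm in per_t.values():
        assert np.isfinite(nm.data.to_numpy()).all()
        assert set(nm.data.index) <= set(counts.index)
        # per-tissue adds the dispersion filter
        assert any("dispersion" in f for f in nm.filters)
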