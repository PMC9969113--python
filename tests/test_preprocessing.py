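"""Preprocessing tests: size factors, VST, MAD filter, UQ normalization, ComBat."""

import numpy as np
import pandas as pd
import pytest

from eoclines.preprocessing import (
    ComBat,
    MADFilter,
    MedianRatioVST,
    UpperQuartileNormalizer,
    combat_adjust,
    mad_filter,
    size_factors,
    upper_quartile_normalize,
    vst_transform,
)


def _df(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=samples)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = _df([[5, 5], [9, 9], [2, 2]])
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_scale_equivariance(self):
        counts = _df([[5, 10], [9, 18], [2, 4]])
        f = size_factors(counts)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)

    def test_hand_computed_toy_matrix(self):
        # geometric means: sqrt(8)=2.828, sqrt(128)=11.314, 2; medians of
        # ratios: (1/sqrt2, 1/sqrt2, 1) -> 1/sqrt2 and (sqrt2, sqrt2, 1) -> sqrt2
        counts = _df([[2, 4], [8, 16], [2, 2]])
        np.testing.assert_allclose(
            size_factors(counts), [2**-0.5, 2**0.5], rtol=1e-12
        )

    def test_no_universally_expressed_gene_advises_pseudocount(self):
        counts = _df([[0, 4], [8, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)
        assert (size_factors(counts, pseudocount=0.5) > 0).all()


class TestVST:
    def test_zero_count_maps_to_zero_and_known_value(self):
        counts = _df([[0, 7]])
        factors = pd.Series([1.0, 1.0], index=counts.columns)
        out = vst_transform(counts, factors)
        assert out.iloc[0, 0] == 0.0
        assert out.iloc[0, 1] == pytest.approx(3.0)  # log2(8)

    def test_variance_stabilization_across_scales(self):
        # overdispersed counts (the data this surrogate targets): log2(x+1)
        # variance ~ dispersion / ln(2)^2, nearly flat in the mean, whereas
        # raw count variance spans 4+ orders of magnitude across these means
        rng = np.random.default_rng(0)
        alpha = 0.1
        frames = []
        for mu in (10, 100, 1000):
            n = 1 / alpha
            frames.append(rng.negative_binomial(n, n / (n + mu), size=(400, 30)))
        counts = _df(np.vstack(frames))
        out = vst_transform(counts, pd.Series(1.0, index=counts.columns))
        variances = out.var(axis=1).to_numpy()
        means = [variances[i * 400:(i + 1) * 400].mean() for i in range(3)]
        assert max(means) / min(means) < 10  # < one order of magnitude

    def test_shape_and_ids_preserved(self):
        counts = _df(np.arange(12).reshape(3, 4))
        out = vst_transform(counts)
        assert out.shape == counts.shape
        assert list(out.index) == list(counts.index)
        assert out.attrs["transforms"] == ["vst"]


class TestMADFilter:
    def test_constant_gene_excluded_at_default_threshold(self):
        expr = _df([[1.0, 1.0, 1.0], [0.0, 5.0, 10.0]])
        result = mad_filter(expr, threshold=1.5)
        assert result.kept_gene_ids == ["g1"]
        assert result.mad_values["g0"] == 0.0

    def test_hand_computed_outlier_row_is_excluded(self):
        # (1,2,3,4,100): median 3, abs devs (2,1,0,1,97), MAD 1*1.4826 < 1.5
        expr = _df([[1.0, 2.0, 3.0, 4.0, 100.0]])
        result = mad_filter(expr, threshold=1.5)
        assert result.mad_values["g0"] == pytest.approx(1.4826)
        assert result.kept_gene_ids == []

    def test_zero_threshold_keeps_all_genes(self):
        rng = np.random.default_rng(1)
        expr = _df(rng.normal(size=(20, 5)))
        assert len(mad_filter(expr, threshold=0.0).kept_gene_ids) == 20

    def test_kept_set_non_increasing_in_threshold_and_order_invariant(self):
        rng = np.random.default_rng(2)
        expr = _df(rng.normal(size=(50, 8)))
        sizes = [
            len(mad_filter(expr, threshold=t).kept_gene_ids)
            for t in (0.0, 0.5, 1.0, 1.5)
        ]
        assert sizes == sorted(sizes, reverse=True)
        shuffled = expr[list(expr.columns[::-1])]
        assert (
            mad_filter(expr, threshold=0.8).kept_gene_ids
            == mad_filter(shuffled, threshold=0.8).kept_gene_ids
        )

    def test_requires_two_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            mad_filter(_df([[1.0]]))

    def test_top_n_selection(self):
        rng = np.random.default_rng(3)
        expr = _df(rng.normal(size=(30, 6)))
        result = mad_filter(expr, top_n=10)
        assert len(result.kept_gene_ids) == 10
        kept_mads = result.mad_values[result.kept_gene_ids]
        dropped = result.mad_values.drop(result.kept_gene_ids)
        assert kept_mads.min() >= dropped.max()


class TestUpperQuartile:
    def test_identical_and_scaled_samples_normalize_equal(self):
        counts = _df([[2, 6], [4, 12], [6, 18], [8, 24]])
        out = upper_quartile_normalize(counts)
        np.testing.assert_allclose(out.iloc[:, 0], out.iloc[:, 1])

    def test_hand_computed_type7_quantile(self):
        # nonzero counts (2,4,6,8): type-7 75th percentile = 6.5
        counts = _df([[2], [4], [6], [8], [0]])
        out = upper_quartile_normalize(counts)
        np.testing.assert_allclose(
            out.iloc[:, 0], np.array([2, 4, 6, 8, 0]) / 6.5 * 6.5
        )

    def test_all_zero_sample_is_rejected_by_name(self):
        counts = _df([[1, 0], [2, 0]], samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            upper_quartile_normalize(counts)


class TestComBat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(4)
        expr = _df(rng.normal(5, 1, size=(40, 10)))
        out = combat_adjust(expr, np.array(["a"] * 10))
        np.testing.assert_allclose(out.to_numpy(), expr.to_numpy(), atol=1e-10)

    def test_constant_shift_between_batches_is_removed(self):
        rng = np.random.default_rng(5)
        n, delta = 50, 3.0
        base = rng.normal(6, 1, size=(200, 2 * n))
        base[:, n:] += delta
        expr = _df(base)
        batches = np.array(["a"] * n + ["b"] * n)
        out = combat_adjust(expr, batches).to_numpy()
        residual = np.abs(out[:, n:].mean(axis=1) - out[:, :n].mean(axis=1))
        assert (residual / delta).mean() < 0.05

    def test_heterogeneous_shifts_strictly_decrease_batch_distance(self):
        rng = np.random.default_rng(15)
        n = 40
        delta = rng.uniform(0.5, 3.0, size=150)
        base = rng.normal(6, 1, size=(150, 2 * n))
        base[:, n:] += delta[:, None]
        expr = _df(base)
        batches = np.array(["a"] * n + ["b"] * n)
        out = combat_adjust(expr, batches).to_numpy()
        before = np.abs(base[:, n:].mean(axis=1) - base[:, :n].mean(axis=1)).mean()
        after = np.abs(out[:, n:].mean(axis=1) - out[:, :n].mean(axis=1)).mean()
        assert after < before * 0.2

    def test_label_order_invariance(self):
        rng = np.random.default_rng(6)
        expr = _df(rng.normal(size=(30, 12)))
        batches = np.array(["a", "b"] * 6)
        out1 = combat_adjust(expr, batches)
        # permuting sample order within batches then restoring it
        perm = np.concatenate([np.arange(0, 12, 2)[::-1], np.arange(1, 12, 2)[::-1]])
        expr_p = expr.iloc[:, perm]
        out2 = combat_adjust(expr_p, batches[perm])[expr.columns]
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), atol=1e-8)

    def test_singleton_batch_is_rejected(self):
        expr = _df(np.random.default_rng(7).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="singleton"):
            combat_adjust(expr, np.array(["a", "a", "a", "a", "b"]))

    def test_zero_variance_gene_passes_through_with_warning(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(10, 8))
        values[3] = 2.5
        expr = _df(values)
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            out = combat_adjust(expr, np.array(["a"] * 4 + ["b"] * 4))
        np.testing.assert_allclose(out.iloc[3], 2.5)

    def test_grand_mean_preserved_and_finite(self):
        rng = np.random.default_rng(9)
        expr = _df(rng.normal(3, 2, size=(60, 20)))
        batches = np.array(["a"] * 7 + ["b"] * 6 + ["c"] * 7)
        out = combat_adjust(expr, batches)
        assert np.isfinite(out.to_numpy()).all()
        np.testing.assert_allclose(
            out.mean(axis=1), expr.mean(axis=1), atol=0.2
        )


class TestEstimators:
    """The sklearn-facing wrappers agree with the functional surface."""

    def test_vst_estimator_matches_function(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(50, size=(15, 80))  # samples x genes
        df = _df(counts.T)
        expected = vst_transform(df).to_numpy().T
        got = MedianRatioVST().fit_transform(counts)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_mad_estimator_selects_same_genes(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 40))
        est = MADFilter(top_n=10).fit(X)
        result = mad_filter(_df(X.T), top_n=10)
        expected_mask = np.zeros(40, dtype=bool)
        expected_mask[[int(g[1:]) for g in result.kept_gene_ids]] = True
        np.testing.assert_array_equal(est.get_support(), expected_mask)
        assert est.transform(X).shape == (12, 10)

    def test_uq_estimator_matches_function(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(30, size=(8, 50))
        expected = upper_quartile_normalize(_df(counts.T)).to_numpy().T
        got = UpperQuartileNormalizer().fit_transform(counts)
        np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_combat_estimator_matches_function(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(16, 30))
        batch = np.array(["a"] * 8 + ["b"] * 8)
        expected = combat_adjust(_df(X.T), batch).to_numpy().T
        got = ComBat().fit_transform(X, batch=batch)
        np.testing.assert_allclose(got, expected, rtol=1e-8)

    def test_sklearn_pipeline_composition(self):
        from sklearn.pipeline import Pipeline

        rng = np.random.default_rng(14)
        counts = rng.poisson(40, size=(10, 60))
        pipe = Pipeline(
            [("vst", MedianRatioVST()), ("mad", MADFilter(top_n=15))]
        )
        out = pipe.fit_transform(counts)
        assert out.shape == (10, 15)
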