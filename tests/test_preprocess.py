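"""Preparation chain: sparsity filter, trim, masked-NNMF imputation,
agglomeration, scaling, transform selection, target construction, SMOTEENN
resampling and univariate odds ratios."""

import numpy as np
import pandas as pd
import pytest

from evoselect import (
    SMOTEENN,
    BinaryTarget,
    MaskedNNMFImputer,
    TabularPreparer,
    agglomerate_items,
    binarize_target,
    drop_sparse_features,
    impute_nnmf,
    scale_minmax,
    select_normalizing_transform,
    trim_outliers,
    univariate_odds_ratio,
)

from conftest import make_table


class TestSparseFilter:
    def test_feature_above_threshold_dropped_at_exact_kept(self):
        n = 100
        vals = np.random.default_rng(0).normal(size=(n, 3))
        vals[:41, 0] = np.nan  # 41% missing -> dropped
        vals[:40, 1] = np.nan  # exactly 40% -> kept
        out = drop_sparse_features(make_table(vals), max_missing=0.40)
        assert list(out.feature_names) == ["f1", "f2"]

    def test_fully_observed_table_unchanged(self):
        vals = np.random.default_rng(1).normal(size=(20, 4))
        table = make_table(vals)
        out = drop_sparse_features(table)
        assert out.shape == table.shape

    def test_grid_of_missing_rates_keeps_five_of_ten(self):
        n = 100
        vals = np.random.default_rng(2).normal(size=(n, 10))
        for j in range(10):
            vals[: int(n * j / 10), j] = np.nan
        out = drop_sparse_features(make_table(vals), max_missing=0.40)
        assert out.shape[1] == 5

    def test_dropping_everything_is_an_error(self):
        vals = np.full((10, 2), np.nan)
        vals[0] = 1.0  # 90% missing everywhere
        with pytest.raises(ValueError):
            drop_sparse_features(make_table(vals), max_missing=0.40)


class TestTrimOutliers:
    def test_values_within_bounds_are_identity(self):
        # {0,0,0,0,100}: mean 20, sample sd ~44.7 -> bound ~154, no clipping
        vals = np.array([[0.0], [0.0], [0.0], [0.0], [100.0]])
        out = trim_outliers(make_table(vals))
        np.testing.assert_array_equal(out.values.to_numpy(), vals)

    def test_extreme_value_clipped_to_mean_plus_3sd(self):
        col = np.array([0.0] * 11 + [100.0])
        vals = col.reshape(-1, 1)
        out = trim_outliers(make_table(vals))
        mu, sd = col.mean(), col.std(ddof=1)
        expected = col.copy()
        expected[-1] = mu + 3 * sd  # hand oracle: ~94.9 < 100
        assert expected[-1] < 100
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], expected)

    def test_constant_column_untouched_with_warning(self):
        vals = np.full((10, 1), 7.0)
        with pytest.warns(UserWarning, match="zero variance"):
            out = trim_outliers(make_table(vals))
        np.testing.assert_array_equal(out.values.to_numpy(), vals)


class TestMaskedNNMF:
    def test_no_missing_cells_is_identity(self):
        vals = np.abs(np.random.default_rng(3).normal(size=(30, 5)))
        table = make_table(vals)
        out = impute_nnmf(table, rank=2, seed=0)
        np.testing.assert_array_equal(out.values.to_numpy(), vals)

    def _rank2_problem(self, seed):
        rng = np.random.default_rng(seed)
        W = np.abs(rng.normal(size=(200, 2)))
        H = np.abs(rng.normal(size=(2, 30)))
        truth = W @ H
        mask = rng.uniform(size=truth.shape) >= 0.2
        vals = np.where(mask, truth, np.nan)
        return truth, vals, mask

    def test_beats_column_mean_imputation_on_low_rank_data(self):
        truth, vals, mask = self._rank2_problem(4)
        out = impute_nnmf(make_table(vals, mask), rank=2, max_iter=300, seed=0)
        est = out.values.to_numpy()
        miss = ~mask
        rmse = np.sqrt(np.mean((est[miss] - truth[miss]) ** 2))
        col_means = np.nanmean(vals, axis=0)
        mean_fill = np.broadcast_to(col_means, truth.shape)
        rmse_mean = np.sqrt(np.mean((mean_fill[miss] - truth[miss]) ** 2))
        assert rmse < rmse_mean

    def test_observed_cells_bit_identical(self):
        truth, vals, mask = self._rank2_problem(5)
        table = make_table(vals, mask)
        out = impute_nnmf(table, rank=2, seed=1)
        assert (out.values.to_numpy()[mask] == vals[mask]).all()
        # and nothing is left missing
        assert np.isfinite(out.values.to_numpy()).all()

    def test_masked_objective_non_increasing(self):
        _, vals, mask = self._rank2_problem(6)
        imp = MaskedNNMFImputer(rank=2, max_iter=100, seed=2)
        imp.fit(make_table(vals, mask))
        trace = np.asarray(imp.objective_trace_)
        assert (np.diff(trace) <= 1e-8 * np.maximum(trace[:-1], 1)).all()

    def test_negative_values_roundtrip_through_offset(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(loc=-5, size=(50, 6))
        mask = rng.uniform(size=vals.shape) >= 0.1
        table = make_table(np.where(mask, vals, np.nan), mask)
        out = impute_nnmf(table, rank=2, seed=0)
        assert (out.values.to_numpy()[mask] == vals[mask]).all()


class TestAgglomeration:
    def test_single_column_returned_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = agglomerate_items(df)
        np.testing.assert_array_equal(out.to_numpy(), df["a"].to_numpy())

    def test_duplicate_columns_pool_to_the_column(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        df = pd.DataFrame({"a": x, "b": x})
        out = agglomerate_items(df)
        np.testing.assert_allclose(out.to_numpy(), x)

    def test_three_columns_pool_to_leaf_mean(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        y = rng.normal(size=20) * 3 + 1
        df = pd.DataFrame({"a": x, "b": x, "c": y})
        out = agglomerate_items(df)
        # merge tree: (a,b) then ((a,b),c); size-weighted pooling = leaf mean
        np.testing.assert_allclose(out.to_numpy(), (x + x + y) / 3)


class TestScaleMinMax:
    def test_affine_map_to_unit_interval(self):
        tr = make_table(np.array([[2.0], [4.0], [6.0]]))
        out = scale_minmax(tr)
        np.testing.assert_allclose(out.values.to_numpy()[:, 0], [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        tr = make_table(np.full((4, 1), 3.0))
        with pytest.warns(UserWarning, match="constant"):
            out = scale_minmax(tr)
        np.testing.assert_array_equal(out.values.to_numpy(), np.zeros((4, 1)))

    def test_test_partition_may_leave_unit_interval(self):
        tr = make_table(np.array([[0.0], [10.0]]))
        te = make_table(np.array([[20.0]]))
        tr_s, te_s = scale_minmax(tr, te)
        assert te_s.values.iloc[0, 0] == 2.0  # preserved, not clipped
        assert tr_s.values.to_numpy().min() == 0 and tr_s.values.to_numpy().max() == 1


class TestTransformSelection:
    def test_normal_sample_left_untransformed(self):
        x = pd.Series(np.random.default_rng(9).normal(size=300), name="x")
        _, rep = select_normalizing_transform(x)
        assert rep.chosen == "none"

    def test_lognormal_sample_gets_a_transform_that_improves(self):
        x = pd.Series(np.exp(np.random.default_rng(10).normal(size=300)), name="x")
        _, rep = select_normalizing_transform(x)
        assert rep.chosen in {"power", "quantile"}
        assert rep.stat_after < rep.stat_before

    def test_constant_column_is_identity_with_warning(self):
        x = pd.Series(np.full(50, 2.0), name="x")
        with pytest.warns(UserWarning, match="constant"):
            out, rep = select_normalizing_transform(x)
        assert rep.chosen == "none"
        np.testing.assert_array_equal(out.to_numpy(), x.to_numpy())


class TestBinarizeTarget:
    def test_zero_score_is_not_case_positive_is_case(self):
        items = pd.DataFrame(
            {
                "i1": [0.0, 0.0, 2.0, 1.0],
                "i2": [0.0, 3.0, 0.0, 1.0],
                "i3": [0.0, 0.0, 0.0, 4.0],
            }
        )
        target = binarize_target(items)
        # hand enumeration: subject 0 all-zero -> 0; others have a positive item
        assert list(target.labels) == [0, 1, 1, 1]
        assert target.source_items == ["i1", "i2", "i3"]

    def test_negative_items_rejected(self):
        with pytest.raises(ValueError):
            binarize_target(pd.DataFrame({"i": [-1.0, 2.0]}))

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning, match="single-class"):
            binarize_target(pd.DataFrame({"i": [1.0, 2.0]}))


class TestSMOTEENN:
    def _imbalanced(self, seed, n=300, rate=0.12):
        rng = np.random.default_rng(seed)
        n1 = int(n * rate)
        X = np.vstack(
            [
                rng.normal(0, 1, size=(n - n1, 4)),
                rng.normal(1.5, 1, size=(n1, 4)),
            ]
        )
        y = np.array([0] * (n - n1) + [1] * n1)
        return X, y

    def test_labels_stay_binary_and_minority_rate_increases(self):
        X, y = self._imbalanced(11)
        sampler = SMOTEENN(seed=0)
        Xr, yr = sampler.fit_resample(X, y)
        assert set(np.unique(yr)) <= {0, 1}
        assert (yr == 1).mean() > (y == 1).mean()

    def test_synthetic_rows_lie_on_minority_segments(self):
        X, y = self._imbalanced(12)
        sampler = SMOTEENN(seed=1)
        Xr, yr = sampler.fit_resample(X, y)
        Xmin = X[y == 1]
        kept_synth = Xr[sampler.synthetic_mask_]
        kept_idx = np.flatnonzero(sampler.synthetic_mask_)
        # match each kept synthetic row back to its generating pair
        orig_kept = int(sampler.kept_original_mask_.sum())
        synth_rows = Xr[orig_kept:]
        prov = sampler.synthetic_provenance_
        all_synth = np.array(
            [Xmin[i] + g * (Xmin[j] - Xmin[i]) for i, j, g in prov]
        )
        for row in synth_rows:
            # geometric check: distance to the nearest generating segment
            d = np.abs(all_synth - row).sum(axis=1)
            t = int(np.argmin(d))
            i, j, g = prov[t]
            a, b = Xmin[i], Xmin[j]
            ab = b - a
            denom = float(ab @ ab)
            lam = 0.0 if denom == 0 else float((row - a) @ ab) / denom
            assert -1e-8 <= lam <= 1 + 1e-8
            proj = a + np.clip(lam, 0, 1) * ab
            assert np.linalg.norm(row - proj) < 1e-8

    def test_surviving_majority_rows_are_original_rows(self):
        X, y = self._imbalanced(13)
        sampler = SMOTEENN(seed=2)
        Xr, yr = sampler.fit_resample(X, y)
        orig_kept = sampler.kept_original_mask_
        kept_rows = Xr[: orig_kept.sum()]
        np.testing.assert_array_equal(kept_rows, X[orig_kept])

    def test_tiny_minority_reduces_k_with_warning(self):
        X, y = self._imbalanced(14, n=60, rate=0.06)  # 3 minority points
        with pytest.warns(UserWarning, match="reducing SMOTE k"):
            SMOTEENN(seed=3).fit_resample(X, y)


class TestUnivariateOddsRatio:
    def test_two_by_two_cross_product(self):
        # a=10 exposed cases, b=5 exposed non-cases, c=5, d=10 -> OR 4
        x = np.array([1] * 15 + [0] * 15, dtype=float)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10)
        res = univariate_odds_ratio(x, y)
        assert res["or"] == pytest.approx(4.0, rel=1e-4)
        assert res["ci"][0] < 4.0 < res["ci"][1]

    def test_negating_the_feature_inverts_the_odds_ratio(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-x))).astype(int)
        a = univariate_odds_ratio(x, y)
        b = univariate_odds_ratio(-x, y)
        assert a["or"] == pytest.approx(1 / b["or"], rel=1e-6)

    def test_wald_interval_covers_null_under_independence(self):
        rng = np.random.default_rng(16)
        covered = 0
        for _ in range(100):
            x = rng.normal(size=200)
            y = rng.integers(0, 2, size=200)
            res = univariate_odds_ratio(x, y)
            covered += res["ci"][0] <= 1.0 <= res["ci"][1]
        assert covered >= 90

    def test_perfect_separation_flagged(self):
        x = np.array([0.0] * 10 + [1.0] * 10)
        y = np.array([0] * 10 + [1] * 10)
        res = univariate_odds_ratio(x, y)
        assert res["diverged"]


class TestPipelineHygiene:
    def _cohortlike(self, seed, n=150, p=12):
        rng = np.random.default_rng(seed)
        vals = np.exp(rng.normal(size=(n, p)) * 0.8)
        mask = rng.uniform(size=vals.shape) >= 0.15
        return make_table(np.where(mask, vals, np.nan), mask)

    def test_test_partition_cannot_poison_fitted_parameters(self):
        import pickle

        train = self._cohortlike(17)
        test = self._cohortlike(18, n=60)
        prep = TabularPreparer(nnmf_rank=3, seed=0).fit(train)
        frozen = pickle.dumps(
            (
                prep.filter_.retained_,
                prep.imputer_.H_,
                prep.imputer_.offset_,
                prep.scaler_.scaler_.data_min_,
                prep.scaler_.scaler_.data_range_,
                prep.transformer_.transforms_,
            )
        )
        train_out = prep.train_prepared_.values.copy()

        _ = prep.transform(test)
        poisoned = test.copy()
        poisoned.values.iloc[:, :] = poisoned.values.to_numpy() * 100 + 7
        _ = prep.transform(poisoned)

        refrozen = pickle.dumps(
            (
                prep.filter_.retained_,
                prep.imputer_.H_,
                prep.imputer_.offset_,
                prep.scaler_.scaler_.data_min_,
                prep.scaler_.scaler_.data_range_,
                prep.transformer_.transforms_,
            )
        )
        assert frozen == refrozen
        assert train_out.equals(prep.train_prepared_.values)

    def test_train_output_is_complete_and_in_unit_interval_before_transform(self):
        train = self._cohortlike(19)
        prep = TabularPreparer(nnmf_rank=3, seed=1).fit(train)
        out = prep.train_prepared_
        assert np.isfinite(out.values.to_numpy()).all()
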