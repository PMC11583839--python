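import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabopipe import (
    filter_noise,
    impute_knn,
    integrate_batches,
    median_qc_rsd,
    missing_profile,
    normalize_svr_qc,
    simulate_dataset,
    triage_outliers,
)
from metabopipe.errors import ParameterError

from conftest import make_dataset


def _qc_groups(n_subj, n_qc, n_groups=2):
    classes = ["Subject"] * n_subj + ["QC"] * n_qc
    groups = [f"g{(i % n_groups) + 1}" for i in range(n_subj)] + ["QC"] * n_qc
    return classes, groups


class TestMissingProfile:
    def test_one_of_four_qc_missing_is_quarter(self):
        classes, groups = _qc_groups(4, 4)
        X = np.ones((3, 8))
        X[0, 4] = np.nan  # first QC sample
        ds = make_dataset(X, classes=classes, groups=groups)
        prof = missing_profile(ds)
        assert prof.per_feature_qc_rate["F1"] == pytest.approx(0.25)
        assert prof.per_feature_qc_rate["F2"] == 0.0

    def test_fully_observed_all_zero(self, clean_dataset):
        prof = missing_profile(clean_dataset)
        assert (prof.per_feature_qc_rate == 0).all()
        assert (prof.per_feature_group_rates == 0).all().all()
        assert (prof.per_sample_rate == 0).all()

    def test_random_mask_matches_brute_force_recount(self):
        rng = np.random.default_rng(11)
        classes, groups = _qc_groups(10, 4, n_groups=3)
        X = rng.uniform(1, 10, size=(25, 14))
        X[rng.uniform(size=X.shape) < 0.3] = np.nan
        ds = make_dataset(X, classes=classes, groups=groups)
        prof = missing_profile(ds)
        # brute force: recount every denominator by hand
        for i, fid in enumerate(ds.feature_ids):
            qc_idx = [j for j, c in enumerate(classes) if c == "QC"]
            expect = np.mean([np.isnan(X[i, j]) for j in qc_idx])
            assert prof.per_feature_qc_rate[fid] == pytest.approx(expect)
            for g in set(groups) - {"QC"}:
                idx = [j for j, (c, gg) in enumerate(zip(classes, groups))
                       if c == "Subject" and gg == g]
                expect = np.mean([np.isnan(X[i, j]) for j in idx])
                assert prof.per_feature_group_rates.loc[fid, g] == pytest.approx(expect)


class TestFilterNoise:
    def _dataset(self):
        classes, groups = _qc_groups(8, 4)
        X = np.ones((4, 12)) * 100.0
        # F1: half missing in QC -> removed
        X[0, 8:10] = np.nan
        # F2: fully observed in g1, fully missing in g2 -> retained
        X[1, [1, 3, 5, 7]] = np.nan
        # F3: >20% missing in *every* group -> removed
        X[2, 0:8] = np.nan
        X[2, 0] = 100.0
        # F4: clean -> retained
        return make_dataset(X, classes=classes, groups=groups)

    def test_qc_rate_above_threshold_removed(self):
        out = filter_noise(self._dataset())
        assert "F1" not in out.feature_ids

    def test_detected_in_one_group_retained(self):
        out = filter_noise(self._dataset())
        assert "F2" in out.feature_ids

    def test_missing_in_every_group_removed(self):
        out = filter_noise(self._dataset())
        assert "F3" not in out.feature_ids and "F4" in out.feature_ids

    def test_boundary_rate_equal_threshold_retained(self):
        # exactly 20% missing in QC (1 of 5) must be kept ("more than" is strict)
        classes = ["Subject"] * 4 + ["QC"] * 5
        groups = ["g1"] * 4 + ["QC"] * 5
        X = np.ones((2, 9))
        X[0, 4] = np.nan
        ds = make_dataset(X, classes=classes, groups=groups)
        assert "F1" in filter_noise(ds, qc_thresh=0.2).feature_ids

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            filter_noise(self._dataset(), qc_thresh=1.5)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0.0, 1.0), t2=st.floats(0.0, 1.0),
        seed=st.integers(0, 100),
    )
    def test_monotone_in_thresholds(self, t1, t2, seed):
        """Raising either threshold never removes more features."""
        lo, hi = sorted([t1, t2])
        ds, _ = simulate_dataset(n_features=30, n_samples=16, n_modules=1,
                                 module_size=10, mcar_rate=0.25, seed=seed)
        kept_lo = set(filter_noise(ds, qc_thresh=lo, group_thresh=0.2).feature_ids)
        kept_hi = set(filter_noise(ds, qc_thresh=hi, group_thresh=0.2).feature_ids)
        assert kept_lo <= kept_hi


class TestTriageOutliers:
    def test_thresholds_partition_keep_review_remove(self):
        classes, groups = _qc_groups(3, 2)
        X = np.ones((10, 5))
        X[:1, 0] = np.nan   # S1: 10%
        X[:6, 1] = np.nan   # S2: 60%
        X[:9, 2] = np.nan   # S3: 90%
        ds = make_dataset(X, classes=classes, groups=groups)
        tri = triage_outliers(ds)
        assert (tri.keep, tri.review, tri.remove) == (["S1"], ["S2"], ["S3"])

    def test_all_observed_only_keep(self, clean_dataset):
        tri = triage_outliers(clean_dataset)
        assert tri.review == [] and tri.remove == []
        assert set(tri.keep) == set(clean_dataset.subject_sample_ids)

    def test_boundary_exactly_half_goes_to_review(self):
        classes, groups = _qc_groups(1, 2)
        X = np.ones((10, 3))
        X[:5, 0] = np.nan
        ds = make_dataset(X, classes=classes, groups=groups)
        assert triage_outliers(ds).review == ["S1"]

    def test_inverted_thresholds_rejected(self, clean_dataset):
        with pytest.raises(ParameterError):
            triage_outliers(clean_dataset, keep_below=0.9, remove_above=0.5)


class TestImputeKnn:
    def test_no_missing_is_identity(self, clean_dataset):
        out = impute_knn(clean_dataset, k=3)
        pd.testing.assert_frame_equal(out.expression, clean_dataset.expression)

    def test_hand_computed_neighbor_mean(self):
        # F1 missing in S3; F2 is the nearer neighbour of F1 on log2 profiles
        X = np.array([
            [10.0, 20.0, np.nan, 40.0],
            [10.0, 20.0, 31.0, 40.0],
            [500.0, 600.0, 700.0, 800.0],
        ])
        ds = make_dataset(X, classes=["Subject"] * 4)
        out = impute_knn(ds, k=2)
        # k=2 neighbours of F1 are F2 and F3; imputed = mean of their S3 values
        assert out.expression.loc["F1", "S3"] == pytest.approx((31.0 + 700.0) / 2)

    def test_k1_uses_single_nearest(self):
        X = np.array([
            [10.0, 20.0, np.nan, 40.0],
            [10.0, 20.0, 31.0, 40.0],
            [500.0, 600.0, 700.0, 800.0],
        ])
        ds = make_dataset(X, classes=["Subject"] * 4)
        assert impute_knn(ds, k=1).expression.loc["F1", "S3"] == pytest.approx(31.0)

    def test_observed_entries_never_change(self):
        ds, _ = simulate_dataset(n_features=50, n_samples=20, n_modules=2,
                                 module_size=15, mcar_rate=0.1, seed=8)
        obs = ~ds.expression.isna()
        out = impute_knn(ds, k=5)
        assert (out.expression.to_numpy()[obs.to_numpy()]
                == ds.expression.to_numpy()[obs.to_numpy()]).all()
        assert not out.expression.isna().to_numpy().any()

    def test_mask_and_recover_beats_feature_mean(self):
        """On correlated data, KNN recovers masked values better than the
        per-feature mean baseline (median relative error)."""
        ds, _ = simulate_dataset(n_features=60, n_samples=40, n_modules=3,
                                 module_size=20, within_cor=0.9, seed=13)
        rng = np.random.default_rng(13)
        truth = ds.expression.copy()
        mask = rng.uniform(size=truth.shape) < 0.05
        ds.expression = truth.mask(mask)
        out = impute_knn(ds, k=10)
        knn_err = np.abs(out.expression.to_numpy()[mask] - truth.to_numpy()[mask]) / truth.to_numpy()[mask]
        fmean = np.nanmean(ds.expression.to_numpy(), axis=1)
        base = np.broadcast_to(fmean[:, None], truth.shape)
        base_err = np.abs(base[mask] - truth.to_numpy()[mask]) / truth.to_numpy()[mask]
        assert np.median(knn_err) < np.median(base_err)

    def test_fully_missing_feature_rejected(self):
        X = np.ones((3, 4))
        X[0, :] = np.nan
        ds = make_dataset(X)
        with pytest.raises(ParameterError, match="100% missing"):
            impute_knn(ds, k=1)

    def test_k_too_large_rejected(self, clean_dataset):
        with pytest.raises(ParameterError):
            impute_knn(clean_dataset, k=10)


class TestNormalizeSvr:
    def test_drift_free_data_nearly_unchanged(self):
        # constant QC intensities: the fitted drift curve is flat, so the
        # correction factor is 1 up to numerics
        n = 20
        classes = ["QC" if i % 4 == 0 else "Subject" for i in range(n)]
        groups = ["QC" if c == "QC" else "g1" for c in classes]
        rng = np.random.default_rng(4)
        X = np.empty((10, n))
        qc_cols = [i for i, c in enumerate(classes) if c == "QC"]
        for f in range(10):
            level = rng.uniform(1e4, 1e6)
            X[f] = rng.uniform(0.8, 1.2, size=n) * level
            X[f, qc_cols] = level
        ds = make_dataset(X, classes=classes, groups=groups)
        out = normalize_svr_qc(ds, min_qc_per_batch=5)
        rel = np.abs(out.expression.to_numpy() / X - 1.0)
        assert rel.max() < 0.01

    def test_monotone_drift_reduces_qc_rsd(self):
        ds, _ = simulate_dataset(n_features=40, n_samples=60, n_modules=2,
                                 module_size=10, drift_slope=0.02, qc_every=6, seed=21)
        out = normalize_svr_qc(ds)
        assert median_qc_rsd(out) < median_qc_rsd(ds)

    def test_too_few_qc_mentions_fallback_flag(self):
        classes = ["Subject"] * 6 + ["QC"] * 2
        ds = make_dataset(np.ones((5, 8)) * 10, classes=classes,
                          groups=["g1"] * 6 + ["QC"] * 2)
        with pytest.raises(ParameterError, match="median"):
            normalize_svr_qc(ds)


class TestIntegrateBatches:
    def test_single_batch_is_noop(self, clean_dataset):
        out = integrate_batches(clean_dataset)
        pd.testing.assert_frame_equal(out.expression, clean_dataset.expression)
        assert out.log[-1].params.get("noop") is True

    def test_two_batches_with_offset_align_qc_medians(self):
        classes = (["Subject"] * 3 + ["QC"] * 3) * 2
        groups = ["g1" if c == "Subject" else "QC" for c in classes]
        batches = ["1"] * 6 + ["2"] * 6
        orders = list(range(1, 7)) + list(range(1, 7))
        rng = np.random.default_rng(5)
        X = rng.uniform(100, 200, size=(6, 12))
        X[:, 6:] *= 2.0  # batch-2 intensities doubled
        ds = make_dataset(X, classes=classes, groups=groups, batches=batches,
                          orders=orders)
        out = integrate_batches(ds)
        qc1 = [s for s, c, b in zip(ds.sample_ids, classes, batches)
               if c == "QC" and b == "1"]
        qc2 = [s for s, c, b in zip(ds.sample_ids, classes, batches)
               if c == "QC" and b == "2"]
        med1 = out.expression[qc1].median(axis=1)
        med2 = out.expression[qc2].median(axis=1)
        pd.testing.assert_series_equal(med1, med2, check_names=False)

    def test_batch_without_qc_rejected(self):
        classes = ["Subject"] * 3 + ["QC"] * 2 + ["Subject"] * 3
        batches = ["1"] * 5 + ["2"] * 3
        orders = [1, 2, 3, 4, 5, 1, 2, 3]
        ds = make_dataset(np.ones((4, 8)), classes=classes,
                          groups=["g1"] * 8, batches=batches, orders=orders)
        with pytest.raises(ParameterError, match="QC"):
            integrate_batches(ds)

    def test_three_batch_fixture_collapses_batch_separation(self):
        from sklearn.metrics import silhouette_score

        ds, _ = simulate_dataset(n_features=60, n_samples=90, n_batches=3,
                                 n_modules=2, module_size=15, drift_slope=0.02,
                                 qc_every=8, seed=17)
        # plant a per-batch multiplicative offset on top of the drift
        for i, b in enumerate(ds.batches):
            ids = ds.samples.index[ds.samples["batch"] == b]
            ds.expression[ids] *= 1.0 + 0.8 * i

        def batch_silhouette(d):
            qc = d.qc_sample_ids
            X = np.log2(d.expression[qc].to_numpy().T + 1)
            labels = d.samples.loc[qc, "batch"].to_numpy()
            return silhouette_score(X, labels)

        before = batch_silhouette(ds)
        out = integrate_batches(normalize_svr_qc(ds))
        assert batch_silhouette(out) < before
        assert batch_silhouette(out) < 0.1
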