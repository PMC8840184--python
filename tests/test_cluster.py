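"""Feature extraction, from-scratch k-means, silhouette, screening rule."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_score as sk_silhouette

import sasod
from sasod.cluster import (
    BreathKMeans,
    SasScreener,
    extract_features,
    fit_kmeans,
    select_k_and_decide,
    silhouette,
)
from sasod.segments import BreathSegment


def tone_segment(env_per_second, rate=1000.0, freq=100.0):
    """15-s segment whose per-second RMS follows env_per_second."""
    t = np.arange(int(15 * rate)) / rate
    gains = np.repeat(np.asarray(env_per_second, dtype=float), int(rate))
    x = gains * np.sqrt(2) * np.sin(2 * np.pi * freq * t)
    return BreathSegment(samples=x, rate=rate, center_s=7.5, peak_pressure=1.0)


def brute_silhouette(X, labels):
    """Independent O(n^2) loop implementation."""
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j]) for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


class TestExtractFeatures:
    def test_constant_envelope_maps_to_zero_vector(self):
        seg = tone_segment([0.5] * 15)
        v = extract_features(seg).values
        assert v.shape == (15,)
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_loud_second_is_vector_maximum(self):
        env = [0.1] * 15
        env[6] = 0.9
        v = extract_features(tone_segment(env)).values
        assert int(np.argmax(v)) == 6

    def test_deterministic(self, sas_recording):
        seg = sasod.extract_segments(sas_recording, n_segments=1)[0]
        a = extract_features(seg).values
        b = extract_features(seg).values
        assert np.array_equal(a, b)

    def test_all_zero_segment_rejected(self):
        seg = BreathSegment(samples=np.zeros(15 * 1000), rate=1000.0,
                            center_s=7.5, peak_pressure=0.0)
        with pytest.raises(ValueError, match="zero"):
            extract_features(seg)

    def test_band_energy_scheme_shape(self, sas_recording):
        seg = sasod.extract_segments(sas_recording, n_segments=1)[0]
        v = extract_features(seg, "BAND_ENERGY").values
        assert v.ndim == 1 and v.size >= 4
        assert np.all(np.isfinite(v))


class TestBreathKMeans:
    def test_recovers_separated_blobs(self, rng):
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        labels_true = np.repeat([0, 1, 2], 30)
        X = centers[labels_true] + 0.01 * rng.standard_normal((90, 2))
        est = BreathKMeans(n_clusters=3, random_state=0).fit(X)
        # same partition up to relabeling
        for c in range(3):
            assert len(set(est.labels_[labels_true == c])) == 1
        assert len(set(est.labels_)) == 3

    def test_degenerate_k_distinct_points(self):
        X = np.vstack([np.zeros((10, 2)), [[5, 5]], [[9, 0]]])
        est = BreathKMeans(n_clusters=3, random_state=0).fit(X)
        assert est.inertia_ == pytest.approx(0.0, abs=1e-12)

    def test_inertia_beats_random_assignment_baselines(self, rng):
        X = rng.standard_normal((30, 5))
        est = BreathKMeans(n_clusters=4, random_state=1).fit(X)
        for _ in range(50):
            labels = rng.integers(0, 4, size=30)
            centers = np.array([
                X[labels == c].mean(axis=0) if np.any(labels == c) else X[0]
                for c in range(4)
            ])
            inertia = float(
                ((X - centers[labels]) ** 2).sum()
            )
            assert est.inertia_ <= inertia + 1e-9

    def test_lloyd_inertia_monotone_descent(self, rng):
        X = rng.standard_normal((120, 6))
        est = BreathKMeans(n_clusters=5, random_state=2).fit(X)
        path = est.inertia_path_
        assert all(b <= a + 1e-9 for a, b in zip(path, path[1:]))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            BreathKMeans(n_clusters=5).fit(np.zeros((4, 2)))

    def test_fewer_distinct_values_than_k_rejected(self):
        X = np.repeat(np.array([[0.0, 0.0], [1.0, 1.0]]), 10, axis=0)
        with pytest.raises(ValueError, match="distinct"):
            BreathKMeans(n_clusters=3).fit(X)

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((60, 4))
        est = BreathKMeans(n_clusters=4, random_state=7).fit(X)
        perm = rng.permutation(60)
        est_p = BreathKMeans(n_clusters=4, random_state=7).fit(X[perm])
        assert est_p.inertia_ == pytest.approx(est.inertia_, rel=1e-12)

    def test_predict_assigns_nearest_centroid(self, rng):
        X = rng.standard_normal((40, 3))
        est = BreathKMeans(n_clusters=3, random_state=0).fit(X)
        pred = est.predict(X)
        d = cdist(X, est.cluster_centers_)
        assert np.array_equal(pred, d.argmin(axis=1))


class TestSilhouette:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            X = rng.standard_normal((12, 3))
            labels = rng.integers(0, 3, size=12)
            if len(set(labels.tolist())) < 2:
                continue
            assert silhouette(X, labels) == pytest.approx(
                brute_silhouette(X, labels), rel=1e-10
            )

    def test_matches_sklearn_when_no_singletons(self, rng):
        for _ in range(10):
            X = rng.standard_normal((20, 4))
            labels = np.repeat([0, 1, 2, 3], 5)
            assert silhouette(X, labels) == pytest.approx(
                float(sk_silhouette(X, labels)), rel=1e-9
            )

    def test_separated_blobs_approach_one(self, rng):
        X = np.vstack([rng.standard_normal((20, 2)),
                       rng.standard_normal((20, 2)) + 500.0])
        labels = np.repeat([0, 1], 20)
        assert silhouette(X, labels) > 0.98

    def test_random_labels_near_zero(self, rng):
        X = rng.uniform(size=(200, 2))
        labels = rng.integers(0, 2, size=200)
        assert abs(silhouette(X, labels)) < 0.1

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestScreeningRule:
    def test_disjoint_cohort_called_perfectly(self):
        X, ids, flags = sasod.gen_feature_cohort(seed=0)
        model, calls, table = select_k_and_decide(X, y=flags, groups=ids, seed=0)
        truth = {f"subj{i:03d}": i < 37 for i in range(42)}
        assert calls == truth
        # clusters are class-pure, so the table has no mixed rows
        for row in table.values():
            assert row["sas"] == 0 or row["non_sas"] == 0

    def test_all_healthy_cohort_yields_no_calls(self, rng):
        X = np.vstack([rng.standard_normal((40, 5)) + 20 * c
                       for c in range(5)])
        ids = [f"s{i}" for i in range(40) for _ in range(5)]
        flags = np.zeros(200, dtype=bool)
        scr = SasScreener(random_state=0).fit(X, flags, groups=ids)
        assert scr.indicative_clusters_ == []
        assert not any(scr.subject_calls_.values())

    def test_forced_singleton_k_range(self):
        X, ids, flags = sasod.gen_feature_cohort(n_sas=5, n_non_sas=3, seed=2)
        model, _, _ = select_k_and_decide(X, y=flags, groups=ids,
                                          k_range=(4,), seed=0)
        assert model.k == 4

    def test_unlabeled_cohort_returns_model_only(self):
        X, ids, _ = sasod.gen_feature_cohort(n_sas=4, n_non_sas=3, seed=3)
        scr = SasScreener(random_state=0).fit(X)
        assert scr.model_.k == scr.k_
        assert scr.subject_calls_ is None
        with pytest.raises(ValueError, match="unavailable|labels"):
            scr.predict(X)

    def test_subject_calls_invariant_under_permutation(self, rng):
        X, ids, flags = sasod.gen_feature_cohort(n_sas=8, n_non_sas=4, seed=5)
        model, calls, _ = select_k_and_decide(X, y=flags, groups=ids, seed=1)
        perm = rng.permutation(len(ids))
        model_p, calls_p, _ = select_k_and_decide(
            X[perm], y=flags[perm], groups=[ids[i] for i in perm], seed=1
        )
        assert calls == calls_p
        assert model_p.inertia == pytest.approx(model.inertia, rel=1e-12)

    def test_unequal_segment_counts_rejected(self):
        X = np.random.default_rng(0).standard_normal((7, 3)) * 10
        with pytest.raises(ValueError, match="same number"):
            SasScreener(k_range=(2,), random_state=0).fit(
                X, np.zeros(7, dtype=bool), groups=["a"] * 4 + ["b"] * 3
            )

    def test_predict_on_held_out_subjects(self):
        X, ids, flags = sasod.gen_feature_cohort(seed=9)
        scr = SasScreener(random_state=0).fit(X, flags, groups=ids)
        Xn, idn, fn = sasod.gen_feature_cohort(n_sas=3, n_non_sas=2, seed=10)
        calls = scr.predict(Xn, groups=idn)
        truth = {f"subj{i:03d}": i < 3 for i in range(5)}
        assert calls == truth


def test_fit_kmeans_wrapper_reports_silhouette(rng):
    X = np.vstack([rng.standard_normal((20, 3)),
                   rng.standard_normal((20, 3)) + 30])
    model = fit_kmeans(X, k=2, seed=0)
    assert model.silhouette == pytest.approx(silhouette(X, model.assignments))
    assert model.k == 2 and model.centroids.shape == (2, 3)
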