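"""Performance measures, silhouette clustering and condition-derived labels."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from mwlcnn.labeling import (
    CASE1_CLASSES,
    CASE2_CLASSES,
    assign_condition_labels,
    cluster_labels,
    compute_pi,
    compute_tir,
    select_num_classes,
    silhouette,
)
from mwlcnn.signal_io import EpochSet, default_schedule


def brute_force_silhouette(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """O(n^2) reference: explicit per-point a(i), b(i) loops."""
    points = np.atleast_2d(points.astype(float))
    if points.shape[0] == 1:
        points = points.T
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        others = {}
        for j in range(n):
            d = np.linalg.norm(points[i] - points[j])
            if own[j]:
                if j != i:
                    others.setdefault("own", []).append(d)
            else:
                others.setdefault(labels[j], []).append(d)
        own_ds = others.pop("own", [])
        if not own_ds:
            continue  # singleton -> 0
        a = np.mean(own_ds)
        b = min(np.mean(v) for v in others.values())
        s[i] = (b - a) / max(a, b)
    return s


class TestTirAndPi:
    def test_all_in_range_gives_one(self):
        assert compute_tir(np.ones((10, 4), dtype=bool)) == 1.0

    def test_half_flags_single_instant(self):
        assert compute_tir(np.array([[1, 0, 1, 0]])) == 0.5

    def test_alternating_instants_symmetry(self):
        flags = np.array([[1, 1, 1, 1], [0, 0, 0, 0]] * 5)
        assert compute_tir(flags) == 0.5

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_tir(np.empty((0, 4)))

    @pytest.mark.parametrize(
        "tir,nos,expected",
        [(1.0, 0, 0.7), (0.571, 4, 1.5997), (0.0, 0, 0.0)],
    )
    def test_pi_affine_combination(self, tir, nos, expected):
        assert compute_pi(tir, nos) == pytest.approx(expected, abs=1e-12)

    def test_pi_reduces_to_tir(self):
        assert compute_pi(0.37, 3, c1=1.0, c2=0.0) == pytest.approx(0.37)

    def test_pi_rejects_out_of_range_tir(self):
        with pytest.raises(ValueError):
            compute_pi(1.2, 2)


class TestSilhouette:
    def test_two_tight_far_pairs_hand_value(self):
        pts = np.array([0.0, 0.1, 10.0, 10.1])
        labels = np.array([0, 0, 1, 1])
        res = silhouette(pts, labels)
        # a(0) = 0.1, b(0) = mean(10, 10.1) = 10.05
        assert res.s[0] == pytest.approx((10.05 - 0.1) / 10.05, abs=1e-12)
        assert res.s[0] == pytest.approx(0.990, abs=5e-4)

    def test_zero_within_distance_scores_one(self):
        pts = np.array([0.0, 0.0, 5.0, 5.0])
        res = silhouette(pts, np.array([0, 0, 1, 1]))
        assert np.allclose(res.s, 1.0)

    def test_equal_a_and_b_scores_zero(self):
        # point 0: a = |0-2| = 2 and b = mean(|0-1|, |0-3|) = 2, so S = 0
        pts = np.array([0.0, 2.0, 1.0, 3.0])
        res = silhouette(pts, np.array([0, 0, 1, 1]))
        assert res.a[0] == pytest.approx(res.b[0])
        assert res.s[0] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([0.0, 0.1, 9.0])
        res = silhouette(pts, np.array([0, 0, 1]))
        assert res.s[2] == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((60, 3))
        labels = rng.integers(0, 4, 60)
        res = silhouette(pts, labels)
        np.testing.assert_allclose(res.s, brute_force_silhouette(pts, labels), atol=1e-12)

    def test_matches_sklearn_on_multi_member_clusters(self):
        rng = np.random.default_rng(1)
        pts = rng.standard_normal((80, 2))
        labels = rng.integers(0, 3, 80)
        res = silhouette(pts, labels)
        np.testing.assert_allclose(res.s, silhouette_samples(pts, labels), atol=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.arange(5.0), np.zeros(5, dtype=int))


class TestSelectNumClasses:
    def _blobs(self, centers, n_per=30, scale=0.05, seed=0):
        rng = np.random.default_rng(seed)
        return np.concatenate(
            [c + scale * rng.standard_normal(n_per) for c in centers]
        )

    @pytest.mark.parametrize("centers", [(0.0, 5.0, 10.0), (0.0, 8.0)])
    def test_recovers_blob_count(self, centers):
        best_k, curve = select_num_classes(self._blobs(centers), range(2, 8), seed=0)
        assert best_k == len(centers)
        assert curve.loc[curve["k"] == best_k, "is_local_max"].item()

    def test_curve_matches_bruteforce_silhouette(self):
        pts = self._blobs((0.0, 5.0, 10.0))
        _, curve = select_num_classes(pts, range(2, 5), seed=0)
        for _, row in curve.iterrows():
            labels = cluster_labels(pts, int(row["k"]), seed=0)
            brute = brute_force_silhouette(pts.reshape(-1, 1), labels).mean()
            assert row["mean_silhouette"] == pytest.approx(brute, abs=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            select_num_classes(np.full(50, 1.3), range(2, 5), seed=0)


def _epochs_for(schedule, n_per_condition, n_sessions=1):
    cond_ids = np.concatenate(
        [
            np.repeat([c.condition_id for c in schedule], n_per_condition)
            for _ in range(n_sessions)
        ]
    )
    n = len(cond_ids)
    return EpochSet(
        data=np.zeros((n, 1, 4)),
        condition_ids=cond_ids,
        start_times_s=np.zeros(n),
        session_ids=np.array(["s"] * n, dtype=object),
        window_s=2.0,
        sampling_rate_hz=2.0,
    )


class TestConditionLabels:
    def test_case1_class_sizes_two_sessions(self):
        schedule = default_schedule()
        epochs = _epochs_for(schedule, 145, n_sessions=2)
        labels = assign_condition_labels(schedule, epochs, case=4)
        assert labels.class_names == CASE1_CLASSES
        assert labels.class_sizes().tolist() == [1160, 580, 580, 580]

    def test_case2_class_sizes_two_sessions(self):
        schedule = default_schedule()
        epochs = _epochs_for(schedule, 145, n_sessions=2)
        labels = assign_condition_labels(schedule, epochs, case=7)
        assert labels.class_names == CASE2_CLASSES
        assert labels.class_sizes().tolist() == [1160, 290, 290, 290, 290, 290, 290]

    def test_hard_condition_is_top_class(self):
        schedule = default_schedule()
        epochs = _epochs_for(schedule, 1)
        for case, top in ((4, "High"), (7, "Overloaded")):
            labels = assign_condition_labels(schedule, epochs, case=case)
            assert labels.names()[8] == top  # condition 9: NOS=4, AS=high

    def test_unknown_condition_id_rejected(self):
        schedule = default_schedule()
        epochs = _epochs_for(schedule, 1)
        epochs.condition_ids[0] = 11
        with pytest.raises(ValueError, match="11"):
            assign_condition_labels(schedule, epochs, case=4)

    def test_label_export_frame(self):
        schedule = default_schedule()
        epochs = _epochs_for(schedule, 2)
        df = assign_condition_labels(schedule, epochs, case=4).to_frame(epochs)
        assert list(df.columns) == [
            "epoch_index", "session_id", "condition_id", "case", "class_index", "class_name",
        ]
        assert len(df) == 20
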