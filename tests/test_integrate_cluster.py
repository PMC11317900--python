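import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from capitulum3d import (
    BBox,
    Cluster,
    Detection,
    SlicePlane,
    agglomerate,
    backproject,
    estimate_contact_points,
    evaluate_positions,
    group_average,
    jittered_centroid_error,
    nearest_floret_distances,
    sweep_cluster_counts,
)


def naive_agglomerate(pts, d):
    """Recompute-everything oracle with the same tie-break rule."""
    clusters = [[i] for i in range(len(pts))]
    created = list(range(len(pts)))
    nxt = len(pts)
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = cdist(pts[clusters[a]], pts[clusters[b]]).mean()
                key = (dist, tuple(sorted((created[a], created[b]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best[0][0] >= d:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        created[a] = nxt
        nxt += 1
        del clusters[b], created[b]
    return {frozenset(c) for c in clusters}


def partition(clusters):
    return {frozenset(c.indices) for c in clusters}


class TestBackproject:
    def plane(self, theta):
        return SlicePlane(theta_deg=theta, center_xy=(50.0, 50.0), width=101, height=80)

    def test_axis_centered_box_lands_on_axis(self):
        p = self.plane(77.0)
        d = Detection(box=BBox(48, 10, 52, 14), confidence=1.0, theta_deg=77.0)
        pt = backproject(d, p)
        assert np.allclose([pt.x, pt.y, pt.z], [50.0, 50.0, 12.0])

    def test_theta0_offset_along_x(self):
        p = self.plane(0.0)
        d = Detection(box=BBox(58, 20, 62, 24), confidence=1.0, theta_deg=0.0)
        pt = backproject(d, p)
        assert np.allclose([pt.x, pt.y, pt.z], [60.0, 50.0, 22.0])

    def test_theta30_matches_trigonometry(self):
        p = self.plane(30.0)
        d = Detection(box=BBox(68, 0, 72, 2), confidence=1.0, theta_deg=30.0)  # r = 20
        pt = backproject(d, p)
        assert np.allclose([pt.x - 50, pt.y - 50], [17.3205, 10.0], atol=1e-4)

    def test_angle_mismatch_rejected(self):
        d = Detection(box=BBox(0, 0, 2, 2), confidence=1.0, theta_deg=10.0)
        with pytest.raises(ValueError, match="azimuth"):
            backproject(d, self.plane(20.0))


class TestGroupAverage:
    def test_singletons_reduce_to_euclidean_distance(self):
        a = Cluster(members=[[0, 0, 0]], indices=(0,))
        b = Cluster(members=[[3, 4, 0]], indices=(1,))
        assert group_average(a, b) == 5.0

    def test_pair_enumeration(self):
        a = Cluster(members=[[0, 0, 0], [2, 0, 0]], indices=(0, 1))
        b = Cluster(members=[[0, 3, 0], [0, 4, 0]], indices=(2, 3))
        expected = (3 + 4 + np.sqrt(13) + np.sqrt(20)) / 4
        assert group_average(a, b) == pytest.approx(expected)
        assert group_average(a, b) == pytest.approx(3.76942, abs=1e-5)

    def test_symmetry(self, rng):
        a = Cluster(members=rng.normal(size=(4, 3)), indices=tuple(range(4)))
        b = Cluster(members=rng.normal(size=(6, 3)), indices=tuple(range(4, 10)))
        assert group_average(a, b) == pytest.approx(group_average(b, a))


class TestAgglomerate:
    def test_everything_merges_below_threshold(self, rng):
        pts = rng.normal(scale=0.5, size=(3, 3))
        clusters = agglomerate(pts, d=100.0)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_separated_blobs_stay_separate(self, rng):
        blob1 = rng.normal(scale=0.3, size=(3, 3))
        blob2 = rng.normal(scale=0.3, size=(3, 3)) + [100, 0, 0]
        clusters = agglomerate(np.vstack([blob1, blob2]), d=10.0)
        assert partition(clusters) == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 41))
            pts = rng.uniform(0, 100, size=(n, 3))
            diam = cdist(pts, pts).max()
            d = float(rng.uniform(1e-6, diam))
            assert partition(agglomerate(pts, d)) == naive_agglomerate(pts, d)

    def test_matches_scipy_average_linkage(self, rng):
        # independent library cross-check: cut scipy's average-linkage tree at d
        pts = rng.uniform(0, 50, size=(40, 3))
        d = 12.0
        ours = partition(agglomerate(pts, d))
        labels = fcluster(linkage(pts, method="average"), t=d - 1e-9, criterion="distance")
        theirs = {frozenset(np.where(labels == lab)[0].tolist()) for lab in set(labels)}
        assert ours == theirs

    def test_cluster_count_monotone_in_d(self, rng):
        pts = rng.uniform(0, 60, size=(50, 3))
        counts = sweep_cluster_counts(pts, [1, 10, 20, 30, 40, 50])
        vals = [counts[d] for d in [1, 10, 20, 30, 40, 50]]
        assert vals == sorted(vals, reverse=True)

    def test_limits_of_d(self, rng):
        pts = rng.uniform(0, 10, size=(8, 3))
        assert len(agglomerate(pts, 1e-9)) == 8  # every distinct point its own cluster
        assert len(agglomerate(pts, 1e6)) == 1  # one cluster beyond the data diameter

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            agglomerate(np.empty((0, 3)), 1.0)


class TestEstimates:
    def test_centroid_is_midpoint(self):
        clusters = agglomerate(np.array([[0.0, 0, 0], [2.0, 0, 0]]), d=10.0)
        cps = estimate_contact_points(clusters, 10.0)
        assert np.allclose(cps.estimates, [[1.0, 0, 0]])

    def test_singletons_are_identity(self, rng):
        pts = rng.uniform(0, 100, size=(6, 3))
        clusters = agglomerate(pts, d=1e-9)
        cps = estimate_contact_points(clusters, 1e-9)
        assert len(cps) == 6
        assert np.allclose(sorted(map(tuple, cps.estimates)), sorted(map(tuple, pts)))


class TestEvaluation:
    def test_exact_estimates_have_zero_error(self, rng):
        gt = rng.uniform(0, 50, size=(10, 3))
        ev = evaluate_positions(gt, gt)
        assert np.all(ev.errors == 0) and ev.mean == 0 and ev.sd == 0

    def test_unit_offset(self):
        gt = np.array([[5.0, 5.0, 5.0]])
        ev = evaluate_positions(gt + [1, 0, 0], gt)
        assert ev.errors[0] == pytest.approx(1.0)

    def test_matches_brute_force_nearest_neighbour(self, rng):
        est = rng.uniform(0, 100, size=(20, 3))
        gt = rng.uniform(0, 100, size=(20, 3))
        ev = evaluate_positions(est, gt, axis_xy=(50.0, 50.0))
        all_pairs = cdist(est, gt)
        assert np.allclose(ev.errors, all_pairs.min(axis=1))
        assert np.array_equal(ev.nearest_gt_index, all_pairs.argmin(axis=1))
        assert np.allclose(ev.axis_distances, np.hypot(est[:, 0] - 50, est[:, 1] - 50))

    def test_population_sd(self):
        gt = np.array([[0.0, 0, 0]])
        est = np.array([[1.0, 0, 0], [3.0, 0, 0]])
        ev = evaluate_positions(est, gt)
        assert ev.sd == pytest.approx(1.0)  # population, not sample, sd


class TestNearestFloretDistances:
    def test_two_points(self):
        assert np.allclose(nearest_floret_distances([[0, 0, 0], [3, 4, 0]]), [5, 5])

    def test_collinear_points(self):
        d = nearest_floret_distances([[0, 0, 0], [1, 0, 0], [10, 0, 0]])
        assert np.allclose(d, [1, 1, 9])

    def test_matches_exhaustive_search(self, rng):
        pts = rng.uniform(0, 30, size=(30, 3))
        dm = cdist(pts, pts)
        np.fill_diagonal(dm, np.inf)
        assert np.allclose(nearest_floret_distances(pts), dm.min(axis=1))

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            nearest_floret_distances([[0, 0, 0]])


class TestAveragingDebiasing:
    def test_centroid_error_shrinks_with_supporting_slices(self):
        # zero-mean jitter averages out: more supporting slices, smaller error
        errs = {
            n: np.mean(
                [
                    jittered_centroid_error(n, 1.0, 100.0, 200.0, np.random.default_rng(1000 * n + s))
                    for s in range(60)
                ]
            )
            for n in (5, 100)
        }
        assert errs[100] < errs[5]
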