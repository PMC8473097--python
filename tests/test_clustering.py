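"""Breakpoint clustering, body gating, and per-frame leg estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

from gaitlidar.clustering import (
    Cluster,
    ClusterConfig,
    LegEstimate,
    PARTICLE_FILTER,
    ParticleFilterConfig,
    breakpoint_cluster,
    extract_legs,
    find_torso,
    gate_by_body,
    particle_filter_step,
)
from gaitlidar.geometry import PointCloud, SensorPose


POSES = {
    "a": SensorPose("a", 0.0, 0.0, 0.0),
    "b": SensorPose("b", 8.0, 0.0, 180.0),
}


def cloud_of(points, sensors=None):
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if sensors is None:
        sensors = ["a"] * len(points)
    return PointCloud(0.0, points, np.asarray(sensors, dtype=object))


def single_linkage_partition(points, threshold, min_size=1):
    """Independent oracle: single-linkage connected components."""
    if len(points) == 0:
        return []
    if len(points) == 1:
        groups = [np.array([0])]
    else:
        labels = fcluster(linkage(points, method="single"), t=threshold,
                          criterion="distance")
        groups = [np.flatnonzero(labels == k) for k in np.unique(labels)]
    return [g for g in groups if len(g) >= min_size]


def as_partition(clusters):
    return sorted(sorted(map(tuple, np.round(c.points, 9))) for c in clusters)


def oracle_partition(points, groups):
    return sorted(sorted(map(tuple, np.round(points[g], 9))) for g in groups)


def random_cloud(rng, n_max=200):
    n = rng.integers(2, n_max + 1)
    pts = rng.uniform(0, 4, size=(n, 2))
    sensors = rng.choice(list(POSES), size=n)
    return cloud_of(pts, sensors)


class TestBreakpointCluster:
    def test_two_separated_groups(self):
        pts = np.vstack([np.random.default_rng(0).normal([0, 0], 0.02, (10, 2)),
                         np.random.default_rng(1).normal([1, 0], 0.02, (10, 2))])
        clusters = breakpoint_cluster(cloud_of(pts), ClusterConfig(0.2, 5, 0.5), POSES)
        assert len(clusters) == 2

    def test_small_clusters_removed(self):
        pts = np.array([[0, 0], [0.01, 0], [0.02, 0], [0.03, 0]])  # only 4 points
        clusters = breakpoint_cluster(cloud_of(pts), ClusterConfig(0.1, 5, 0.5), POSES)
        assert clusters == []

    def test_empty_cloud(self):
        assert breakpoint_cluster(PointCloud.empty(), ClusterConfig(), POSES) == []

    def test_matches_single_linkage_components(self):
        """Per-sensor chaining + min-distance chain merging is exactly
        single-linkage connected components at the same threshold."""
        rng = np.random.default_rng(11)
        cfg = ClusterConfig(0.12, 1, 0.5)
        for _ in range(100):
            cloud = random_cloud(rng)
            got = breakpoint_cluster(cloud, cfg, POSES)
            want = single_linkage_partition(cloud.xy, cfg.breakpoint_threshold_m)
            assert as_partition(got) == oracle_partition(cloud.xy, want)

    def test_size_filter_matches_oracle(self):
        rng = np.random.default_rng(5)
        cfg = ClusterConfig(0.12, 5, 0.5)
        for _ in range(20):
            cloud = random_cloud(rng, n_max=80)
            got = breakpoint_cluster(cloud, cfg, POSES)
            want = single_linkage_partition(cloud.xy, 0.12, min_size=5)
            assert as_partition(got) == oracle_partition(cloud.xy, want)


class TestFindTorso:
    def test_largest_cluster_wins(self):
        small = Cluster(np.zeros((12, 2)))
        big = Cluster(np.full((30, 2), 2.0))
        np.testing.assert_allclose(find_torso([small, big]), [2.0, 2.0])

    def test_no_clusters_absent(self):
        assert find_torso([]) is None


class TestGating:
    def test_boundary_semantics(self):
        body = np.zeros(2)
        cfg = ClusterConfig(0.12, 5, 0.50)
        cloud = cloud_of([[0.49, 0], [0.51, 0], [0.50, 0]])
        kept = gate_by_body(cloud, body, cfg)
        np.testing.assert_allclose(sorted(kept.xy[:, 0]), [0.49, 0.50])

    def test_empty_cloud_passthrough(self):
        out = gate_by_body(PointCloud.empty(), np.zeros(2), ClusterConfig())
        assert len(out) == 0

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 1000), r_small=st.floats(0.05, 0.4))
    def test_shrinking_gate_never_adds_points(self, seed, r_small):
        rng = np.random.default_rng(seed)
        cloud = cloud_of(rng.uniform(-1, 1, (50, 2)))
        body = np.zeros(2)
        big = gate_by_body(cloud, body, ClusterConfig(0.12, 5, 0.5))
        small = gate_by_body(cloud, body, ClusterConfig(0.12, 5, r_small * 0.999))
        big_set = set(map(tuple, big.xy))
        assert set(map(tuple, small.xy)) <= big_set


def leg_cluster(center, rng, n=30, sd=0.02):
    return Cluster(np.asarray(center) + rng.normal(0, sd, size=(n, 2)))


class TestExtractLegs:
    def test_two_clusters_kmeans_centroids(self):
        rng = np.random.default_rng(0)
        c1, c2 = leg_cluster([0, 0], rng), leg_cluster([0.5, 0], rng)
        pair = extract_legs([c1, c2], None, ParticleFilterConfig(), np.zeros(2),
                            0.025, np.random.default_rng(1))
        got = sorted([p.position for p in pair], key=lambda p: p[0])
        assert np.linalg.norm(got[0] - c1.centroid) < 0.02
        assert np.linalg.norm(got[1] - c2.centroid) < 0.02

    def test_no_previous_state_and_one_cluster_unresolved(self):
        rng = np.random.default_rng(0)
        assert extract_legs([leg_cluster([0, 0], rng)], None, ParticleFilterConfig(),
                            np.zeros(2), 0.025, np.random.default_rng(1)) is None

    def test_zero_velocity_filter_stays_at_previous_position(self):
        prev = (LegEstimate([0.0, 0.0], "one_cluster_measured"),
                LegEstimate([1.0, 0.0], "one_cluster_measured"))
        cfg = ParticleFilterConfig()
        pair = extract_legs([], prev, cfg, np.zeros(2), 0.025,
                            np.random.default_rng(7))
        for est, p in zip(pair, prev):
            assert est.provenance == PARTICLE_FILTER
            tol = 3 * np.sqrt(2) * cfg.process_noise_sd_m / np.sqrt(cfg.n_particles)
            assert np.linalg.norm(est.position - p.position) < 5 * tol

    def test_filter_converges_onto_abundant_measurements(self):
        """With measurements available the particle estimate locks onto the
        measured centroid within a couple of centimetres."""
        rng = np.random.default_rng(3)
        target = np.array([0.3, 0.2])
        est = LegEstimate(target + [0.05, -0.04], PARTICLE_FILTER)
        pts = target + np.random.default_rng(0).normal(0, 0.01, (40, 2))
        for _ in range(10):
            est = particle_filter_step(est, np.zeros(2), 0.025,
                                       ParticleFilterConfig(), rng, pts)
        assert np.linalg.norm(est.position - pts.mean(axis=0)) < 0.02

    def test_measurements_beyond_gate_ignored(self):
        """Points farther than the measurement gate belong to the other leg
        and must not drag the filter."""
        rng = np.random.default_rng(3)
        est = LegEstimate([0.0, 0.0], PARTICLE_FILTER)
        far = np.array([[0.5, 0.0]])
        moved = particle_filter_step(est, np.zeros(2), 0.025,
                                     ParticleFilterConfig(), rng, far)
        assert np.linalg.norm(moved.position) < 0.05

    def test_occluded_swing_leg_recovered_within_10cm(self):
        """A leg hidden for 5 frames mid-swing is carried by the filter to
        within 10 cm of its true position at re-acquisition (noise-free
        measurements, fixed seed, 500 particles)."""
        rng = np.random.default_rng(42)
        dt, v_body = 0.025, np.array([0.6, 0.0])
        T, L = 1.0, 0.6
        swing = lambda t: np.array([-L + 2 * L * (1 - np.cos(np.pi * t / T)) / 2, 0.0])
        stance_pos = np.array([0.0, 0.07])
        # occlusion starts in early swing, where the leg's speed lies inside
        # the filter's modelled velocity envelope of [0.5, 2] x body speed
        t0 = 0.15
        prev = (LegEstimate(stance_pos, "one_cluster_measured"),
                LegEstimate(swing(t0), "one_cluster_measured"))
        pair = prev
        for k in range(1, 6):
            stance = Cluster(stance_pos + np.random.default_rng(k).normal(0, 0.005, (20, 2)))
            pair = extract_legs([stance], pair, ParticleFilterConfig(), v_body, dt, rng)
        true_now = swing(t0 + 5 * dt)
        assert pair[1].provenance == PARTICLE_FILTER
        assert np.linalg.norm(pair[1].position - true_now) < 0.10

    def test_merged_blob_split_into_two_legs(self):
        """A single elongated cluster (two legs in each other's angular
        shadow) is split instead of being treated as one leg."""
        rng = np.random.default_rng(0)
        blob = Cluster(np.vstack([
            np.array([0.0, 0.0]) + rng.normal(0, 0.01, (25, 2)),
            np.array([0.25, 0.0]) + rng.normal(0, 0.01, (25, 2)),
        ]))
        prev = (LegEstimate([0.0, 0.0], "one_cluster_measured"),
                LegEstimate([0.2, 0.0], "one_cluster_measured"))
        pair = extract_legs([blob], prev, ParticleFilterConfig(), np.zeros(2),
                            0.025, np.random.default_rng(1))
        assert all(p.provenance == "two_clusters_kmeans" for p in pair)
        xs = sorted(p.position[0] for p in pair)
        assert xs[0] == pytest.approx(0.0, abs=0.03)
        assert xs[1] == pytest.approx(0.25, abs=0.03)

    def test_well_separated_legs_never_coincide(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            r = np.random.default_rng(seed)
            c1, c2 = leg_cluster([0, 0], r), leg_cluster([0.4, 0], r)
            pair = extract_legs([c1, c2], None, ParticleFilterConfig(), np.zeros(2),
                                0.025, rng)
            assert np.linalg.norm(pair[0].position - pair[1].position) > 0.24
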