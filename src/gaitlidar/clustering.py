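"""Cloud segmentation, body gating, and per-frame leg estimation.

Segmentation uses threshold-based breakpoint detection: within each source
sensor, points are ordered by bearing about that sensor and a new chain
starts wherever the Euclidean gap between angular neighbours exceeds the
breakpoint threshold.  Chains (within and across sensors) are then merged
whenever their minimum inter-chain point distance is within the same
threshold, which makes the result identical to single-linkage connected
components at that threshold; angular ordering is only defined per sensor,
so chaining + merging is how the overlaid multi-sensor cloud is segmented.
Small clusters (fewer than ``min_cluster_size`` points) are removed.

Per frame, the gated shin cloud yields two leg estimates:

* two (or more) clusters: k-means with k=2, seeded at the two largest
  cluster centroids — both legs measured;
* one cluster: its centroid is the visible leg; the occluded leg is
  imputed by an SIR particle filter whose per-particle velocity is the
  previous upper-body velocity scaled uniformly from [0.5, 2.0];
* no clusters: both legs run on their particle filters.

Tracking initializes at the first frame with at least two clusters; earlier
frames are unresolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .geometry import PointCloud, SensorPose


@dataclass(frozen=True)
class ClusterConfig:
    breakpoint_threshold_m: float = 0.12
    min_cluster_size: int = 5
    body_gate_radius_m: float = 0.50

    def __post_init__(self) -> None:
        if min(self.breakpoint_threshold_m, self.min_cluster_size, self.body_gate_radius_m) <= 0:
            raise ValueError("cluster configuration values must be positive")


@dataclass
class Cluster:
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) < 1:
            raise ValueError("cluster needs at least one point")

    @property
    def size(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def _chain_split(points: np.ndarray, threshold: float) -> list[np.ndarray]:
    """Split angularly ordered points where consecutive gaps exceed threshold."""
    if len(points) == 0:
        return []
    gaps = np.hypot(*np.diff(points, axis=0).T)
    breaks = np.flatnonzero(gaps > threshold) + 1
    return np.split(points, breaks)


def breakpoint_cluster(cloud: PointCloud, cfg: ClusterConfig,
                       poses: Mapping[str, SensorPose]) -> list[Cluster]:
    """Segment a (possibly multi-sensor) cloud into clusters.

    Equivalent to single-linkage connected components at the breakpoint
    threshold, followed by removal of clusters smaller than
    ``min_cluster_size``.
    """
    if len(cloud) == 0:
        return []
    chains: list[np.ndarray] = []
    for sid in np.unique(cloud.sensor_id):
        sel = cloud.sensor_id == sid
        pts = cloud.xy[sel]
        pose = poses[sid]
        ang = np.arctan2(pts[:, 1] - pose.y, pts[:, 0] - pose.x)
        pts = pts[np.argsort(ang, kind="stable")]
        chains.extend(_chain_split(pts, cfg.breakpoint_threshold_m))

    # merge chains whose closest points are within the same threshold:
    # chain adjacency lifted from the point-level proximity graph
    all_pts = np.concatenate(chains)
    chain_of = np.repeat(np.arange(len(chains)), [len(c) for c in chains])
    close = cdist(all_pts, all_pts) <= cfg.breakpoint_threshold_m
    n_chains = len(chains)
    indicator = np.zeros((n_chains, len(all_pts)), dtype=bool)
    indicator[chain_of, np.arange(len(all_pts))] = True
    adj = (indicator.astype(np.int32) @ close @ indicator.T.astype(np.int32)) > 0
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    clusters = []
    for k in range(n_comp):
        member = np.concatenate([chains[i] for i in np.flatnonzero(comp == k)])
        if len(member) >= cfg.min_cluster_size:
            clusters.append(Cluster(member))
    return clusters


def find_torso(clusters: Sequence[Cluster]) -> np.ndarray | None:
    """Centroid of the largest surviving cluster, or None when none survive."""
    if not clusters:
        return None
    best = max(clusters, key=lambda c: c.size)
    return best.centroid


def gate_by_body(cloud: PointCloud, body: np.ndarray, cfg: ClusterConfig) -> PointCloud:
    """Keep points within the body gate radius of the torso centroid
    (boundary inclusive); everything farther is treated as noise."""
    if len(cloud) == 0:
        return cloud
    d = np.hypot(*(cloud.xy - np.asarray(body)).T)
    return cloud.select(d <= cfg.body_gate_radius_m)


# -- leg estimation ----------------------------------------------------------


@dataclass(frozen=True)
class ParticleFilterConfig:
    n_particles: int = 500
    velocity_scale_range: tuple[float, float] = (0.5, 2.0)
    process_noise_sd_m: float = 0.03
    measurement_noise_sd_m: float = 0.03
    #: Measurements farther than this from every particle are ignored (the
    #: points belong to the other, visible leg); the filter then propagates
    #: its prior instead of being dragged onto the wrong target.
    measurement_gate_m: float = 0.15

    def __post_init__(self) -> None:
        if self.n_particles < 100:
            raise ValueError("need at least 100 particles")
        lo, hi = self.velocity_scale_range
        if not (0 < lo <= hi):
            raise ValueError("invalid velocity scale range")


TWO_CLUSTERS_KMEANS = "two_clusters_kmeans"
ONE_CLUSTER_MEASURED = "one_cluster_measured"
PARTICLE_FILTER = "particle_filter"

#: A single cluster whose largest pairwise extent exceeds this is two legs
#: walking through each other's angular shadow, not one leg: a shin section
#: is ~0.10 m across, so anything much longer gets split by k-means.
SPLIT_EXTENT_M = 0.18


@dataclass
class LegEstimate:
    """One shin position with provenance and dispersion; particle-filter
    estimates carry their particle set so occlusion can span frames."""

    position: np.ndarray
    provenance: str
    spread: float = 0.0
    particles: np.ndarray | None = None
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(2)


def _systematic_resample(particles: np.ndarray, weights: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    n = len(particles)
    positions = (rng.uniform(0.0, 1.0) + np.arange(n)) / n
    cum = np.cumsum(weights)
    cum[-1] = 1.0
    idx = np.searchsorted(cum, positions)
    return particles[idx]


def particle_filter_step(prev: LegEstimate, body_velocity: np.ndarray, dt: float,
                         cfg: ParticleFilterConfig, rng: np.random.Generator,
                         measurements: np.ndarray | None = None) -> LegEstimate:
    """One SIR predict/update/resample cycle for an occluded leg.

    Prediction moves each particle by the previous upper-body velocity
    scaled by a per-particle uniform draw from the configured range, plus
    Gaussian process noise.  With measurements, weights come from a
    Gaussian likelihood of each particle's distance to its nearest
    measurement point; without, the prior propagates unweighted.
    """
    n = cfg.n_particles
    if prev.particles is not None and len(prev.particles) == n:
        particles = prev.particles.copy()
    else:
        particles = prev.position + rng.normal(0.0, cfg.process_noise_sd_m, size=(n, 2))
    lo, hi = cfg.velocity_scale_range
    scale = rng.uniform(lo, hi, size=(n, 1))
    v = np.asarray(body_velocity, dtype=float).reshape(1, 2)
    particles = particles + v * scale * dt + rng.normal(0.0, cfg.process_noise_sd_m, size=(n, 2))

    weights = np.full(n, 1.0 / n)
    if measurements is not None and len(measurements) > 0:
        d = cdist(particles, np.asarray(measurements, dtype=float).reshape(-1, 2)).min(axis=1)
        if d.min() <= cfg.measurement_gate_m:
            logw = -0.5 * (d / cfg.measurement_noise_sd_m) ** 2
            logw -= logw.max()
            w = np.exp(logw)
            w_sum = w.sum()
            if w_sum > 0:
                weights = w / w_sum

    est = weights @ particles
    spread = float(np.sqrt((weights @ ((particles - est) ** 2).sum(axis=1))))
    resampled = _systematic_resample(particles, weights, rng)
    return LegEstimate(est, PARTICLE_FILTER, spread, particles=resampled)


def _kmeans_two(points: np.ndarray, init: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=50)
    labels = km.fit_predict(points)
    return km.cluster_centers_, labels


def _align_pair(candidates: Sequence[LegEstimate],
                reference: Sequence[np.ndarray] | None) -> tuple[LegEstimate, LegEstimate]:
    """Order a pair of estimates to match the reference pair by minimum
    total displacement (optimal for the 2x2 case)."""
    a, b = candidates
    if reference is None:
        return a, b
    p0, p1 = reference
    keep = (np.linalg.norm(a.position - p0) + np.linalg.norm(b.position - p1))
    swap = (np.linalg.norm(b.position - p0) + np.linalg.norm(a.position - p1))
    return (a, b) if keep <= swap else (b, a)


def extract_legs(clusters: Sequence[Cluster],
                 prev_legs: tuple[LegEstimate, LegEstimate] | None,
                 pf_cfg: ParticleFilterConfig,
                 body_velocity: np.ndarray,
                 dt: float,
                 rng: np.random.Generator,
                 gated_cloud: PointCloud | None = None,
                 predicted: Sequence[np.ndarray] | None = None,
                 split_extent_m: float = SPLIT_EXTENT_M) -> tuple[LegEstimate, LegEstimate] | None:
    """Produce the two per-frame leg estimates, or None while unresolved.

    The returned pair is ordered to correspond to ``prev_legs``.
    ``predicted`` optionally supplies short-horizon predicted positions of
    the two legs (e.g. constant-velocity extrapolations from their last
    measured positions); association uses them instead of the raw previous
    estimates, which stabilizes identities while legs merge and separate.
    Before initialization (no previous state) at least two clusters are
    required.
    """
    if predicted is None and prev_legs is not None:
        predicted = (prev_legs[0].position, prev_legs[1].position)

    if len(clusters) >= 2:
        two = sorted(clusters, key=lambda c: c.size, reverse=True)[:2]
        pooled = np.concatenate([c.points for c in two])
        init = np.vstack([c.centroid for c in two])
        centers, labels = _kmeans_two(pooled, init)
        ests = []
        for k in range(2):
            member = pooled[labels == k]
            spread = float(np.sqrt(((member - centers[k]) ** 2).sum(axis=1).mean())) if len(member) else 0.0
            ests.append(LegEstimate(centers[k], TWO_CLUSTERS_KMEANS, spread))
        return _align_pair(ests, predicted)

    if prev_legs is None:
        return None  # unresolved: tracking starts at the first two-cluster frame

    meas_pts = gated_cloud.xy if (gated_cloud is not None and len(gated_cloud) > 0) else None

    if len(clusters) == 1:
        c = clusters[0]
        d_pair = cdist(c.points, c.points)
        if d_pair.max() > split_extent_m:
            # merged double-leg blob: split it instead of ghosting one leg
            if predicted is not None:
                init = np.vstack(predicted)
            else:
                i, j = np.unravel_index(int(d_pair.argmax()), d_pair.shape)
                init = np.vstack([c.points[i], c.points[j]])
            centers, labels = _kmeans_two(c.points, init)
            ests = []
            for k in range(2):
                member = c.points[labels == k]
                spread = float(np.sqrt(((member - centers[k]) ** 2).sum(axis=1).mean())) if len(member) else 0.0
                ests.append(LegEstimate(centers[k], TWO_CLUSTERS_KMEANS, spread))
            return _align_pair(ests, predicted)
        measured = LegEstimate(c.centroid, ONE_CLUSTER_MEASURED,
                               float(np.sqrt(((c.points - c.centroid) ** 2).sum(axis=1).mean())))
        d0 = np.linalg.norm(measured.position - predicted[0])
        d1 = np.linalg.norm(measured.position - predicted[1])
        measured_slot = 0 if d0 <= d1 else 1
        # the occluded leg's filter weights against the gated points: while
        # the legs are merged the single cluster contains that leg's returns
        # too, and the measurement gate keeps a genuinely hidden leg from
        # being dragged onto the visible one
        filtered = particle_filter_step(prev_legs[1 - measured_slot], body_velocity,
                                        dt, pf_cfg, rng, meas_pts)
        pair: list[LegEstimate | None] = [None, None]
        pair[measured_slot] = measured
        pair[1 - measured_slot] = filtered
        return tuple(pair)  # already in prev order

    # no clusters: both legs filtered
    return (
        particle_filter_step(prev_legs[0], body_velocity, dt, pf_cfg, rng, meas_pts),
        particle_filter_step(prev_legs[1], body_velocity, dt, pf_cfg, rng, meas_pts),
    )
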