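"""Synthetic range-scan generator: a parametric walker raycast into
per-sensor polar scans, with exact ground truth.

The scene is a home-like room with static furniture (2-D line segments per
height band), three shin-height sensors and one torso-height sensor on the
perimeter.  A walker is modelled as two shin-height circles (the legs) and a
torso-height rectangle; its kinematics idealize gait as alternating single
support: at any instant one shin is stationary at its stance site while the
other travels two step lengths along the path with a half-sine speed
profile peaking mid-swing.  Foot exchange is instantaneous.  The torso moves
at the constant mean speed ``step_length / step_time``.

Each scan frame raycasts every beam against the static segments of the
sensor's height band plus the moving bodies; the returned range is the
nearest hit (occlusion is implicit), with i.i.d. Gaussian range noise added
to valid returns.  Beams with no hit inside ``max_range`` carry the sentinel.

Ground-truth identities hold exactly by construction::

    stride_length = 2 * step_length
    step_time     = 60 / cadence
    cycle_time    = 2 * step_time
    velocity      = step_length * cadence / 60
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .geometry import (
    SHIN,
    TORSO,
    PolarScan,
    SensorPose,
    SensorSpec,
    beam_directions,
)

# -- ray casting -------------------------------------------------------------


def ray_segment_ranges(origin: np.ndarray, dirs: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Nearest positive intersection range of each ray with a set of segments.

    ``dirs`` is (B, 2) unit vectors, ``segments`` is (S, 2, 2) endpoints.
    Returns (B,) ranges, ``inf`` where a ray hits nothing.
    """
    segments = np.asarray(segments, dtype=float).reshape(-1, 2, 2)
    B = len(dirs)
    if segments.size == 0:
        return np.full(B, np.inf)
    a = segments[:, 0]                       # (S, 2)
    r = segments[:, 1] - segments[:, 0]      # (S, 2)
    ao = a - np.asarray(origin, dtype=float)  # (S, 2)
    # Solve origin + t*d = a + u*r for each (beam, segment) pair.
    denom = dirs[:, 0:1] * r[None, :, 1] - dirs[:, 1:2] * r[None, :, 0]  # (B, S)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[None, :, 0] * r[None, :, 1] - ao[None, :, 1] * r[None, :, 0]) / denom
        u = (ao[None, :, 0] * dirs[:, 1:2] - ao[None, :, 1] * dirs[:, 0:1]) / denom
    valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (u >= 0.0) & (u <= 1.0)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def ray_circle_ranges(origin: np.ndarray, dirs: np.ndarray,
                      centers: np.ndarray, radius: float) -> np.ndarray:
    """Nearest positive intersection range of each ray with circles.

    ``centers`` is (C, 2).  Returns (B,) ranges, ``inf`` for misses.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    B = len(dirs)
    if centers.size == 0:
        return np.full(B, np.inf)
    oc = centers - np.asarray(origin, dtype=float)          # (C, 2)
    proj = dirs @ oc.T                                      # (B, C)
    d2 = (oc**2).sum(axis=1)[None, :] - proj**2             # squared miss distance
    disc = radius**2 - d2
    with np.errstate(invalid="ignore"):
        t = proj - np.sqrt(disc)
    valid = (disc >= 0.0) & (t > 1e-9)
    t = np.where(valid, t, np.inf)
    return t.min(axis=1)


def _finalize_ranges(ranges: np.ndarray, spec: SensorSpec,
                     rng: np.random.Generator | None, noise_sd: float) -> np.ndarray:
    """Apply max-range cutoff, additive noise and the no-return sentinel."""
    out = ranges.copy()
    miss = ~np.isfinite(out) | (out > spec.max_range_m)
    if noise_sd > 0 and rng is not None:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
        out = np.maximum(out, 1e-6)
    out[miss] = spec.invalid_value
    return out


def rectangle_segments(center: np.ndarray, tangent: np.ndarray,
                       width: float, depth: float) -> np.ndarray:
    """Four segments of a rectangle oriented with ``depth`` along ``tangent``
    and ``width`` perpendicular to it."""
    t = np.asarray(tangent, dtype=float)
    t = t / np.linalg.norm(t)
    n = np.array([-t[1], t[0]])
    c = np.asarray(center, dtype=float)
    corners = np.array([
        c + t * depth / 2 + n * width / 2,
        c - t * depth / 2 + n * width / 2,
        c - t * depth / 2 - n * width / 2,
        c + t * depth / 2 - n * width / 2,
    ])
    return np.stack([np.stack([corners[i], corners[(i + 1) % 4]]) for i in range(4)])


# -- room model --------------------------------------------------------------


@dataclass
class RoomModel:
    """Static occupancy of the room: line segments per height band, plus an
    axis-aligned extent ``((xmin, ymin), (xmax, ymax))``."""

    segments: dict[str, np.ndarray]
    extent: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.segments = {
            band: np.asarray(segs, dtype=float).reshape(-1, 2, 2)
            for band, segs in self.segments.items()
        }

    def band(self, band: str) -> np.ndarray:
        return self.segments.get(band, np.empty((0, 2, 2)))


def _rect_outline(x0, y0, x1, y1) -> list:
    return [
        [[x0, y0], [x1, y0]],
        [[x1, y0], [x1, y1]],
        [[x1, y1], [x0, y1]],
        [[x0, y1], [x0, y0]],
    ]


def default_room() -> RoomModel:
    """A ~8 m x 6 m living room: four walls in both height bands, plus
    shin-height furniture (couch, table, sideboard) clear of the walkway."""
    walls = _rect_outline(0.0, 0.0, 8.0, 6.0)
    furniture = (
        _rect_outline(2.0, 4.6, 4.0, 5.2)      # couch
        + _rect_outline(5.2, 4.3, 6.2, 5.0)    # table
        + _rect_outline(2.4, 0.0, 3.3, 0.30)   # sideboard
    )
    return RoomModel(
        segments={SHIN: np.asarray(walls + furniture), TORSO: np.asarray(walls)},
        extent=((0.0, 0.0), (8.0, 6.0)),
    )


def default_sensors() -> dict[str, SensorPose]:
    """Three shin-height sensors on the room perimeter plus one torso-height
    sensor, mirroring a walkway flanked by scanners at both ends and one side."""
    poses = [
        SensorPose("shin1", 0.25, 2.0, 0.0, SHIN),
        SensorPose("shin2", 4.0, 0.35, 90.0, SHIN),
        SensorPose("shin3", 7.75, 2.0, 180.0, SHIN),
        SensorPose("torso1", 4.0, 5.75, 270.0, TORSO),
    ]
    return {p.sensor_id: p for p in poses}


# -- walker ------------------------------------------------------------------


class PolylinePath:
    """Arclength-parameterized polyline with linear extrapolation at the ends."""

    def __init__(self, waypoints: Sequence[Sequence[float]]):
        pts = np.asarray(waypoints, dtype=float).reshape(-1, 2)
        seg = np.diff(pts, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        keep = lens > 1e-12
        if not keep.any():
            raise ValueError("path needs at least two distinct waypoints")
        self.pts = np.vstack([pts[:-1][keep], pts[-1]])
        seg = np.diff(self.pts, axis=0)
        self.seg = seg
        self.lens = np.hypot(seg[:, 0], seg[:, 1])
        self.cum = np.concatenate([[0.0], np.cumsum(self.lens)])

    @property
    def length(self) -> float:
        return float(self.cum[-1])

    def _segment_index(self, s: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.cum, s, side="right") - 1
        return np.clip(idx, 0, len(self.seg) - 1)

    def point(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = self._segment_index(s)
        frac = (s - self.cum[idx]) / self.lens[idx]
        return self.pts[idx] + frac[:, None] * self.seg[idx]

    def tangent(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = self._segment_index(s)
        return self.seg[idx] / self.lens[idx, None]

    def normal(self, s) -> np.ndarray:
        t = self.tangent(s)
        return np.column_stack([-t[:, 1], t[:, 0]])


def straight_walkway() -> PolylinePath:
    """The default 6.3 m straight walk along the room's main corridor."""
    return PolylinePath([[0.7, 2.0], [7.0, 2.0]])


def uturn_path(marker: tuple[float, float] = (4.0, 2.6), radius: float = 0.6) -> PolylinePath:
    """Out along the corridor, a semicircular turn around the marker, back."""
    mx, my = marker
    theta = np.deg2rad(np.arange(-90.0, 90.0 + 1e-9, 10.0))
    arc = np.column_stack([mx + radius * np.cos(theta), my + radius * np.sin(theta)])
    way = np.vstack([[0.7, my - radius], arc, [0.7, my + radius]])
    return PolylinePath(way)


@dataclass
class WalkSpec:
    """Ground-truth parameterization of one simulated walk."""

    step_length_m: float = 0.60
    cadence_spm: float = 60.0
    step_width_m: float = 0.07
    leg_diameter_m: float = 0.10
    torso_width_m: float = 0.45
    torso_depth_m: float = 0.18
    range_noise_sd_m: float = 0.01
    tail_s: float = 0.5
    seed: int = 0
    path: PolylinePath | None = None

    def __post_init__(self) -> None:
        if self.step_length_m <= 0 or self.cadence_spm <= 0:
            raise ValueError("step length and cadence must be positive")
        if self.step_width_m < 0 or self.range_noise_sd_m < 0:
            raise ValueError("step width and noise sd must be non-negative")

    @property
    def step_time_s(self) -> float:
        return 60.0 / self.cadence_spm

    @property
    def mean_velocity_ms(self) -> float:
        return self.step_length_m * self.cadence_spm / 60.0


@dataclass
class GroundTruth:
    """Per-frame true body positions and per-walk true gait parameters."""

    times: np.ndarray
    left: np.ndarray
    right: np.ndarray
    torso: np.ndarray
    stance_events: dict[str, list[tuple[float, float, float]]]
    step_length_m: float
    step_time_s: float
    cadence_spm: float

    @property
    def stride_length_m(self) -> float:
        return 2.0 * self.step_length_m

    @property
    def cycle_time_s(self) -> float:
        return 2.0 * self.step_time_s

    @property
    def mean_velocity_ms(self) -> float:
        return self.step_length_m / self.step_time_s


def walker_trajectory(walk: WalkSpec, path: PolylinePath, times: np.ndarray):
    """Left/right shin centers and torso center at each time.

    The walk starts mid-gait: the left foot is in stance at arclength 0 and
    the right foot is mid-swing from −L toward +L, so the recording contains
    no artificial double-stance at a single site.  Stance sites are at
    arclength ``k·L`` (left at even k, right at odd k); swing *j* occupies
    ``[j·T, (j+1)·T)`` and moves the foot landing at site ``j+1``.
    """
    L, T, w = walk.step_length_m, walk.step_time_s, walk.step_width_m
    K = int(np.floor(path.length / L))  # last stance site index
    if K < 1:
        raise ValueError("path too short for a single step")
    t = np.asarray(times, dtype=float)
    j = np.clip(np.floor(t / T).astype(int), 0, K - 1)
    tau = np.clip((t - j * T) / T, 0.0, 1.0)
    moving_s = (j - 1) * L + L * (1.0 - np.cos(np.pi * tau))
    stance_s = j * L
    left_moving = (j + 1) % 2 == 0
    left_s = np.where(left_moving, moving_s, stance_s)
    right_s = np.where(~left_moving, moving_s, stance_s)
    left = path.point(left_s) + 0.5 * w * path.normal(left_s)
    right = path.point(right_s) - 0.5 * w * path.normal(right_s)
    # constant mean speed along the path, stopping over the final feet
    torso_s = np.minimum(-L / 2.0 + (L / T) * t, (2 * K - 1) * L / 2.0)
    torso = path.point(torso_s)
    heading = path.tangent(torso_s)

    events: dict[str, list[tuple[float, float, float]]] = {"left": [], "right": []}
    t_end = float(t[-1]) if len(t) else K * T
    for k in range(0, K + 1):
        label = "left" if k % 2 == 0 else "right"
        t_mid = min((k + 0.5) * T, (k * T + t_end) / 2.0)
        if k * T > t_end:
            break
        s = k * L
        side = 0.5 * w if label == "left" else -0.5 * w
        pos = (path.point(s) + side * path.normal(s))[0]
        events[label].append((t_mid, float(pos[0]), float(pos[1])))
    return left, right, torso, heading, events, K


# -- scene synthesis ---------------------------------------------------------


def _static_scene_ranges(room: RoomModel, poses: Mapping[str, SensorPose],
                         spec: SensorSpec) -> dict[str, np.ndarray]:
    out = {}
    for sid, pose in poses.items():
        dirs = beam_directions(pose, spec)
        out[sid] = ray_segment_ranges(pose.origin, dirs, room.band(pose.height_band))
    return out


def synthesize_background(room: RoomModel, poses: Mapping[str, SensorPose],
                          spec: SensorSpec, n_frames: int = 2000,
                          noise_sd: float = 0.01, seed: int = 0) -> dict[str, list[PolarScan]]:
    """Raycast the static room ``n_frames`` times with independent noise.

    The duration is ``n_frames / scan_rate`` (2000 frames at 40 Hz = 50 s).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    rng = np.random.default_rng(seed)
    static = _static_scene_ranges(room, poses, spec)
    times = np.arange(n_frames) * spec.scan_period_s
    scans: dict[str, list[PolarScan]] = {}
    for sid, base in static.items():
        block = np.broadcast_to(base, (n_frames, len(base))).copy()
        miss = ~np.isfinite(block) | (block > spec.max_range_m)
        if noise_sd > 0:
            block += rng.normal(0.0, noise_sd, size=block.shape)
            block = np.maximum(block, 1e-6)
        block[miss] = spec.invalid_value
        scans[sid] = [PolarScan(sid, float(times[i]), block[i]) for i in range(n_frames)]
    return scans


def synthesize_walk(walk: WalkSpec, room: RoomModel, poses: Mapping[str, SensorPose],
                    spec: SensorSpec) -> tuple[dict[str, list[PolarScan]], GroundTruth]:
    """Simulate a full walk and raycast it into per-sensor scan sequences."""
    path = walk.path if walk.path is not None else straight_walkway()
    (lo, hi) = room.extent
    for p in path.pts:
        if not (lo[0] <= p[0] <= hi[0] and lo[1] <= p[1] <= hi[1]):
            raise ValueError("walk path leaves the room extent")
    rng = np.random.default_rng(walk.seed)
    T = walk.step_time_s
    K = int(np.floor(path.length / walk.step_length_m))
    t_end = K * T + walk.tail_s
    times = np.arange(0.0, t_end, spec.scan_period_s)
    left, right, torso, heading, events, K = walker_trajectory(walk, path, times)

    static = _static_scene_ranges(room, poses, spec)
    scans: dict[str, list[PolarScan]] = {sid: [] for sid in poses}
    for sid, pose in poses.items():
        dirs = beam_directions(pose, spec)
        base = static[sid]
        for i, t in enumerate(times):
            if pose.height_band == SHIN:
                dyn = ray_circle_ranges(pose.origin, dirs,
                                        np.vstack([left[i], right[i]]),
                                        walk.leg_diameter_m / 2.0)
            else:
                rect = rectangle_segments(torso[i], heading[i],
                                          walk.torso_width_m, walk.torso_depth_m)
                dyn = ray_segment_ranges(pose.origin, dirs, rect)
            merged = np.minimum(base, dyn)
            ranges = _finalize_ranges(merged, spec, rng, walk.range_noise_sd_m)
            scans[sid].append(PolarScan(sid, float(t), ranges))

    truth = GroundTruth(times, left, right, torso, events,
                        walk.step_length_m, walk.step_time_s, walk.cadence_spm)
    return scans, truth


@dataclass
class StaticLegScene:
    """Long-term static test scene: two shin-height pipes plus a torso-height
    box, raycast over a multi-hour span; frames are produced in chunks so a
    12 h recording never has to be materialized at once."""

    room: RoomModel
    poses: Mapping[str, SensorPose]
    spec: SensorSpec
    duration_s: float
    sample_rate_hz: float
    pipe_centers: np.ndarray
    pipe_diameter_m: float
    box_center: np.ndarray
    box_width_m: float
    box_depth_m: float
    noise_sd: float
    seed: int

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.sample_rate_hz))

    def true_ranges(self) -> dict[str, np.ndarray]:
        """Noise-free ranges of the static scene, per sensor."""
        out = {}
        box = rectangle_segments(self.box_center, np.array([1.0, 0.0]),
                                 self.box_width_m, self.box_depth_m)
        for sid, pose in self.poses.items():
            dirs = beam_directions(pose, self.spec)
            base = ray_segment_ranges(pose.origin, dirs, self.room.band(pose.height_band))
            if pose.height_band == SHIN:
                dyn = ray_circle_ranges(pose.origin, dirs, self.pipe_centers,
                                        self.pipe_diameter_m / 2.0)
            else:
                dyn = ray_segment_ranges(pose.origin, dirs, box)
            out[sid] = np.minimum(base, dyn)
        return out

    def iter_chunks(self, chunk_frames: int = 900) -> Iterator[tuple[np.ndarray, dict[str, np.ndarray]]]:
        """Yield ``(times, {sensor: (F, B) ranges})`` chunks with noise applied."""
        rng = np.random.default_rng(self.seed)
        base = self.true_ranges()
        dt = 1.0 / self.sample_rate_hz
        n = self.n_frames
        for start in range(0, n, chunk_frames):
            stop = min(start + chunk_frames, n)
            times = (np.arange(start, stop)) * dt
            block: dict[str, np.ndarray] = {}
            for sid, b in base.items():
                arr = np.broadcast_to(b, (stop - start, len(b))).copy()
                miss = ~np.isfinite(arr) | (arr > self.spec.max_range_m)
                if self.noise_sd > 0:
                    arr += rng.normal(0.0, self.noise_sd, size=arr.shape)
                    arr = np.maximum(arr, 1e-6)
                arr[miss] = self.spec.invalid_value
                block[sid] = arr
            yield times, block


def synthesize_static_legs(room: RoomModel, poses: Mapping[str, SensorPose],
                           spec: SensorSpec, duration_h: float = 12.0,
                           pipe_diameter_m: float = 0.10,
                           pipe_spacing_m: float = 0.25,
                           box_width_m: float = 0.45,
                           noise_sd: float = 0.005,
                           sample_rate_hz: float | None = None,
                           center: tuple[float, float] = (4.0, 2.9),
                           seed: int = 0) -> StaticLegScene:
    """Build the two-pipe + cardboard-box long-term scene.

    ``sample_rate_hz`` defaults to the scanner rate; pass a lower value to
    down-sample multi-hour recordings.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    cx, cy = center
    pipes = np.array([[cx - pipe_spacing_m / 2.0, cy], [cx + pipe_spacing_m / 2.0, cy]])
    return StaticLegScene(
        room=room, poses=poses, spec=spec,
        duration_s=duration_h * 3600.0,
        sample_rate_hz=spec.scan_rate_hz if sample_rate_hz is None else sample_rate_hz,
        pipe_centers=pipes, pipe_diameter_m=pipe_diameter_m,
        box_center=np.array([cx, cy]), box_width_m=box_width_m, box_depth_m=0.30,
        noise_sd=noise_sd, seed=seed,
    )


# -- presets -----------------------------------------------------------------

#: The study's fixed walk conditions (step length m / cadence steps-per-min)
#: plus self-paced and u-turn walks.
WALK_PRESETS: dict[str, WalkSpec] = {
    "free": WalkSpec(step_length_m=0.65, cadence_spm=105.0),
    "30-100": WalkSpec(step_length_m=0.30, cadence_spm=100.0),
    "30-120": WalkSpec(step_length_m=0.30, cadence_spm=120.0),
    "60-60": WalkSpec(step_length_m=0.60, cadence_spm=60.0),
    "60-120": WalkSpec(step_length_m=0.60, cadence_spm=120.0),
    "uturn": WalkSpec(step_length_m=0.60, cadence_spm=90.0, path=None),
}


def preset_walk(name: str, seed: int = 7) -> WalkSpec:
    if name not in WALK_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(WALK_PRESETS)}")
    w = replace(WALK_PRESETS[name], seed=seed)
    if name == "uturn":
        w = replace(w, path=uturn_path())
    return w
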