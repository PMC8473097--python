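"""Sensor geometry: planar LiDAR specifications, polar/Cartesian transforms,
and beam-coverage arithmetic.

A planar LiDAR sweeps a fixed angular window (here 270°) once per revolution
and reports one range per beam.  The scanners modelled here acquire 2162
points per turn at 40 Hz, giving an angular resolution of ~0.125°.  Beam
index 0 points at −window/2 relative to the sensor heading, so the window is
symmetric about the heading.  All lengths are metres; angles are degrees in
interfaces and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

SHIN = "shin"
TORSO = "torso"
HEIGHT_BANDS = (SHIN, TORSO)


@dataclass(frozen=True)
class SensorSpec:
    """Static acquisition parameters of one scanner model.

    ``invalid_value`` is the sentinel stored for beams with no return; it is
    non-positive so that ``ranges > 0`` selects valid beams.
    """

    points_per_turn: int = 2162
    window_deg: float = 270.0
    scan_rate_hz: float = 40.0
    max_range_m: float = 20.0
    invalid_value: float = 0.0

    def __post_init__(self) -> None:
        if self.points_per_turn <= 0:
            raise ValueError("points_per_turn must be positive")
        if self.window_deg <= 0 or self.scan_rate_hz <= 0:
            raise ValueError("window and scan rate must be positive")
        if self.invalid_value > 0:
            raise ValueError("invalid_value must be non-positive")

    @property
    def angular_step_deg(self) -> float:
        """Exact beam-to-beam angular increment (window / points per turn)."""
        return self.window_deg / self.points_per_turn

    @property
    def scan_period_s(self) -> float:
        return 1.0 / self.scan_rate_hz

    def beam_angles_deg(self) -> np.ndarray:
        """Beam directions relative to the sensor heading, degrees.

        Beam 0 points at −window/2 so the sweep is symmetric about heading.
        """
        return -self.window_deg / 2.0 + np.arange(self.points_per_turn) * self.angular_step_deg


@dataclass(frozen=True)
class SensorPose:
    """Rigid mounting pose of one sensor in the room frame.

    ``height_band`` selects the pipeline branch: shin-height sensors feed leg
    tracking, the torso-height sensor feeds body tracking.
    """

    sensor_id: str
    x: float
    y: float
    heading_deg: float
    height_band: str = SHIN

    def __post_init__(self) -> None:
        if self.height_band not in HEIGHT_BANDS:
            raise ValueError(f"unknown height band {self.height_band!r}")

    @property
    def origin(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class PolarScan:
    """One 270° sweep from one sensor at one timestamp."""

    sensor_id: str
    timestamp: float
    ranges: np.ndarray

    def __post_init__(self) -> None:
        self.ranges = np.asarray(self.ranges, dtype=float)

    def valid_mask(self, spec: SensorSpec | None = None) -> np.ndarray:
        m = self.ranges > 0
        if spec is not None:
            m &= self.ranges <= spec.max_range_m
        return m


@dataclass
class PointCloud:
    """2-D points in the room frame with per-point sensor provenance."""

    timestamp: float
    xy: np.ndarray
    sensor_id: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        self.sensor_id = np.asarray(self.sensor_id)
        if len(self.sensor_id) != len(self.xy):
            raise ValueError("xy and sensor_id length mismatch")

    def __len__(self) -> int:
        return len(self.xy)

    @classmethod
    def empty(cls, timestamp: float = 0.0) -> "PointCloud":
        return cls(timestamp, np.empty((0, 2)), np.empty(0, dtype=object))

    @classmethod
    def concatenate(cls, clouds: Sequence["PointCloud"], timestamp: float | None = None) -> "PointCloud":
        clouds = [c for c in clouds if c is not None]
        if not clouds:
            return cls.empty(0.0 if timestamp is None else timestamp)
        t = clouds[0].timestamp if timestamp is None else timestamp
        return cls(
            t,
            np.concatenate([c.xy for c in clouds]),
            np.concatenate([c.sensor_id for c in clouds]),
        )

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(self.timestamp, self.xy[mask], self.sensor_id[mask])


def beam_directions(pose: SensorPose, spec: SensorSpec) -> np.ndarray:
    """Unit direction vectors of all beams in the room frame, shape (B, 2)."""
    ang = np.deg2rad(pose.heading_deg + spec.beam_angles_deg())
    return np.column_stack([np.cos(ang), np.sin(ang)])


def polar_to_cartesian(scan: PolarScan, pose: SensorPose, spec: SensorSpec) -> PointCloud:
    """Project a polar scan into room-frame Cartesian points.

    Sentinel (no-return) beams are excluded.  The mapping is rigid: beam *i*
    at range *r* maps to ``pose.origin + r * (cos, sin)(heading − window/2 +
    i·angular_step)``.
    """
    if len(scan.ranges) != spec.points_per_turn:
        raise ValueError(
            f"scan has {len(scan.ranges)} ranges, spec expects {spec.points_per_turn}"
        )
    mask = scan.valid_mask(spec)
    dirs = beam_directions(pose, spec)[mask]
    pts = pose.origin + scan.ranges[mask, None] * dirs
    ids = np.full(len(pts), scan.sensor_id, dtype=object)
    return PointCloud(scan.timestamp, pts, ids)


def cartesian_to_polar(points: np.ndarray, pose: SensorPose) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of the beam projection: (ranges, bearing degrees rel. heading)."""
    d = np.asarray(points, dtype=float).reshape(-1, 2) - pose.origin
    ranges = np.hypot(d[:, 0], d[:, 1])
    bearing = np.rad2deg(np.arctan2(d[:, 1], d[:, 0])) - pose.heading_deg
    bearing = (bearing + 180.0) % 360.0 - 180.0
    return ranges, bearing


def angular_resolution(window_deg: float, points_per_turn: int) -> float:
    """Angular step of a scanner covering ``window_deg`` with ``points_per_turn`` beams."""
    if points_per_turn <= 0:
        raise ValueError("points_per_turn must be positive")
    return window_deg / points_per_turn


def beams_on_target(
    diameter_m: float, distance_m: float, angular_step_deg: float = 0.125
) -> tuple[int, float]:
    """Number of beams subtending a circular target of given diameter.

    The target subtends ``2·atan((d/2)/D)`` degrees; the count is the floor
    of that width divided by the angular step.  Returns ``(count,
    quotient)`` with the unrounded quotient alongside.
    """
    if diameter_m <= 0:
        raise ValueError("diameter must be positive")
    if distance_m <= diameter_m / 2.0:
        raise ValueError("distance must exceed the target radius")
    if angular_step_deg <= 0:
        raise ValueError("angular step must be positive")
    width_deg = 2.0 * math.degrees(math.atan((diameter_m / 2.0) / distance_m))
    quotient = width_deg / angular_step_deg
    return int(math.floor(quotient)), quotient
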