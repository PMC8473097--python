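"""Spatial and temporal multi-sensor registration.

Sensors are mounted rigidly, so the spatial alignment is the fixed
polar-to-Cartesian transform per sensor pose (see :mod:`gaitlidar.geometry`).
Temporal registration anchors frames on a reference sensor's timestamps and
attaches, for every other sensor, the scan with minimal |Δt| within a
tolerance (default half the scan period, boundary inclusive).  Matching is
monotone two-pointer, so each scan is consumed at most once and frame times
are strictly increasing.  After registration the shin-level foreground
clouds are overlaid into one cloud per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .geometry import (
    SHIN,
    TORSO,
    PointCloud,
    PolarScan,
    SensorPose,
    SensorSpec,
    polar_to_cartesian,
)


@dataclass
class RegisteredFrame:
    """One time-aligned frame: per-sensor foreground clouds in room frame."""

    time: float
    shin_clouds: dict[str, PointCloud]
    torso_cloud: PointCloud | None
    contributing: dict[str, float]  # sensor_id -> scan timestamp


def match_timestamps(reference: Sequence[float], other: Sequence[float],
                     tolerance: float) -> list[tuple[int, int]]:
    """Monotone minimal-|Δt| matching of ``other`` onto ``reference``.

    Both sequences must be sorted.  Each element is used at most once; a
    pair is kept when |Δt| ≤ tolerance (boundary counts as matched).
    """
    pairs: list[tuple[int, int]] = []
    j = 0
    n = len(other)
    tol = tolerance + 1e-12  # float guard: a half-period offset counts as matched
    for i, t in enumerate(reference):
        while j + 1 < n and abs(other[j + 1] - t) <= abs(other[j] - t):
            j += 1
        if j < n and abs(other[j] - t) <= tol:
            pairs.append((i, j))
            j += 1
        if j >= n:
            break
    return pairs


def register_time(scans_by_sensor: Mapping[str, Sequence[PolarScan]],
                  reference_sensor: str,
                  tolerance: float) -> list[dict[str, PolarScan]]:
    """Group scans into frames anchored on the reference sensor.

    Returns one dict per frame mapping sensor id to its attached scan; the
    reference sensor is always present, others only when a scan falls
    within the tolerance.
    """
    if reference_sensor not in scans_by_sensor or not scans_by_sensor[reference_sensor]:
        raise ValueError(f"empty reference stream {reference_sensor!r}")
    ref = scans_by_sensor[reference_sensor]
    frames: list[dict[str, PolarScan]] = [{reference_sensor: s} for s in ref]
    ref_times = [s.timestamp for s in ref]
    for sid, seq in scans_by_sensor.items():
        if sid == reference_sensor:
            continue
        times = [s.timestamp for s in seq]
        for i, j in match_timestamps(ref_times, times, tolerance):
            frames[i][sid] = seq[j]
    return frames


def build_frames(scans_by_sensor: Mapping[str, Sequence[PolarScan]],
                 poses: Mapping[str, SensorPose],
                 spec: SensorSpec,
                 reference_sensor: str | None = None,
                 tolerance: float | None = None) -> list[RegisteredFrame]:
    """Time-register foreground scans and project them into room-frame clouds.

    The reference sensor defaults to the torso sensor (it drives the body
    gate); the tolerance defaults to half the scan period.
    """
    if reference_sensor is None:
        torso_ids = [sid for sid, p in poses.items() if p.height_band == TORSO]
        reference_sensor = torso_ids[0] if torso_ids else next(iter(scans_by_sensor))
    if tolerance is None:
        tolerance = spec.scan_period_s / 2.0
    grouped = register_time(scans_by_sensor, reference_sensor, tolerance)
    frames: list[RegisteredFrame] = []
    for group in grouped:
        t = group[reference_sensor].timestamp
        shin: dict[str, PointCloud] = {}
        torso_cloud: PointCloud | None = None
        contributing: dict[str, float] = {}
        for sid, scan in group.items():
            contributing[sid] = scan.timestamp
            cloud = polar_to_cartesian(scan, poses[sid], spec)
            cloud.timestamp = t
            if poses[sid].height_band == SHIN:
                shin[sid] = cloud
            else:
                torso_cloud = cloud
        frames.append(RegisteredFrame(t, shin, torso_cloud, contributing))
    return frames


def overlay_shin(frame: RegisteredFrame) -> PointCloud:
    """Union of all shin-sensor foreground points, provenance preserved.

    Set semantics: the result is independent of sensor order (points are
    concatenated in sorted sensor order)."""
    clouds = [frame.shin_clouds[sid] for sid in sorted(frame.shin_clouds)]
    return PointCloud.concatenate(clouds, timestamp=frame.time)
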