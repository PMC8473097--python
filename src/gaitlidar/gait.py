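"""Velocity profiles, stance/swing event detection, and spatio-temporal
gait parameters.

Each leg's speed profile is the centred finite difference of its track,
smoothed with a centred moving average (edge frames use the available
partial window).  Stance instants are the speed minima of contiguous
below-ceiling regions — the ceiling is a fraction of the profile's 90th
percentile, which keeps mid-swing ripples from registering as stance — and
the swing peak between two stance instants is the global speed maximum
there.  From the alternating event series:

* stride length / cycle time: distance / time between consecutive stance
  events of the *same* leg;
* step length / step time: distance / time between a stance event and the
  preceding stance event of the *opposite* leg;
* cadence: ``60 · steps / (last − first stance time)`` over the whole walk;
* velocity: torso path length over the same span, from the smoothed torso
  track sampled at the stance times (no straight-line assumption).

Distances are straight-line chords between stance positions, as measured
by a pressure-sensitive walkway.  Outputs are cm, s, steps/min and cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import LegTrack

#: A speed minimum only counts as stance below this fraction of the
#: profile's 90th percentile speed.
STANCE_CEILING_FRACTION = 0.25

#: Two stance candidates are distinct only if the speed between them rises
#: above this fraction of the 90th percentile (a genuine swing); otherwise
#: they are the same stance disturbed by estimation noise and are merged.
SWING_FLOOR_FRACTION = 0.5


@dataclass
class VelocityProfile:
    label: str
    times: np.ndarray
    speed_cms: np.ndarray
    window: int


@dataclass
class GaitEventSeries:
    """Alternating stance minima and swing maxima for one leg."""

    label: str
    stance: np.ndarray          # (K, 3): t, x, y
    swing_times: np.ndarray     # (K-1,) peaks between consecutive stances
    #: stance phases cut off by the recording boundary; their instants are
    #: biased toward the interior and are excluded from temporal parameters
    #: when trimming is requested
    truncated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.truncated is None:
            self.truncated = np.zeros(len(self.stance), dtype=bool)

    @property
    def n_stance(self) -> int:
        return len(self.stance)


@dataclass
class GaitParameters:
    """Per-event series and summary statistics of the six gait parameters."""

    step_length_cm: np.ndarray
    step_time_s: np.ndarray
    stride_length_cm: np.ndarray
    cycle_time_s: np.ndarray
    cadence_spm: float | None
    velocity_cms: float | None

    def summary(self) -> dict[str, float | None]:
        def ms(x):
            return (float(np.mean(x)), float(np.std(x))) if len(x) else (None, None)

        out: dict[str, float | None] = {}
        for name, arr in [("step_length_cm", self.step_length_cm),
                          ("step_time_s", self.step_time_s),
                          ("stride_length_cm", self.stride_length_cm),
                          ("cycle_time_s", self.cycle_time_s)]:
            m, s = ms(arr)
            out[f"{name}_mean"], out[f"{name}_sd"] = m, s
        out["cadence_spm"] = self.cadence_spm
        out["velocity_cms"] = self.velocity_cms
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, arr in [("step_length_cm", self.step_length_cm),
                          ("step_time_s", self.step_time_s),
                          ("stride_length_cm", self.stride_length_cm),
                          ("cycle_time_s", self.cycle_time_s)]:
            for i, v in enumerate(arr):
                rows.append({"parameter": name, "event": i, "value": float(v)})
        if self.cadence_spm is not None:
            rows.append({"parameter": "cadence_spm", "event": 0, "value": self.cadence_spm})
        if self.velocity_cms is not None:
            rows.append({"parameter": "velocity_cms", "event": 0, "value": self.velocity_cms})
        return pd.DataFrame(rows, columns=["parameter", "event", "value"])


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; edges average over the available window."""
    return pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()


def velocity_profile(track: LegTrack, window: int = 9) -> VelocityProfile:
    """Smoothed speed profile (cm/s) from a leg track via centred differences."""
    t, xy = track.times, track.xy
    if len(t) < window + 1:
        raise ValueError("track shorter than the smoothing window")
    if np.any(np.diff(t) <= 0):
        raise ValueError("track has non-increasing timestamps")
    speed = np.empty(len(t))
    speed[1:-1] = np.hypot(*(xy[2:] - xy[:-2]).T) / (t[2:] - t[:-2])
    speed[0] = np.hypot(*(xy[1] - xy[0])) / (t[1] - t[0])
    speed[-1] = np.hypot(*(xy[-1] - xy[-2])) / (t[-1] - t[-2])
    smooth = moving_average(speed, window)
    return VelocityProfile(track.label, t, smooth * 100.0, window)


def detect_events(profile: VelocityProfile, track: LegTrack,
                  stance_ceiling_fraction: float = STANCE_CEILING_FRACTION,
                  swing_floor_fraction: float = SWING_FLOOR_FRACTION) -> GaitEventSeries:
    """Stance minima and swing maxima of one leg's speed profile.

    Each contiguous region with speed below the stance ceiling yields one
    stance candidate at its minimum-speed sample (the middle one on
    plateaus).  Candidates not separated by a genuine swing — the speed
    between them never reaching the swing floor — are merged, keeping the
    slower one.  The global maximum between consecutive stance events is
    the swing peak.
    """
    v = profile.speed_cms
    if len(v) == 0:
        raise ValueError("empty velocity profile")
    p90 = np.percentile(v, 90)
    ceiling = stance_ceiling_fraction * p90
    swing_floor = swing_floor_fraction * p90
    below = v < ceiling
    # contiguous below-ceiling regions
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = [0] if below[0] else []
    starts += [int(e) + 1 for e in edges if not below[e]]
    ends = [int(e) + 1 for e in edges if below[e]]
    if below[-1]:
        ends.append(len(v))

    # regions not separated by a genuine swing are one stance disturbed by
    # estimation wobble: union them
    regions: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if regions and v[regions[-1][1] - 1:s + 1].max() < swing_floor:
            regions[-1] = (regions[-1][0], e)
        else:
            regions.append((s, e))
    # the stance position comes from the minimum-speed sample (the foot is
    # stationary there); the stance instant is the middle of the region
    # expanded to the surrounding genuine-swing boundaries, which stays
    # unbiased when estimation wobble clips one side of the region
    stance_rows = []
    truncated_rows = []
    for s, e in regions:
        pos_i = s + int(v[s:e].argmin())
        while s > 0 and v[s - 1] < swing_floor:
            s -= 1
        while e < len(v) and v[e] < swing_floor:
            e += 1
        mid = (s + e - 1) // 2
        stance_rows.append([profile.times[mid], track.xy[pos_i, 0], track.xy[pos_i, 1]])
        truncated_rows.append(s == 0 or e == len(v))
    stance_idx = [int(np.searchsorted(profile.times, row[0])) for row in stance_rows]
    stance = np.asarray(stance_rows, dtype=float).reshape(-1, 3)
    truncated = np.asarray(truncated_rows, dtype=bool)
    swing = []
    for i0, i1 in zip(stance_idx[:-1], stance_idx[1:]):
        j = i0 + int(np.argmax(v[i0:i1 + 1]))
        swing.append(profile.times[j])
    return GaitEventSeries(profile.label, stance, np.asarray(swing), truncated)


def _torso_path_length(torso_times: np.ndarray, torso_xy: np.ndarray,
                       stance_times: np.ndarray, window: int) -> float:
    """Torso path length over the stance span, via chords of the smoothed
    torso track sampled at the stance times."""
    sm = np.column_stack([moving_average(torso_xy[:, 0], window),
                          moving_average(torso_xy[:, 1], window)])
    xs = np.interp(stance_times, torso_times, sm[:, 0])
    ys = np.interp(stance_times, torso_times, sm[:, 1])
    return float(np.hypot(np.diff(xs), np.diff(ys)).sum())


def compute_gait_parameters(events_left: GaitEventSeries | None,
                            events_right: GaitEventSeries | None,
                            torso_times: np.ndarray | None = None,
                            torso_xy: np.ndarray | None = None,
                            smoothing_window: int = 9,
                            trim_incomplete: bool = False) -> GaitParameters:
    """Spatio-temporal gait parameters from both legs' stance events.

    Missing opposite-leg events leave the step metrics empty while stride
    metrics are still produced; fewer than two stance events on both legs
    yields an empty parameter set (nothing is fabricated).

    ``trim_incomplete`` drops stance events whose stance phase was cut off
    by the recording boundary: their detected instants are biased, which
    distorts cadence and the boundary step times.
    """
    per_leg = {"left": events_left, "right": events_right}
    merged = []
    for label, ev in per_leg.items():
        if ev is None:
            continue
        for (t, x, y), cut in zip(ev.stance, ev.truncated):
            if trim_incomplete and cut:
                continue
            merged.append((t, x, y, label))
    merged.sort(key=lambda r: r[0])

    strides, cycles = [], []
    for label in per_leg:
        ev = [(t, x, y) for t, x, y, l in merged if l == label]
        if len(ev) < 2:
            continue
        arr = np.asarray(ev)
        strides.extend(np.hypot(*np.diff(arr[:, 1:3], axis=0).T) * 100.0)
        cycles.extend(np.diff(arr[:, 0]))

    # step length is measured along the local line of progression (as a
    # pressure walkway reports it): the raw chord between opposite-foot
    # stance positions also contains the lateral step width, which would
    # inflate short steps by ~1 cm and break stride ≈ 2·step
    pts = np.array([[x, y] for _, x, y, _ in merged], dtype=float).reshape(-1, 2)
    steps, step_times = [], []
    for i in range(len(merged) - 1):
        if merged[i][3] == merged[i + 1][3]:
            continue
        vec = pts[i + 1] - pts[i]
        if i >= 1:
            ref = pts[i + 1] - pts[i - 1]   # same-leg stride spanning this step
        elif i + 2 < len(pts):
            ref = pts[i + 2] - pts[i]
        else:
            ref = vec
        norm = np.linalg.norm(ref)
        u = ref / norm if norm > 0 else vec / max(np.linalg.norm(vec), 1e-12)
        steps.append(abs(float(vec @ u)) * 100.0)
        step_times.append(merged[i + 1][0] - merged[i][0])

    cadence = None
    velocity = None
    if len(merged) >= 2:
        span = merged[-1][0] - merged[0][0]
        if span > 0:
            cadence = 60.0 * (len(merged) - 1) / span
            if torso_times is not None and torso_xy is not None:
                stance_t = np.array([r[0] for r in merged])
                path = _torso_path_length(torso_times, torso_xy, stance_t, smoothing_window)
                velocity = 100.0 * path / span

    return GaitParameters(
        step_length_cm=np.asarray(steps),
        step_time_s=np.asarray(step_times),
        stride_length_cm=np.asarray(strides),
        cycle_time_s=np.asarray(cycles),
        cadence_spm=cadence,
        velocity_cms=velocity,
    )
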