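"""Left/right leg labelling and track maintenance.

The initial assignment compares each leg's body-referenced position vector
against the walking-direction vector: the leg lying counter-clockwise of
the direction (positive z of the 2-D cross product) is the anatomical left.
The direction vector is the torso displacement over the first ~0.5 s of
resolved frames, extended until the displacement is informative.  In
subsequent frames each estimate inherits the label of the nearest
previous-frame leg; when both map onto the same previous leg the 2x2
assignment minimizing total displacement wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import LegEstimate

#: Torso displacement below which a direction vector is considered degenerate.
MIN_DIRECTION_NORM_M = 0.05


@dataclass
class FrameState:
    """Fully resolved per-frame state after labelling."""

    time: float
    torso: np.ndarray | None
    torso_velocity: np.ndarray
    left: LegEstimate
    right: LegEstimate


@dataclass
class LegTrack:
    label: str
    times: np.ndarray
    xy: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")


def cross_z(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def assign_initial_labels(leg_a: np.ndarray, leg_b: np.ndarray,
                          body: np.ndarray, direction: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray] | None:
    """Label two leg positions as (left, right) from the travel direction.

    Returns None when both legs are collinear with the direction (the
    decision is deferred to a later frame).
    """
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if n == 0:
        raise ValueError("direction vector must be non-zero")
    direction = direction / n
    ca = cross_z(direction, np.asarray(leg_a) - body)
    cb = cross_z(direction, np.asarray(leg_b) - body)
    if abs(ca - cb) < 1e-12 or (abs(ca) < 1e-9 and abs(cb) < 1e-9):
        return None
    return (leg_a, leg_b) if ca > cb else (leg_b, leg_a)


def propagate_labels(prev_left: np.ndarray, prev_right: np.ndarray,
                     est_a: LegEstimate, est_b: LegEstimate
                     ) -> tuple[LegEstimate, LegEstimate]:
    """Carry labels forward by nearest previous-frame position; ties and
    double-claims resolved by the minimum-total-distance 2x2 assignment."""
    keep = (np.linalg.norm(est_a.position - prev_left)
            + np.linalg.norm(est_b.position - prev_right))
    swap = (np.linalg.norm(est_b.position - prev_left)
            + np.linalg.norm(est_a.position - prev_right))
    return (est_a, est_b) if keep <= swap else (est_b, est_a)


def walking_direction(times: np.ndarray, torso: np.ndarray,
                      window_s: float = 0.5,
                      min_norm: float = MIN_DIRECTION_NORM_M) -> np.ndarray | None:
    """Torso displacement over the first ``window_s`` of resolved frames,
    growing the window until the displacement is long enough to be a
    reliable direction.  None when the torso never moves far enough."""
    t0 = times[0]
    for horizon in np.arange(window_s, times[-1] - t0 + window_s, window_s):
        idx = np.searchsorted(times, t0 + horizon)
        idx = min(idx, len(times) - 1)
        d = torso[idx] - torso[0]
        if np.linalg.norm(d) >= min_norm:
            return d
        if idx == len(times) - 1:
            break
    return None


def label_leg_sequence(times: np.ndarray, torso: np.ndarray,
                       pairs: Sequence[tuple[LegEstimate, LegEstimate]]
                       ) -> tuple[LegTrack, LegTrack] | None:
    """Assign left/right labels to an identity-consistent estimate sequence.

    ``pairs`` must already be frame-to-frame aligned (element 0 of each pair
    is the same physical leg throughout); the initial left/right decision is
    made once from the walking direction and then fixed.
    """
    direction = walking_direction(times, torso)
    if direction is None:
        return None
    first_left_is_0: bool | None = None
    for i in range(len(pairs)):
        labelled = assign_initial_labels(pairs[i][0].position, pairs[i][1].position,
                                         torso[i], direction)
        if labelled is not None:
            first_left_is_0 = np.array_equal(labelled[0], pairs[i][0].position)
            break
    if first_left_is_0 is None:
        return None
    order = (0, 1) if first_left_is_0 else (1, 0)
    tracks = []
    for slot, label in zip(order, ("left", "right")):
        xy = np.stack([p[slot].position for p in pairs])
        prov = [p[slot].provenance for p in pairs]
        tracks.append(LegTrack(label, times, xy, prov))
    return tracks[0], tracks[1]
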