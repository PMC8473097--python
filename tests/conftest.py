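"""Shared fixtures: the default sensor rig, a background recording, and
cached end-to-end pipeline runs of the walk presets (simulation and
processing are deterministic, so one run per preset serves every test)."""

from __future__ import annotations

import numpy as np
import pytest

from gaitlidar import simulate
from gaitlidar.geometry import SensorSpec
from gaitlidar.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def spec():
    return SensorSpec()


@pytest.fixture(scope="session")
def room():
    return simulate.default_room()


@pytest.fixture(scope="session")
def poses():
    return simulate.default_sensors()


@pytest.fixture(scope="session")
def background_scans(room, poses, spec):
    """50 s of empty-room background (2000 frames at 40 Hz, 1 cm noise)."""
    return simulate.synthesize_background(room, poses, spec, n_frames=2000,
                                          noise_sd=0.01, seed=1)


@pytest.fixture(scope="session")
def run_preset(room, poses, spec, background_scans):
    """Factory: simulate a walk preset (seed 7) and run the full pipeline,
    caching results across the session."""
    cache = {}

    def _run(name: str):
        if name not in cache:
            walk = simulate.preset_walk(name, seed=7)
            scans, truth = simulate.synthesize_walk(walk, room, poses, spec)
            result = run_pipeline(scans, background_scans,
                                  PipelineConfig(spec=spec, poses=poses, seed=7))
            cache[name] = (walk, truth, result)
        return cache[name]

    return _run


def track_side_errors(track, truth):
    """Per-frame distance of a labelled track to the true left and right
    shin centres (frames matched by timestamp)."""
    idx = {round(t, 6): i for i, t in enumerate(truth.times)}
    e_left, e_right = [], []
    for k, t in enumerate(track.times):
        i = idx[round(t, 6)]
        e_left.append(np.linalg.norm(track.xy[k] - truth.left[i]))
        e_right.append(np.linalg.norm(track.xy[k] - truth.right[i]))
    return np.asarray(e_left), np.asarray(e_right)


def count_label_swaps(track, truth, own: str, margin: float = 0.03,
                      min_run: int = 5) -> int:
    """Number of persistent identity swaps: runs of at least ``min_run``
    frames in which the track is closer to the *other* leg by more than
    ``margin`` (identity is undefined at the instants the legs coincide,
    so brief coincidences do not count)."""
    e_l, e_r = track_side_errors(track, truth)
    wrong = (e_r + margin < e_l) if own == "left" else (e_l + margin < e_r)
    swaps = run = 0
    for w in wrong:
        run = run + 1 if w else 0
        if run == min_run:
            swaps += 1
    return swaps
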