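"""Scan and configuration file I/O.

Scan files are JSON-lines, one scan per line::

    {"sensor_id": "s1", "t": 0.025, "ranges": [2.31, 2.30, ...]}

A CSV alternative stores one row per scan: ``sensor_id,t,r0,r1,...``.
Both round-trip losslessly at float precision (ranges are serialized with
``repr``-exact floats).

The sensor/room configuration is a single YAML file holding the scanner
spec, the sensor poses, and the room occupancy segments per height band.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .geometry import PolarScan, SensorPose, SensorSpec


def write_scans_jsonl(path: str | Path, scans: Iterable[PolarScan]) -> None:
    with open(path, "w") as fh:
        for s in scans:
            fh.write(
                json.dumps(
                    {"sensor_id": s.sensor_id, "t": s.timestamp, "ranges": s.ranges.tolist()}
                )
            )
            fh.write("\n")


def read_scans_jsonl(path: str | Path) -> list[PolarScan]:
    scans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            scans.append(PolarScan(rec["sensor_id"], float(rec["t"]), np.asarray(rec["ranges"])))
    return scans


def write_scans_csv(path: str | Path, scans: Iterable[PolarScan]) -> None:
    with open(path, "w") as fh:
        for s in scans:
            vals = ",".join(repr(float(v)) for v in s.ranges)
            fh.write(f"{s.sensor_id},{s.timestamp!r},{vals}\n")


def read_scans_csv(path: str | Path) -> list[PolarScan]:
    scans = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            scans.append(
                PolarScan(parts[0], float(parts[1]), np.array([float(v) for v in parts[2:]]))
            )
    return scans


def group_by_sensor(scans: Iterable[PolarScan]) -> dict[str, list[PolarScan]]:
    out: dict[str, list[PolarScan]] = {}
    for s in scans:
        out.setdefault(s.sensor_id, []).append(s)
    for seq in out.values():
        seq.sort(key=lambda s: s.timestamp)
    return out


# -- configuration -----------------------------------------------------------


def sensor_config_to_dict(spec: SensorSpec, poses: Mapping[str, SensorPose],
                          segments: Mapping[str, np.ndarray] | None = None) -> dict:
    cfg: dict = {
        "sensor_spec": {
            "points_per_turn": spec.points_per_turn,
            "window_deg": spec.window_deg,
            "scan_rate_hz": spec.scan_rate_hz,
            "max_range_m": spec.max_range_m,
            "invalid_value": spec.invalid_value,
        },
        "sensors": [
            {
                "sensor_id": p.sensor_id,
                "x": p.x,
                "y": p.y,
                "heading_deg": p.heading_deg,
                "height_band": p.height_band,
            }
            for p in poses.values()
        ],
    }
    if segments is not None:
        cfg["segments"] = {
            band: np.asarray(segs, dtype=float).reshape(-1, 4).tolist()
            for band, segs in segments.items()
        }
    return cfg


def dict_to_sensor_config(cfg: Mapping) -> tuple[SensorSpec, dict[str, SensorPose], dict[str, np.ndarray]]:
    spec = SensorSpec(**cfg.get("sensor_spec", {}))
    poses = {p["sensor_id"]: SensorPose(**p) for p in cfg.get("sensors", [])}
    segments = {
        band: np.asarray(rows, dtype=float).reshape(-1, 2, 2)
        for band, rows in cfg.get("segments", {}).items()
    }
    return spec, poses, segments


def save_sensor_config(path: str | Path, spec: SensorSpec, poses: Mapping[str, SensorPose],
                       segments: Mapping[str, np.ndarray] | None = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sensor_config_to_dict(spec, poses, segments), fh, sort_keys=False)


def load_sensor_config(path: str | Path):
    with open(path) as fh:
        return dict_to_sensor_config(yaml.safe_load(fh))
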