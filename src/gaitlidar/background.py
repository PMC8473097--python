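"""Per-beam Gaussian background models and foreground classification.

Each beam of each sensor observes an essentially static range while the room
is empty; its distribution is modelled as a Gaussian with the per-beam
sample mean and sample standard deviation.  A beam in a later scan is
foreground when its two-sided Gaussian tail probability falls below
``p_threshold`` (default 1e-5) *and* its range is shorter than the
background mean — only objects between the sensor and the background are
physical foreground; longer-than-background returns are dropouts or
multipath, not objects.  Beams that mostly return nothing while the room is
empty ("open" beams, e.g. pointing out of a window) have no background
surface: any valid return on them is foreground.

The model is frozen after fitting; there is no online adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PolarScan

#: Lower bound on the fitted per-beam standard deviation.  Noise-free
#: synthetic input would otherwise make the tail test degenerate.
STD_FLOOR_M = 0.005


@dataclass
class BackgroundModel:
    """Per-sensor, per-beam Gaussian range statistics."""

    mean: dict[str, np.ndarray]
    std: dict[str, np.ndarray]
    n_valid: dict[str, np.ndarray]
    open_beam: dict[str, np.ndarray]
    p_threshold: float = 1e-5
    std_floor: float = STD_FLOOR_M

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")

    @property
    def z_threshold(self) -> float:
        """|z| above which the two-sided tail probability is < p_threshold."""
        return float(stats.norm.isf(self.p_threshold / 2.0))

    def sensors(self) -> list[str]:
        return list(self.mean)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid in self.mean:
            rows.append(pd.DataFrame({
                "sensor_id": sid,
                "beam": np.arange(len(self.mean[sid])),
                "mean": self.mean[sid],
                "std": self.std[sid],
                "n": self.n_valid[sid],
                "open": self.open_beam[sid].astype(int),
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, p_threshold: float = 1e-5) -> "BackgroundModel":
        df = pd.read_csv(path)
        mean, std, n, open_beam = {}, {}, {}, {}
        for sid, grp in df.groupby("sensor_id", sort=False):
            grp = grp.sort_values("beam")
            mean[sid] = grp["mean"].to_numpy()
            std[sid] = grp["std"].to_numpy()
            n[sid] = grp["n"].to_numpy()
            open_beam[sid] = grp["open"].to_numpy().astype(bool)
        return cls(mean, std, n, open_beam, p_threshold=p_threshold)


def fit_background(scans: Mapping[str, Iterable[PolarScan]] | Iterable[PolarScan],
                   p_threshold: float = 1e-5,
                   std_floor: float = STD_FLOOR_M,
                   min_valid_fraction: float = 0.5) -> BackgroundModel:
    """Fit per-beam sample mean/std (ddof=1) of valid ranges per sensor.

    Beams with fewer than ``min_valid_fraction`` valid returns (or fewer
    than 2) are flagged open.  At least two scans per sensor are required.
    """
    if not isinstance(scans, Mapping):
        grouped: dict[str, list[PolarScan]] = {}
        for s in scans:
            grouped.setdefault(s.sensor_id, []).append(s)
        scans = grouped
    if not scans:
        raise ValueError("no background scans supplied")

    mean, std, n_valid, open_beam = {}, {}, {}, {}
    for sid, seq in scans.items():
        block = np.stack([s.ranges for s in seq])
        if block.shape[0] < 2:
            raise ValueError(f"sensor {sid!r}: need at least 2 background scans")
        valid = block > 0
        n = valid.sum(axis=0)
        safe_n = np.maximum(n, 1)
        mu = np.where(n > 0, np.where(valid, block, 0.0).sum(axis=0) / safe_n, np.nan)
        dev2 = np.where(valid, (block - mu) ** 2, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(dev2 / np.maximum(n - 1, 1))
        sd = np.maximum(sd, std_floor)
        is_open = (n < max(2, int(np.ceil(min_valid_fraction * block.shape[0]))))
        mean[sid], std[sid], n_valid[sid], open_beam[sid] = mu, sd, n, is_open
    return BackgroundModel(mean, std, n_valid, open_beam,
                           p_threshold=p_threshold, std_floor=std_floor)


def foreground_mask(ranges: np.ndarray, sensor_id: str, model: BackgroundModel) -> np.ndarray:
    """Boolean foreground mask for one scan's ranges (or an (F, B) stack)."""
    if sensor_id not in model.mean:
        raise KeyError(f"sensor {sensor_id!r} not in background model")
    mu, sd, op = model.mean[sensor_id], model.std[sensor_id], model.open_beam[sensor_id]
    valid = ranges > 0
    with np.errstate(invalid="ignore"):
        z_front = (mu - ranges) / sd  # positive when in front of background
    fg = valid & ~op & (z_front > model.z_threshold)
    fg |= valid & op
    return fg


def remove_background(scan: PolarScan, model: BackgroundModel) -> PolarScan:
    """Return a scan whose background beams are replaced by the sentinel.

    The surviving (foreground) beams are exactly those whose two-sided tail
    probability under the beam's Gaussian is below the threshold and whose
    range is in front of the background mean, plus valid returns on open
    beams.
    """
    fg = foreground_mask(scan.ranges, scan.sensor_id, model)
    out = np.where(fg, scan.ranges, 0.0)
    return PolarScan(scan.sensor_id, scan.timestamp, out)


def foreground_indices(scan: PolarScan, model: BackgroundModel) -> np.ndarray:
    return np.flatnonzero(foreground_mask(scan.ranges, scan.sensor_id, model))
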