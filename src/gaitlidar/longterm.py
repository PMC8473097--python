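"""Long-term drift assessment from multi-hour static recordings.

Position estimates of a static target (the two-pipe "legs" and box "torso")
are computed per sensor individually — not pooled — then trimmed at both
ends to discard movement artifacts, bucketed into fixed windows (15 min),
and summarized by median and quartiles per coordinate.  A least-squares
slope of the window medians over time, with its 95% confidence interval,
quantifies drift in mm/h; a CI containing zero means no detectable drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .background import BackgroundModel, foreground_mask
from .clustering import ClusterConfig, breakpoint_cluster
from .geometry import SHIN, PointCloud, SensorPose, SensorSpec, beam_directions

WINDOW_S = 15.0 * 60.0
TRIM_S = 15.0 * 60.0


def windowed_stats(times: np.ndarray, xy: np.ndarray,
                   window_s: float = WINDOW_S, trim_s: float = TRIM_S) -> pd.DataFrame:
    """Median/Q1/Q3 per coordinate per window after trimming both ends.

    Windows tile the trimmed span; an empty window is reported with
    ``n = 0`` and absent statistics.  The recording must be longer than
    ``2·trim + window``.
    """
    times = np.asarray(times, dtype=float)
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    # the recording covers one sample period past the last timestamp
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    t0, t1 = times[0] + trim_s, times[-1] + dt - trim_s
    if t1 - t0 < window_s:
        raise ValueError("recording shorter than 2*trim + window")
    n_windows = int(np.floor((t1 - t0) / window_s))
    rows = []
    for w in range(n_windows):
        lo, hi = t0 + w * window_s, t0 + (w + 1) * window_s
        sel = (times >= lo) & (times < hi)
        for ci, coord in enumerate("xy"):
            vals = xy[sel, ci]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            rows.append({"window": w, "t_mid": (lo + hi) / 2.0, "coord": coord,
                         "median": med, "q1": q1, "q3": q3, "n": int(len(vals))})
    return pd.DataFrame(rows)


def drift_slope(stats_df: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Least-squares slope of window medians vs window mid-time, in mm/h,
    with a confidence interval, per coordinate."""
    out = []
    for coord, grp in stats_df.groupby("coord"):
        grp = grp[grp["n"] > 0]
        if len(grp) < 3:
            raise ValueError("need at least 3 non-empty windows")
        t_h = grp["t_mid"].to_numpy() / 3600.0
        y_mm = grp["median"].to_numpy() * 1000.0
        res = stats.linregress(t_h, y_mm)
        df = len(grp) - 2
        if res.stderr > 0:
            tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
            lo, hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
        else:
            lo = hi = res.slope
        out.append({"coord": coord, "slope_mm_per_h": res.slope,
                    "ci_low": lo, "ci_high": hi, "n_windows": len(grp)})
    return pd.DataFrame(out)


def static_leg_positions(chunks: Iterable[tuple[np.ndarray, Mapping[str, np.ndarray]]],
                         model: BackgroundModel,
                         poses: Mapping[str, SensorPose],
                         spec: SensorSpec,
                         cfg: ClusterConfig | None = None) -> dict[str, pd.DataFrame]:
    """Per-sensor leg (or torso) positions over a chunked static recording.

    Shin sensors report the two largest clusters per frame as ``leg1`` /
    ``leg2`` (ordered by x, then y — stable for a static scene); the torso
    sensor reports the largest cluster as ``torso``.  Frames where the
    expected clusters are missing are skipped.
    """
    cfg = cfg or ClusterConfig()
    dirs = {sid: beam_directions(p, spec) for sid, p in poses.items()}
    records: dict[str, list] = {sid: [] for sid in poses}
    for times, block in chunks:
        for sid, ranges in block.items():
            pose = poses[sid]
            fg = foreground_mask(ranges, sid, model)
            for f in range(ranges.shape[0]):
                idx = np.flatnonzero(fg[f])
                if len(idx) == 0:
                    continue
                pts = pose.origin + ranges[f, idx, None] * dirs[sid][idx]
                cloud = PointCloud(times[f], pts, np.full(len(pts), sid, dtype=object))
                clusters = breakpoint_cluster(cloud, cfg, poses)
                if pose.height_band == SHIN:
                    if len(clusters) < 2:
                        continue
                    two = sorted(clusters, key=lambda c: c.size, reverse=True)[:2]
                    cents = sorted((c.centroid for c in two), key=lambda p: (p[0], p[1]))
                    records[sid].append((times[f], "leg1", *cents[0]))
                    records[sid].append((times[f], "leg2", *cents[1]))
                else:
                    if not clusters:
                        continue
                    c = max(clusters, key=lambda c: c.size).centroid
                    records[sid].append((times[f], "torso", *c))
    return {sid: pd.DataFrame(rec, columns=["t", "object", "x", "y"])
            for sid, rec in records.items()}


def longterm_report(positions: Mapping[str, pd.DataFrame],
                    window_s: float = WINDOW_S, trim_s: float = TRIM_S) -> pd.DataFrame:
    """Windowed stats for every sensor/object series, stacked."""
    frames = []
    for sid, df in positions.items():
        for obj, grp in df.groupby("object"):
            st = windowed_stats(grp["t"].to_numpy(), grp[["x", "y"]].to_numpy(),
                                window_s=window_s, trim_s=trim_s)
            st.insert(0, "sensor_id", sid)
            st.insert(1, "object", obj)
            frames.append(st)
    return pd.concat(frames, ignore_index=True)
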