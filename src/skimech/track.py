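"""3D track topography reconstruction from GNSS samples.

Track revolutions are segmented at recurrent closest approaches to the start
point (a gate of configurable radius), each lap is demeaned to strip slow
positional drift, resampled to a common arc-length parameterization, and
averaged into a mean lap polyline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GnssSeries

log = logging.getLogger(__name__)

GATE_RADIUS_M = 5.0
N_RESAMPLE = 400  # ~4 Hz x 100 s lap scale


@dataclass
class TrackModel:
    lap_polylines: list[np.ndarray]  # (m_i, 3) demeaned laps
    mean_lap: np.ndarray  # (N_RESAMPLE, 3)
    lap_boundaries: np.ndarray  # sample indices (lap starts)

    def __post_init__(self) -> None:
        self.lap_boundaries = np.asarray(self.lap_boundaries, dtype=int)
        if len(self.lap_boundaries) > 1 and np.any(np.diff(self.lap_boundaries) <= 0):
            raise ValueError("lap boundaries must be strictly increasing")


def segment_laps(track: GnssSeries, gate_radius_m: float = GATE_RADIUS_M) -> np.ndarray:
    """Lap-start sample indices at recurrent closest approach to the start.

    A new boundary is registered at the local distance minimum inside the
    gate, after the skier has left the gate (distance > 2x radius) since the
    previous boundary. If no recurrence is found the whole series is one lap,
    with a warning.
    """
    xyz = track.xyz()
    d = np.linalg.norm(xyz[:, :2] - xyz[0, :2], axis=1)
    n = len(d)
    boundaries = [0]
    outside = False
    i = 1
    while i < n:
        if not outside:
            if d[i] > 2.0 * gate_radius_m:
                outside = True
            i += 1
        elif d[i] < gate_radius_m:
            # take the distance argmin over the whole in-gate window
            j = i
            while j < n and d[j] < gate_radius_m:
                j += 1
            boundaries.append(i + int(np.argmin(d[i:j])))
            outside = False
            i = j
        else:
            i += 1
    # the final return to the gate closes the last lap; it is not a new start
    if len(boundaries) > 1:
        median_lap = float(np.median(np.diff(boundaries)))
        if n - boundaries[-1] < 0.5 * median_lap:
            boundaries.pop()
    if len(boundaries) == 1:
        log.warning("no lap recurrence found within %.1f m gate; single lap", gate_radius_m)
    return np.asarray(boundaries, dtype=int)


def _resample_arclength(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a 3D polyline to n points equally spaced in arc length."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(poly[:1], n, axis=0)
    s_new = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(s_new, s, poly[:, k]) for k in range(3)])


def demean_laps(track: GnssSeries, boundaries: np.ndarray,
                n_resample: int = N_RESAMPLE) -> TrackModel:
    """Remove each lap's mean position and linear drift, resample to common
    arc length, and average into the mean lap.

    Per-lap linear detrending strips receiver drift without touching the real
    topography: over one closed revolution every true coordinate is periodic,
    so its least-squares line is flat and only drift carries slope. The
    operation is idempotent and invariant to a global position offset.
    """
    xyz = track.xyz()
    boundaries = np.asarray(boundaries, dtype=int)
    if len(boundaries) == 0:
        raise ValueError("at least one lap boundary required")
    if len(boundaries) >= 2:
        # Drift estimate from recurrence: every lap start is the same physical
        # gate, so a least-squares line through the gate positions carries only
        # drift (plus noise), never the track's shape.
        tb = boundaries.astype(float)
        A = np.column_stack([tb, np.ones_like(tb)])
        coef, *_ = np.linalg.lstsq(A, xyz[boundaries], rcond=None)
        xyz = xyz - np.outer(np.arange(len(xyz), dtype=float), coef[0])
    edges = list(boundaries) + [len(xyz)]
    laps = []
    for a, b in zip(edges[:-1], edges[1:]):
        if b - a < 2:
            continue
        lap = xyz[a:b]
        laps.append(lap - lap.mean(axis=0))
    if not laps:
        raise ValueError("no usable laps")
    resampled = [_resample_arclength(lap, n_resample) for lap in laps]
    mean_lap = np.mean(resampled, axis=0)
    return TrackModel(lap_polylines=laps, mean_lap=mean_lap,
                      lap_boundaries=boundaries)


def reconstruct_track(track: GnssSeries, gate_radius_m: float = GATE_RADIUS_M,
                      n_resample: int = N_RESAMPLE) -> TrackModel:
    """segment_laps + demean_laps in one step."""
    return demean_laps(track, segment_laps(track, gate_radius_m), n_resample)


def export_track(model: TrackModel, path: str | Path) -> None:
    """Write the mean lap and demeaned laps as a delimited 3D polyline table."""
    if not model.lap_polylines:
        raise ValueError("empty track model")
    frames = []
    mean = pd.DataFrame(model.mean_lap, columns=["x_m", "y_m", "elev_m"])
    mean.insert(0, "lap", "mean")
    mean.insert(1, "vertex", np.arange(len(mean)))
    frames.append(mean)
    for k, lap in enumerate(model.lap_polylines):
        df = pd.DataFrame(lap, columns=["x_m", "y_m", "elev_m"])
        df.insert(0, "lap", str(k))
        df.insert(1, "vertex", np.arange(len(df)))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_track(path: str | Path) -> TrackModel:
    """Round-trip reader for exported track polylines."""
    df = pd.read_csv(path, dtype={"lap": str})
    mean_lap = df[df["lap"] == "mean"][["x_m", "y_m", "elev_m"]].to_numpy()
    laps = []
    for k in sorted((lap for lap in df["lap"].unique() if lap != "mean"), key=int):
        laps.append(df[df["lap"] == k][["x_m", "y_m", "elev_m"]].to_numpy())
    starts = np.arange(len(laps))
    return TrackModel(lap_polylines=laps, mean_lap=mean_lap, lap_boundaries=starts)
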