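"""Trial and track containers plus long-table readers/writers.

Native on-disk format is a diff-able file pair per trial:

* ``<stem>.points.csv`` — long table: ``frame, time_s, label, x_mm, y_mm, z_mm``
* ``<stem>.power.csv``  — wide table: ``frame, time_s`` + one watt column per
  joint-power channel (``shoulder_l_w`` …)
* ``<stem>.meta.json``  — participant id, skill, effort, body mass

Units ride in the column names; a reader that cannot find the unit-suffixed
column fails hard rather than guessing. An optional C3D reader maps standard
motion-capture exports onto the 76-point model when ``ezc3d`` is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd

from .body import POWER_CHANNELS, SKILL_LEVELS, PointModel, default_point_model

EFFORT_LEVELS = ("easy", "medium", "hard")

_POINT_COLS = ["frame", "time_s", "label", "x_mm", "y_mm", "z_mm"]
_POWER_COLS = ["frame", "time_s"] + [f"{ch}_w" for ch in POWER_CHANNELS]


@dataclass(frozen=True)
class TrialMeta:
    participant: str
    skill: str
    effort: str = "medium"
    body_mass_kg: float = 75.0
    technique: str | None = None  # ground-truth trial technique when simulated

    def __post_init__(self) -> None:
        if self.skill not in SKILL_LEVELS:
            raise ValueError(f"skill must be one of {SKILL_LEVELS}, got {self.skill!r}")
        if self.effort not in EFFORT_LEVELS:
            raise ValueError(f"effort must be one of {EFFORT_LEVELS}, got {self.effort!r}")
        if not self.body_mass_kg > 0:
            raise ValueError("body_mass_kg must be positive")


@dataclass
class KinematicTrial:
    """One recorded trial: T x 76 x 3 positions (mm), T x 5 joint power (W)."""

    frames: np.ndarray
    time_s: np.ndarray
    power: np.ndarray
    meta: TrialMeta
    model: PointModel = field(default_factory=default_point_model)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        t = len(self.time_s)
        if self.frames.shape != (t, 76, 3):
            raise ValueError(f"frames must be (T, 76, 3); got {self.frames.shape} for T={t}")
        if self.power.shape != (t, len(POWER_CHANNELS)):
            raise ValueError(f"power must be (T, {len(POWER_CHANNELS)}); got {self.power.shape}")
        if t and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not np.isfinite(self.power).all():
            raise ValueError("power channels contain non-finite values")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def point(self, label: str) -> np.ndarray:
        """(T, 3) trajectory of one labelled point, millimetres."""
        return self.frames[:, self.model.index(label), :]

    def copy_with(self, **kw) -> "KinematicTrial":
        data = dict(frames=self.frames, time_s=self.time_s, power=self.power,
                    meta=self.meta, model=self.model)
        data.update(kw)
        return KinematicTrial(**data)


@dataclass
class GnssSeries:
    """4 Hz satellite positioning series in local metric coordinates."""

    time_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    elev_m: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        self.elev_m = np.asarray(self.elev_m, dtype=float)
        n = len(self.time_s)
        for name in ("x_m", "y_m", "elev_m"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match time_s length {n}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
        if n > 1 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")

    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x_m, self.y_m, self.elev_m])


def _paths(path: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(path)
    if stem.suffix == ".csv":
        stem = stem.with_suffix("")
    return (stem.with_suffix(".points.csv"), stem.with_suffix(".power.csv"),
            stem.with_suffix(".meta.json"))


def write_trial(trial: KinematicTrial, path: str | Path) -> None:
    """Write the long-table file pair + metadata sidecar for one trial."""
    if trial.n_frames == 0:
        raise ValueError("refusing to write an empty trial (T=0)")
    if not np.isfinite(trial.frames).all():
        raise ValueError("trial contains non-finite coordinates")
    ppath, wpath, mpath = _paths(path)
    t = trial.n_frames
    frames_idx = np.repeat(np.arange(t), 76)
    pts = pd.DataFrame({
        "frame": frames_idx,
        "time_s": np.repeat(trial.time_s, 76),
        "label": np.tile(np.asarray(trial.model.labels, dtype=object), t),
        "x_mm": trial.frames[:, :, 0].ravel(),
        "y_mm": trial.frames[:, :, 1].ravel(),
        "z_mm": trial.frames[:, :, 2].ravel(),
    })
    pts.to_csv(ppath, index=False)
    pw = pd.DataFrame({"frame": np.arange(t), "time_s": trial.time_s})
    for j, ch in enumerate(POWER_CHANNELS):
        pw[f"{ch}_w"] = trial.power[:, j]
    pw.to_csv(wpath, index=False)
    meta = {
        "participant": trial.meta.participant,
        "skill": trial.meta.skill,
        "effort": trial.meta.effort,
        "body_mass_kg": trial.meta.body_mass_kg,
        "technique": trial.meta.technique,
    }
    mpath.write_text(json.dumps(meta, indent=1))


def read_trial(path: str | Path, model: PointModel | None = None) -> KinematicTrial:
    """Read a trial file pair, mapping labels through the point model.

    Loading is label-keyed, never position-keyed: row order in the file is
    irrelevant, missing mandatory labels are a hard error naming the label,
    and unit-suffixed columns are required (no silent unit guessing).
    """
    model = model or default_point_model()
    ppath, wpath, mpath = _paths(path)
    pts = pd.read_csv(ppath)
    missing_cols = [c for c in _POINT_COLS if c not in pts.columns]
    if missing_cols:
        raise ValueError(
            f"{ppath}: missing columns {missing_cols} — unit-suffixed headers are required")
    present = set(pts["label"].unique())
    absent = [lbl for lbl in model.labels if lbl not in present]
    if absent:
        raise ValueError(f"{ppath}: trial is missing required point label(s) {absent[:5]}")
    pts = pts.sort_values(["time_s", "label"], kind="mergesort")
    time_s = np.sort(pts["time_s"].unique())
    t = len(time_s)
    label_codes = pd.Categorical(pts["label"], categories=list(model.labels))
    if label_codes.codes.min() < 0:
        extra = sorted(present - set(model.labels))
        raise ValueError(f"{ppath}: labels not in point model: {extra[:5]}")
    frame_codes = np.searchsorted(time_s, pts["time_s"].to_numpy())
    frames = np.full((t, 76, 3), np.nan)
    frames[frame_codes, label_codes.codes, :] = pts[["x_mm", "y_mm", "z_mm"]].to_numpy()
    if np.isnan(frames).any():
        bad = np.argwhere(np.isnan(frames[:, :, 0]))
        raise ValueError(f"{ppath}: missing frames after load (first gap frame={bad[0][0]})")

    pw = pd.read_csv(wpath)
    missing_cols = [c for c in _POWER_COLS if c not in pw.columns]
    if missing_cols:
        raise ValueError(
            f"{wpath}: missing columns {missing_cols} — unit-suffixed headers are required")
    pw = pw.sort_values("time_s", kind="mergesort")
    power = pw[[f"{ch}_w" for ch in POWER_CHANNELS]].to_numpy()

    raw = json.loads(mpath.read_text())
    meta = TrialMeta(participant=raw["participant"], skill=raw["skill"],
                     effort=raw["effort"], body_mass_kg=raw["body_mass_kg"],
                     technique=raw.get("technique"))
    return KinematicTrial(frames=frames, time_s=time_s, power=power, meta=meta, model=model)


def read_c3d(path: str | Path, model: PointModel | None = None,
             meta: TrialMeta | None = None) -> KinematicTrial:
    """Read a C3D motion-capture file (requires the optional ezc3d package).

    Marker labels are matched by name against the point model, so permuted
    label order in the file yields an identical trial.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "read_c3d requires the optional 'ezc3d' package; install it or use "
            "the long-table format via read_trial") from exc
    model = model or default_point_model()
    c3d = ezc3d.c3d(str(path))
    labels = [lbl.strip() for lbl in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, n_markers, T)
    absent = [lbl for lbl in model.labels if lbl not in labels]
    if absent:
        raise ValueError(f"{path}: C3D missing required label(s) {absent[:5]}")
    order = [labels.index(lbl) for lbl in model.labels]
    frames = np.transpose(pts[:3, order, :], (2, 1, 0)).astype(float)
    t = frames.shape[0]
    time_s = np.arange(t) / rate
    meta = meta or TrialMeta(participant=Path(path).stem, skill="intermediate")
    power = np.zeros((t, len(POWER_CHANNELS)))
    return KinematicTrial(frames=frames, time_s=time_s, power=power, meta=meta, model=model)


def write_gnss(series: GnssSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.time_s, "x_m": series.x_m,
                  "y_m": series.y_m, "elev_m": series.elev_m}).to_csv(path, index=False)


def read_gnss(path: str | Path) -> GnssSeries:
    df = pd.read_csv(path)
    need = ["time_s", "x_m", "y_m", "elev_m"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} — unit-suffixed headers required")
    df = df.sort_values("time_s", kind="mergesort")
    return GnssSeries(time_s=df["time_s"].to_numpy(), x_m=df["x_m"].to_numpy(),
                      y_m=df["y_m"].to_numpy(), elev_m=df["elev_m"].to_numpy())


def write_ground_truth(truth, path: str | Path) -> None:
    """Sidecar table: cycle index, boundary frame, label, embedded effect values."""
    df = pd.DataFrame({
        "cycle": np.arange(len(truth.cycle_boundaries)),
        "boundary_frame": truth.cycle_boundaries,
        "label": truth.technique_labels,
        "frontal_area_m2": truth.frontal_area_m2,
        "ski_angle_deg": truth.ski_angle_deg,
        "peak_upper_wkg": truth.peak_upper_wkg,
        "peak_lower_wkg": truth.peak_lower_wkg,
    })
    df.to_csv(path, index=False)
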