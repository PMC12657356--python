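"""Raw-trial processing chain: pelvis alignment, T12 referencing, cycle
segmentation on left-toe displacement, and 101-point time normalization.

The chain runs in a fixed order — align → reference → segment → normalize.
Alignment removes per-frame heading (pelvis orientation) so every skier faces
the same direction regardless of where they are on the track; T12 referencing
removes slow whole-body translation (travel and sensor drift); segmentation
then partitions propulsive movements at peaks of the left-toe displacement
norm exceeding 1 cm; finally every cycle is resampled to 101 points with a
shape-preserving piecewise cubic Hermite interpolant (PCHIP).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import find_peaks
from scipy.stats import f_oneway

from . import body
from .body import POWER_CHANNELS, SKILL_LEVELS
from .io import KinematicTrial, TrialMeta

log = logging.getLogger(__name__)

N_SAMPLES = 101  # time-normalized samples per cycle
MIN_CYCLE_SAMPLES = 4  # PCHIP needs at least 4 support points
MAX_CYCLE_S = 10.0  # longer spans are glide/rest, not propulsion


@dataclass
class AlignedTrial(KinematicTrial):
    """Trial expressed in the pelvis-fixed frame (optionally T12-referenced)."""

    rotations: np.ndarray | None = None  # (T, 3, 3) applied per frame
    reference_labels: tuple[str, ...] = ()
    t12_referenced: bool = False


def pelvis_basis(frames: np.ndarray, model) -> np.ndarray:
    """Per-frame proper rotation matrices (T, 3, 3) whose columns are the
    pelvis axes (x forward, y left, z up) in the input frame.

    Degenerate geometry (collinear pelvis points) raises with the frame index.
    """
    origin = frames[:, model.index(body.PELVIS_ORIGIN), :]
    lasis = frames[:, model.index(body.PELVIS_LASIS), :]
    rasis = frames[:, model.index(body.PELVIS_RASIS), :]
    ml = rasis - lasis  # points to the skier's right
    anterior = 0.5 * (lasis + rasis) - origin
    ml_norm = np.linalg.norm(ml, axis=1)
    ant_norm = np.linalg.norm(anterior, axis=1)
    bad = np.where((ml_norm < 1e-9) | (ant_norm < 1e-9))[0]
    if bad.size:
        raise ValueError(f"degenerate pelvis geometry at frame {bad[0]}")
    y = -ml / ml_norm[:, None]  # leftward
    x = anterior - (anterior * y).sum(axis=1, keepdims=True) * y
    x_norm = np.linalg.norm(x, axis=1)
    bad = np.where(x_norm < 1e-9)[0]
    if bad.size:
        raise ValueError(f"degenerate pelvis geometry (collinear points) at frame {bad[0]}")
    x = x / x_norm[:, None]
    z = np.cross(x, y)
    return np.stack([x, y, z], axis=2)  # columns are local axes


def align_to_pelvis(trial: KinematicTrial) -> AlignedTrial:
    """Re-express every point in the pelvis-fixed frame at each instant.

    The per-frame pelvis orientation R (a proper rotation, det +1) is removed
    by applying its inverse to the whole point cloud, so heading changes around
    the track vanish and the pelvis axes coincide with the output axes.
    """
    rot = pelvis_basis(trial.frames, trial.model)
    # p_local = R^T p  (einsum over the point axis)
    frames = np.einsum("tij,tpi->tpj", rot, trial.frames)
    return AlignedTrial(frames=frames, time_s=trial.time_s, power=trial.power,
                        meta=trial.meta, model=trial.model, rotations=rot,
                        reference_labels=(body.PELVIS_ORIGIN, body.PELVIS_LASIS,
                                          body.PELVIS_RASIS))


def reference_to_t12(trial: KinematicTrial) -> AlignedTrial:
    """Shift the cloud so the T12 spinous process sits at the origin at every
    frame, removing small linear translations (travel, drift).

    A rigid per-frame translation: it commutes with pelvis alignment, so
    either composition order yields the same frames.
    """
    t12 = trial.frames[:, trial.model.index(body.T12), :]
    frames = trial.frames - t12[:, None, :]
    return AlignedTrial(frames=frames, time_s=trial.time_s, power=trial.power,
                        meta=trial.meta, model=trial.model,
                        rotations=getattr(trial, "rotations", None),
                        reference_labels=getattr(trial, "reference_labels", ())
                        + (body.T12,),
                        t12_referenced=True)


def toe_displacement_norm(trial: KinematicTrial, smooth_s: float = 0.1) -> np.ndarray:
    """Euclidean norm of left-toe displacement about its trial-mean position.

    The norm is smoothed with a short centered moving average (default 0.1 s)
    before peak detection; a symmetric window does not shift peak locations.
    """
    toe = trial.point(body.TOE_L)
    disp = toe - toe.mean(axis=0)
    norm = np.linalg.norm(disp, axis=1)
    if len(trial.time_s) > 2 and smooth_s > 0:
        dt = float(np.median(np.diff(trial.time_s)))
        w = max(1, int(round(smooth_s / dt)))
        if w > 1:
            kernel = np.ones(w) / w
            pad = np.pad(norm, (w // 2, w - 1 - w // 2), mode="edge")
            norm = np.convolve(pad, kernel, mode="valid")
    return norm


def segment_cycles(trial: KinematicTrial, threshold_mm: float = 10.0,
                   smooth_s: float = 0.1) -> list[tuple[int, int]]:
    """Partition propulsive movements at left-toe displacement peaks > 1 cm.

    Returns half-open frame intervals [start, end) between consecutive
    qualifying peaks. Peak detection is two-pass: an initial pass with the
    height threshold (plus a prominence floor of threshold/2 against noise
    doublets) estimates the median inter-peak interval; a second pass enforces
    a minimum separation of 0.25x that interval. Fewer than two qualifying
    peaks yields an empty list.
    """
    if trial.n_frames < 2:
        raise ValueError("segmentation needs at least 2 samples")
    norm = toe_displacement_norm(trial, smooth_s=smooth_s)
    kw = dict(height=threshold_mm, prominence=threshold_mm / 2)
    peaks, _ = find_peaks(norm, **kw)
    if len(peaks) >= 3:
        median_gap = float(np.median(np.diff(peaks)))
        min_dist = max(1, int(round(0.25 * median_gap)))
        peaks, _ = find_peaks(norm, distance=min_dist, **kw)
    if len(peaks) < 2:
        return []
    return [(int(peaks[i]), int(peaks[i + 1])) for i in range(len(peaks) - 1)]


@dataclass
class Cycle:
    """One propulsion cycle, time-normalized to 101 samples on [0, 1]."""

    time_norm: np.ndarray  # (101,) in [0, 1]
    duration_s: float
    coords: np.ndarray  # (101, 76, 3) mm
    power: np.ndarray  # (101, 5) W
    meta: TrialMeta
    cycle_index: int = 0
    technique: str | None = None  # ground-truth label slot

    def __post_init__(self) -> None:
        if self.coords.shape != (N_SAMPLES, 76, 3):
            raise ValueError(f"cycle coords must be ({N_SAMPLES}, 76, 3)")
        if self.power.shape != (N_SAMPLES, len(POWER_CHANNELS)):
            raise ValueError(f"cycle power must be ({N_SAMPLES}, {len(POWER_CHANNELS)})")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")


def time_normalize(time_s: np.ndarray, coords: np.ndarray, power: np.ndarray,
                   meta: TrialMeta, cycle_index: int = 0,
                   technique: str | None = None) -> Cycle:
    """Resample one raw cycle slice to 101 evenly spaced points via PCHIP.

    The shape-preserving interpolant reproduces linear ramps and constants
    exactly and introduces no overshoot; segment endpoints are preserved.
    """
    n = len(time_s)
    if n < MIN_CYCLE_SAMPLES:
        raise ValueError(f"cycle slice has {n} samples; PCHIP needs >= {MIN_CYCLE_SAMPLES}")
    duration = float(time_s[-1] - time_s[0])
    t_new = time_s[0] + np.linspace(0.0, 1.0, N_SAMPLES) * duration
    flat = coords.reshape(n, -1)
    coords_new = PchipInterpolator(time_s, flat, axis=0)(t_new).reshape(N_SAMPLES, 76, 3)
    power_new = PchipInterpolator(time_s, power, axis=0)(t_new)
    # guard against round-off at the right endpoint
    coords_new[0], coords_new[-1] = coords[0], coords[-1]
    power_new[0], power_new[-1] = power[0], power[-1]
    return Cycle(time_norm=np.linspace(0.0, 1.0, N_SAMPLES), duration_s=duration,
                 coords=coords_new, power=power_new, meta=meta,
                 cycle_index=cycle_index, technique=technique)


def extract_cycles(trial: AlignedTrial, threshold_mm: float = 10.0,
                   truth_labels=None) -> list[Cycle]:
    """Segment an aligned trial and time-normalize every valid cycle.

    Cycles shorter than 4 samples or longer than 10 s are discarded with a
    logged warning. ``truth_labels`` (per-interval, from the simulator's
    ground truth) are attached when given.
    """
    intervals = segment_cycles(trial, threshold_mm=threshold_mm)
    cycles: list[Cycle] = []
    for k, (start, end) in enumerate(intervals):
        sl = slice(start, end + 1)  # include the closing peak sample
        t = trial.time_s[sl]
        if len(t) < MIN_CYCLE_SAMPLES:
            log.warning("cycle %d discarded: only %d samples", k, len(t))
            continue
        if t[-1] - t[0] > MAX_CYCLE_S:
            log.warning("cycle %d discarded: %.1f s exceeds %.0f s", k, t[-1] - t[0], MAX_CYCLE_S)
            continue
        technique = None
        if truth_labels is not None and k < len(truth_labels):
            technique = truth_labels[k]
        cycles.append(time_normalize(t, trial.frames[sl], trial.power[sl],
                                     trial.meta, cycle_index=k, technique=technique))
    return cycles


def preprocess_trial(trial: KinematicTrial, threshold_mm: float = 10.0,
                     truth_labels=None) -> list[Cycle]:
    """Full chain: align to pelvis, reference to T12, segment, normalize."""
    aligned = reference_to_t12(align_to_pelvis(trial))
    return extract_cycles(aligned, threshold_mm=threshold_mm, truth_labels=truth_labels)


@dataclass
class CadenceSummary:
    groups: dict = field(default_factory=dict)  # skill -> duration sample (s)
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    f_statistic: float = np.nan
    p_value: float = np.nan


def cadence_summary(durations_by_skill: dict[str, np.ndarray]) -> CadenceSummary:
    """Per-skill cycle-duration distributions and a one-way ANOVA on mean
    cycle time.

    Groups with fewer than two cycles are excluded with a warning. When both
    between- and within-group variance are zero (all durations identical) the
    F test is undefined; p = 1 by convention (no evidence of a difference).
    """
    groups = {}
    for skill in SKILL_LEVELS:
        if skill not in durations_by_skill:
            continue
        sample = np.asarray(durations_by_skill[skill], dtype=float)
        if len(sample) < 2:
            log.warning("skill group %r has <2 cycles; excluded from cadence ANOVA", skill)
            continue
        groups[skill] = sample
    if len(groups) < 2:
        raise ValueError("cadence ANOVA needs at least 2 skill groups with >= 2 cycles")
    samples = list(groups.values())
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = f_oneway(*samples)
        f_stat, p = float(f_stat), float(p)
    return CadenceSummary(groups=groups,
                          means={s: float(v.mean()) for s, v in groups.items()},
                          sds={s: float(v.std(ddof=1)) for s, v in groups.items()},
                          f_statistic=f_stat, p_value=p)
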