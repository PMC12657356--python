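"""Synthetic full-body skiing trials and GNSS tracks with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: six propulsion sub-techniques plus glides, each built from 1-3
harmonic limb templates with technique-specific phase offsets; skill-graded
differences in upper/lower-body joint-power amplitude, frontal area
(mediolateral body width), and ski external rotation; cycle-duration jitter;
band-limited sensor noise and slow common-mode drift. Every trial carries a
GroundTruth sidecar (cycle boundaries, technique labels, realized embedded
effects) so downstream stages can be tested without any external data.

Kinematic amplitudes are invented defaults (no published technique equations
exist); they are documented in docs/methods.md and chosen once for plausible
ranges, not fitted to any outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from . import body, metrics
from .body import SKILL_LEVELS, skill_rank
from .io import GnssSeries, KinematicTrial, TrialMeta, EFFORT_LEVELS

TECHNIQUES = ("double_pole", "kick_double_pole", "diagonal_stride",
              "standing_glide", "free_glide", "skating")

M_TO_MM = 1000.0


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """One synthetic trial's stated world."""

    technique: str
    skill: str
    n_cycles: int = 20
    cycle_period_s: float = 1.0
    cycle_period_cv: float = 0.08
    sample_rate_hz: float = 240.0
    noise_sd_mm: float = 2.0
    drift_mm_per_s: float = 5.0
    body_mass_kg: float = 75.0
    effort: str = "medium"
    heading_deg: float = 0.0
    participant: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; expected {TECHNIQUES}")
        skill_rank(self.skill)  # validates
        if self.effort not in EFFORT_LEVELS:
            raise ValueError(f"unknown effort {self.effort!r}")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not self.cycle_period_s > 0:
            raise ValueError("cycle_period_s must be positive")
        if not self.sample_rate_hz > 2.0 / self.cycle_period_s:
            raise ValueError("sample_rate_hz must exceed 2 / cycle_period_s (Nyquist)")
        for name in ("cycle_period_cv", "noise_sd_mm", "drift_mm_per_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.body_mass_kg > 0:
            raise ValueError("body_mass_kg must be positive")


def default_technique_mix() -> dict[str, dict[str, float]]:
    """Skill -> technique probabilities: beginners lean on the diagonal
    stride; double pole and skating usage grows with skill."""
    return {
        "beginner": {"diagonal_stride": 0.50, "double_pole": 0.15,
                     "kick_double_pole": 0.10, "standing_glide": 0.15,
                     "free_glide": 0.10, "skating": 0.00},
        "intermediate": {"diagonal_stride": 0.30, "double_pole": 0.25,
                         "kick_double_pole": 0.15, "standing_glide": 0.10,
                         "free_glide": 0.10, "skating": 0.10},
        "advanced": {"diagonal_stride": 0.15, "double_pole": 0.30,
                     "kick_double_pole": 0.10, "standing_glide": 0.05,
                     "free_glide": 0.15, "skating": 0.25},
        "elite": {"diagonal_stride": 0.05, "double_pole": 0.35,
                  "kick_double_pole": 0.10, "standing_glide": 0.00,
                  "free_glide": 0.15, "skating": 0.35},
    }


@dataclass(frozen=True)
class SkillEffectProfile:
    """Per-skill-step multipliers encoding the effects the pipeline must
    recover: more joint power, smaller frontal area, less ski external
    rotation at higher skill, plus a skill-dependent technique mix."""

    upper_power_gain: float = 1.25
    lower_power_gain: float = 1.15
    frontal_area_shrink: float = 0.93
    ski_angle_reduction_deg: float = 4.0
    technique_mix: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_technique_mix)

    def __post_init__(self) -> None:
        for name in ("upper_power_gain", "lower_power_gain", "frontal_area_shrink"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.ski_angle_reduction_deg < 0:
            raise ValueError("ski_angle_reduction_deg must be nonnegative")
        for skill, mix in self.technique_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"technique_mix[{skill!r}] sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"technique_mix[{skill!r}] has negative probabilities")
            unknown = set(mix) - set(TECHNIQUES)
            if unknown:
                raise ValueError(f"technique_mix[{skill!r}]: unknown techniques {unknown}")


@dataclass
class GroundTruth:
    """Simulator oracle: boundaries, per-cycle labels, realized effects."""

    cycle_boundaries: np.ndarray  # frame indices of toe-displacement peaks
    technique_labels: list[str]
    frontal_area_m2: np.ndarray  # realized per-cycle mean (clean frames)
    ski_angle_deg: np.ndarray  # realized per-cycle mean |left-ski angle|
    peak_upper_wkg: np.ndarray
    peak_lower_wkg: np.ndarray

    def __post_init__(self) -> None:
        self.cycle_boundaries = np.asarray(self.cycle_boundaries, dtype=int)
        if np.any(np.diff(self.cycle_boundaries) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")
        if len(self.technique_labels) != len(self.cycle_boundaries):
            raise ValueError("one label per cycle required")


# --------------------------------------------------------------------------
# base pose (metres, pelvis-local: x forward, y left, z up)
# --------------------------------------------------------------------------

def _mirror(p):  # left -> right
    return (p[0], -p[1], p[2])


_LEFT_POSE = {
    "HEAD_L": (0.00, 0.08, 0.64), "EAR_L": (0.00, 0.09, 0.60),
    "CLAV_L": (0.05, 0.08, 0.45), "SCAP_L": (-0.08, 0.10, 0.40),
    "THORAX_L": (0.00, 0.15, 0.30),
    "SHOULDER_L": (0.00, 0.20, 0.45), "UPPERARM_L": (0.05, 0.23, 0.30),
    "ELBOW_L": (0.10, 0.25, 0.18), "FOREARM_L": (0.18, 0.25, 0.05),
    "WRIST_L": (0.25, 0.24, -0.05), "HAND_L": (0.30, 0.24, -0.10),
    "FINGER_L": (0.35, 0.24, -0.13),
    "POLE_L_GRIP": (0.33, 0.28, -0.08), "POLE_L_MID": (0.25, 0.30, -0.55),
    "POLE_L_TIP": (0.17, 0.32, -1.00),
    "PELVIS_LASIS": (0.12, 0.13, 0.02), "PELVIS_LPSIS": (-0.05, 0.06, 0.03),
    "HIP_L": (0.00, 0.10, -0.05), "THIGH_L": (0.05, 0.11, -0.25),
    "KNEE_L": (0.10, 0.11, -0.45), "SHANK_L": (0.05, 0.11, -0.70),
    "ANKLE_L": (0.00, 0.11, -0.92), "HEEL_L": (-0.06, 0.11, -0.95),
    "MIDFOOT_L": (0.05, 0.11, -0.97), "TOE_L": (0.15, 0.11, -0.97),
    "TOE_TIP_L": (0.20, 0.11, -0.97),
}

_MID_POSE = {
    "HEAD_TOP": (0.00, 0.0, 0.74), "HEAD_FRONT": (0.10, 0.0, 0.64),
    "HEAD_BACK": (-0.09, 0.0, 0.64), "JAW": (0.08, 0.0, 0.56),
    "NECK_BASE": (0.00, 0.0, 0.50), "C7": (-0.04, 0.0, 0.48),
    "T4": (-0.05, 0.0, 0.40), "T8": (-0.05, 0.0, 0.30), "T12": (-0.05, 0.0, 0.20),
    "STERN_UP": (0.09, 0.0, 0.42), "STERN_MID": (0.10, 0.0, 0.36),
    "STERN_LOW": (0.10, 0.0, 0.30), "XIPHOID": (0.10, 0.0, 0.28),
    "ABDOMEN_UP": (0.10, 0.0, 0.20), "ABDOMEN_LOW": (0.10, 0.0, 0.10),
    "L3": (-0.04, 0.0, 0.12), "L5": (-0.03, 0.0, 0.05),
    "PELVIS_ORIGIN": (0.0, 0.0, 0.0),
}


def base_pose() -> dict[str, tuple[float, float, float]]:
    """Upright skier template, metres in the pelvis frame."""
    pose = dict(_MID_POSE)
    for lbl, p in _LEFT_POSE.items():
        pose[lbl] = p
        pose[lbl.replace("_L", "_R", 1)] = _mirror(p)
    # skis sit under the ankles; exact points are recomputed per frame
    for side in ("L", "R"):
        foot = pose[f"ANKLE_{side}"]
        pose[f"SKI_{side}_TIP"] = (foot[0] + 1.05, foot[1], -1.00)
        pose[f"SKI_{side}_MID"] = (foot[0], foot[1], -1.00)
        pose[f"SKI_{side}_TAIL"] = (foot[0] - 0.65, foot[1], -1.00)
    return pose


# chains moved by the limb templates: (label, amplitude scale along the chain)
_ARM_L = (("SHOULDER_L", 0.10), ("UPPERARM_L", 0.40), ("ELBOW_L", 0.55),
          ("FOREARM_L", 0.75), ("WRIST_L", 0.90), ("HAND_L", 1.00),
          ("FINGER_L", 1.05), ("POLE_L_GRIP", 1.00), ("POLE_L_MID", 1.35),
          ("POLE_L_TIP", 1.70))
_LEG_L = (("HIP_L", 0.05), ("THIGH_L", 0.25), ("KNEE_L", 0.50),
          ("SHANK_L", 0.75), ("ANKLE_L", 0.95), ("HEEL_L", 0.95),
          ("MIDFOOT_L", 0.98), ("TOE_L", 1.00), ("TOE_TIP_L", 1.02))
_TRUNK = (("C7", 1.0), ("T4", 0.8), ("T8", 0.6), ("STERN_UP", 0.9),
          ("STERN_MID", 0.8), ("STERN_LOW", 0.7), ("XIPHOID", 0.65),
          ("HEAD_TOP", 1.2), ("HEAD_FRONT", 1.15), ("HEAD_BACK", 1.15),
          ("HEAD_L", 1.15), ("HEAD_R", 1.15), ("EAR_L", 1.1), ("EAR_R", 1.1),
          ("JAW", 1.05), ("NECK_BASE", 1.0), ("CLAV_L", 0.9), ("CLAV_R", 0.9),
          ("SCAP_L", 0.85), ("SCAP_R", 0.85))


def _right(chain):
    return tuple((lbl.replace("_L", "_R"), s) for lbl, s in chain)


@dataclass(frozen=True)
class TechniqueTemplate:
    """Invented harmonic template for one sub-technique (see docs/methods.md).

    ``toe_loop_r0`` / ``toe_loop_amp`` parameterize the left-toe limacon
    r(theta) = r0 + amp*cos(theta) whose distance-from-centroid has exactly
    one maximum per cycle — the segmentation signal. ``lateral_tilt_deg``
    rotates the loop plane out of the sagittal plane about the forward axis
    (the skating push); a rigid rotation, so the single-peak property of the
    displacement norm is preserved exactly.
    """

    arm_amp: float  # m, sagittal arm sweep
    arm_phase_l: float
    arm_phase_r: float
    toe_loop_r0: float  # m
    toe_loop_amp: float  # m
    leg_phase_r: float  # right-leg loop phase offset
    right_leg_scale: float  # right leg loop amplitude relative to left
    lateral_tilt_deg: float  # leg-loop plane tilt out of the sagittal plane (skating)
    trunk_amp: float  # m, trunk flexion sweep
    ski_yaw_base_deg: float  # mean external rotation of each ski
    ski_yaw_osc_deg: float
    power_peaks_wkg: tuple[float, float, float]  # shoulder(each), knee(each), rta
    power_phases: tuple[float, float, float]
    tuck: float = 1.0  # <1 compresses the upper body vertically (free glide)


TECH_TEMPLATES: dict[str, TechniqueTemplate] = {
    "double_pole": TechniqueTemplate(
        arm_amp=0.30, arm_phase_l=0.0, arm_phase_r=0.0,
        toe_loop_r0=0.10, toe_loop_amp=0.05, leg_phase_r=0.0, right_leg_scale=1.0,
        lateral_tilt_deg=0.0, trunk_amp=0.12, ski_yaw_base_deg=3.0, ski_yaw_osc_deg=1.5,
        power_peaks_wkg=(4.0, 0.8, 2.5), power_phases=(-0.6, 0.2, -0.2)),
    "kick_double_pole": TechniqueTemplate(
        arm_amp=0.28, arm_phase_l=0.0, arm_phase_r=0.0,
        toe_loop_r0=0.13, toe_loop_amp=0.08, leg_phase_r=np.pi, right_leg_scale=0.35,
        lateral_tilt_deg=0.0, trunk_amp=0.10, ski_yaw_base_deg=4.0, ski_yaw_osc_deg=2.0,
        power_peaks_wkg=(3.5, 1.8, 2.2), power_phases=(-0.6, 0.3, -0.1)),
    "diagonal_stride": TechniqueTemplate(
        arm_amp=0.25, arm_phase_l=np.pi, arm_phase_r=0.0,
        toe_loop_r0=0.15, toe_loop_amp=0.10, leg_phase_r=np.pi, right_leg_scale=1.0,
        lateral_tilt_deg=0.0, trunk_amp=0.04, ski_yaw_base_deg=5.0, ski_yaw_osc_deg=2.5,
        power_peaks_wkg=(2.5, 2.5, 1.5), power_phases=(-0.5, 0.0, 0.4)),
    "standing_glide": TechniqueTemplate(
        arm_amp=0.02, arm_phase_l=0.0, arm_phase_r=0.0,
        toe_loop_r0=0.05, toe_loop_amp=0.02, leg_phase_r=0.0, right_leg_scale=1.0,
        lateral_tilt_deg=0.0, trunk_amp=0.01, ski_yaw_base_deg=2.5, ski_yaw_osc_deg=1.0,
        power_peaks_wkg=(0.3, 0.3, 0.2), power_phases=(0.0, 0.0, 0.0)),
    "free_glide": TechniqueTemplate(
        arm_amp=0.02, arm_phase_l=0.0, arm_phase_r=0.0,
        toe_loop_r0=0.05, toe_loop_amp=0.02, leg_phase_r=0.0, right_leg_scale=1.0,
        lateral_tilt_deg=0.0, trunk_amp=0.01, ski_yaw_base_deg=2.0, ski_yaw_osc_deg=1.0,
        power_peaks_wkg=(0.25, 0.35, 0.2), power_phases=(0.0, 0.0, 0.0),
        tuck=0.55),
    "skating": TechniqueTemplate(
        arm_amp=0.26, arm_phase_l=0.0, arm_phase_r=np.pi,
        toe_loop_r0=0.12, toe_loop_amp=0.08, leg_phase_r=np.pi, right_leg_scale=1.0,
        lateral_tilt_deg=40.0, trunk_amp=0.05, ski_yaw_base_deg=22.0, ski_yaw_osc_deg=5.0,
        power_peaks_wkg=(3.0, 3.0, 1.8), power_phases=(-0.4, 0.1, 0.5)),
}

# Sensor-noise clusters: the suit tracks rigid segments with one IMU each, so
# positional noise is shared by all points mapped to a segment (per-point
# i.i.d. noise would shake the pelvis triad and fabricate orientation jitter
# the real sensor fusion does not produce).
_NOISE_CLUSTERS: tuple[tuple[str, ...], ...] = (
    ("HEAD_TOP", "HEAD_FRONT", "HEAD_BACK", "HEAD_L", "HEAD_R", "EAR_L", "EAR_R", "JAW"),
    ("NECK_BASE", "C7", "T4", "T8", "STERN_UP", "STERN_MID", "CLAV_L", "CLAV_R",
     "SCAP_L", "SCAP_R", "THORAX_L", "THORAX_R"),
    ("T12", "STERN_LOW", "XIPHOID", "ABDOMEN_UP", "ABDOMEN_LOW", "L3", "L5"),
    ("PELVIS_ORIGIN", "PELVIS_LASIS", "PELVIS_RASIS", "PELVIS_LPSIS", "PELVIS_RPSIS"),
    ("SHOULDER_L", "UPPERARM_L"), ("SHOULDER_R", "UPPERARM_R"),
    ("ELBOW_L", "FOREARM_L"), ("ELBOW_R", "FOREARM_R"),
    ("WRIST_L", "HAND_L", "FINGER_L"), ("WRIST_R", "HAND_R", "FINGER_R"),
    ("POLE_L_GRIP", "POLE_L_MID", "POLE_L_TIP"),
    ("POLE_R_GRIP", "POLE_R_MID", "POLE_R_TIP"),
    ("HIP_L", "THIGH_L"), ("HIP_R", "THIGH_R"),
    ("KNEE_L", "SHANK_L"), ("KNEE_R", "SHANK_R"),
    ("ANKLE_L", "HEEL_L", "MIDFOOT_L", "TOE_L", "TOE_TIP_L"),
    ("ANKLE_R", "HEEL_R", "MIDFOOT_R", "TOE_R", "TOE_TIP_R"),
    ("SKI_L_TIP", "SKI_L_MID", "SKI_L_TAIL"),
    ("SKI_R_TIP", "SKI_R_MID", "SKI_R_TAIL"),
)

_EFFORT_GAIN = {"easy": 0.8, "medium": 1.0, "hard": 1.2}
_MIN_YAW_DEG = 1.5
_TRAVEL_SPEED_M_S = 3.0
_POWER_PULSE_KAPPA = 4.0  # von-Mises-like pulse concentration
_AMP_JITTER_SD = 0.05  # per-cycle lognormal jitter on embedded effects


def _phase_schedule(cfg: SimConfig, rng: np.random.Generator):
    """Per-cycle periods and the piecewise-linear phase knots.

    Cycle k occupies phase [2*pi*k - pi, 2*pi*k + pi); toe-displacement peaks
    fall at phase 2*pi*k, i.e. mid-cycle in time, so the trial's ends are
    displacement minima and contribute no edge peaks.
    """
    periods = rng.normal(cfg.cycle_period_s, cfg.cycle_period_cv * cfg.cycle_period_s,
                         cfg.n_cycles)
    periods = np.clip(periods, 0.3 * cfg.cycle_period_s, None)
    t_knots = np.concatenate([[0.0], np.cumsum(periods)])
    theta_knots = -np.pi + 2.0 * np.pi * np.arange(cfg.n_cycles + 1)
    return periods, t_knots, theta_knots


def generate_trial(config: SimConfig,
                   effects: SkillEffectProfile | None = None
                   ) -> tuple[KinematicTrial, GroundTruth]:
    """Generate one labelled trial plus its ground truth.

    Fully deterministic given ``config.seed``. Noise and drift are applied
    last; the ground truth's realized effects are measured on the clean
    (pre-noise) frames and power channels.
    """
    effects = effects or SkillEffectProfile()
    tpl = TECH_TEMPLATES[config.technique]
    noise_floor = 10.0 * tpl.toe_loop_amp * M_TO_MM
    if config.noise_sd_mm >= noise_floor:
        raise ValueError(
            f"noise_sd_mm={config.noise_sd_mm} would bury the segmentation signal "
            f"(limit {noise_floor:.0f} mm for {config.technique})")
    rng = np.random.default_rng(config.seed)
    rank = skill_rank(config.skill)
    model = body.default_point_model()

    periods, t_knots, theta_knots = _phase_schedule(config, rng)
    total_s = float(t_knots[-1])
    dt = 1.0 / config.sample_rate_hz
    time_s = np.arange(0.0, total_s, dt)
    theta = np.interp(time_s, t_knots, theta_knots)
    n_frames = len(time_s)

    # per-frame cycle index and per-cycle jitter factors for embedded effects
    cyc_idx = np.clip(((theta + np.pi) // (2 * np.pi)).astype(int), 0, config.n_cycles - 1)
    jit_upper = np.exp(rng.normal(0.0, _AMP_JITTER_SD, config.n_cycles))
    jit_lower = np.exp(rng.normal(0.0, _AMP_JITTER_SD, config.n_cycles))
    jit_area = np.exp(rng.normal(0.0, 0.3 * _AMP_JITTER_SD, config.n_cycles))
    jit_yaw = np.exp(rng.normal(0.0, _AMP_JITTER_SD, config.n_cycles))

    pose = base_pose()
    coords = np.empty((n_frames, 76, 3))
    for i, lbl in enumerate(model.labels):
        coords[:, i, :] = pose[lbl]

    cos_t, sin_t = np.cos(theta), np.sin(theta)

    # arms: elliptical sagittal sweep
    for chain, phase in ((_ARM_L, tpl.arm_phase_l), (_right(_ARM_L), tpl.arm_phase_r)):
        cx = np.cos(theta + phase)
        cz = np.sin(theta + phase)
        for lbl, scale in chain:
            j = model.index(lbl)
            coords[:, j, 0] += tpl.arm_amp * scale * cx
            coords[:, j, 2] += 0.5 * tpl.arm_amp * scale * cz

    # legs: limacon loop in a (possibly tilted) plane; left leg phase 0
    # drives segmentation
    tilt = np.radians(tpl.lateral_tilt_deg)
    for chain, phase, amp_scale, lat_sign in (
            (_LEG_L, 0.0, 1.0, +1.0),
            (_right(_LEG_L), tpl.leg_phase_r, tpl.right_leg_scale, -1.0)):
        th = theta + phase
        rho = tpl.toe_loop_r0 + tpl.toe_loop_amp * np.cos(th)
        lx = rho * np.cos(th) * amp_scale
        lz = rho * np.sin(th) * amp_scale
        ly = lz * np.sin(tilt) * lat_sign  # outward push component
        lz = lz * np.cos(tilt)
        for lbl, scale in chain:
            j = model.index(lbl)
            coords[:, j, 0] += lx * scale
            coords[:, j, 1] += ly * scale
            coords[:, j, 2] += lz * scale

    # trunk flexion (double pole crunch)
    for lbl, scale in _TRUNK:
        j = model.index(lbl)
        coords[:, j, 0] += tpl.trunk_amp * scale * cos_t
        coords[:, j, 2] -= 0.5 * tpl.trunk_amp * scale * np.maximum(cos_t, 0.0)

    # skill-graded frontal area: mediolateral body-width scaling
    area_scale = effects.frontal_area_shrink ** rank * jit_area[cyc_idx]
    body_idx = model.group_indices(body.UPPER) + model.group_indices(body.LOWER)
    coords[:, body_idx, 1] *= area_scale[:, None]
    # free-glide tuck: compress the upper body vertically
    if tpl.tuck < 1.0:
        up_idx = model.group_indices(body.UPPER)
        coords[:, up_idx, 2] *= tpl.tuck

    # skis: follow the feet with skill-graded external rotation (yaw)
    yaw_mean = max(tpl.ski_yaw_base_deg - effects.ski_angle_reduction_deg * rank,
                   _MIN_YAW_DEG)
    for side, sign, phase in (("L", +1.0, 0.0), ("R", -1.0, tpl.leg_phase_r)):
        yaw_deg = (yaw_mean + tpl.ski_yaw_osc_deg * np.sin(theta + phase)) * jit_yaw[cyc_idx]
        yaw = np.radians(yaw_deg) * sign  # external rotation: +y tip for left ski
        cy, sy = np.cos(yaw), np.sin(yaw)
        ankle = coords[:, model.index(f"ANKLE_{side}"), :]
        for lbl, fwd in ((f"SKI_{side}_TIP", 1.05), (f"SKI_{side}_MID", 0.0),
                         (f"SKI_{side}_TAIL", -0.65)):
            j = model.index(lbl)
            coords[:, j, 0] = ankle[:, 0] + fwd * cy
            coords[:, j, 1] = ankle[:, 1] + fwd * sy
            coords[:, j, 2] = -1.00

    # joint power: nonnegative phase-locked pulses, W
    upper_gain = (effects.upper_power_gain ** rank) * _EFFORT_GAIN[config.effort]
    lower_gain = (effects.lower_power_gain ** rank) * _EFFORT_GAIN[config.effort]
    pk_sh, pk_kn, pk_rta = tpl.power_peaks_wkg
    ph_sh, ph_kn, ph_rta = tpl.power_phases

    def pulse(peak_wkg, phase, gain, jitter):
        shape = np.exp(_POWER_PULSE_KAPPA * (np.cos(theta + phase) - 1.0))
        return peak_wkg * gain * jitter[cyc_idx] * shape * config.body_mass_kg

    power = np.column_stack([
        pulse(pk_sh, ph_sh, upper_gain, jit_upper),
        pulse(pk_sh, ph_sh + 0.15, upper_gain, jit_upper),
        pulse(pk_kn, ph_kn, lower_gain, jit_lower),
        pulse(pk_kn, ph_kn + 0.15, lower_gain, jit_lower),
        pulse(pk_rta, ph_rta, lower_gain, jit_lower),
    ])

    coords_mm = coords * M_TO_MM

    # ground truth before corruption: boundaries at the per-cycle maxima of
    # the clean left-toe displacement norm (the segmentation signal itself)
    toe = coords_mm[:, model.index(body.TOE_L), :]
    toe_norm = np.linalg.norm(toe - toe.mean(axis=0), axis=1)
    boundaries = np.empty(config.n_cycles, dtype=int)
    for k in range(config.n_cycles):
        sel = np.where(cyc_idx == k)[0]
        boundaries[k] = sel[np.argmax(toe_norm[sel])]
    labels = [config.technique] * config.n_cycles
    truth = _measure_truth(coords_mm, power, boundaries, cyc_idx, labels,
                           config.body_mass_kg, model)

    # heading + forward travel, then band-limited noise and linear drift (last)
    if config.heading_deg:
        h = np.radians(config.heading_deg)
        rot = np.array([[np.cos(h), -np.sin(h), 0.0],
                        [np.sin(h), np.cos(h), 0.0],
                        [0.0, 0.0, 1.0]])
        coords_mm = coords_mm @ rot.T
        travel_dir = rot @ np.array([1.0, 0.0, 0.0])
    else:
        travel_dir = np.array([1.0, 0.0, 0.0])
    coords_mm = coords_mm + (_TRAVEL_SPEED_M_S * M_TO_MM * time_s)[:, None, None] \
        * travel_dir[None, None, :]

    if config.noise_sd_mm > 0:
        # band-limited (sensor-fusion output is smooth), one draw per segment
        raw = rng.normal(0.0, 1.0, (n_frames, len(_NOISE_CLUSTERS), 3))
        smooth = gaussian_filter1d(raw, sigma=config.sample_rate_hz / 60.0, axis=0)
        sd = smooth.std()
        if sd > 0:
            smooth *= config.noise_sd_mm / sd
            for c, cluster in enumerate(_NOISE_CLUSTERS):
                idx = [model.index(lbl) for lbl in cluster]
                coords_mm[:, idx, :] += smooth[:, c, None, :]
    if config.drift_mm_per_s > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords_mm = coords_mm + (config.drift_mm_per_s * time_s)[:, None, None] \
            * direction[None, None, :]

    meta = TrialMeta(participant=config.participant, skill=config.skill,
                     effort=config.effort, body_mass_kg=config.body_mass_kg,
                     technique=config.technique)
    trial = KinematicTrial(frames=coords_mm, time_s=time_s, power=power,
                           meta=meta, model=model)
    return trial, truth


def _measure_truth(coords_mm, power_w, boundaries, cyc_idx, labels,
                   mass_kg, model) -> GroundTruth:
    """Realized per-cycle effects measured on the clean signals."""
    n_cycles = len(boundaries)
    area = np.empty(n_cycles)
    angle = np.empty(n_cycles)
    up = np.empty(n_cycles)
    lo = np.empty(n_cycles)
    upper_w, lower_w = metrics.summed_power(power_w, mass_kg)
    for k in range(n_cycles):
        sel = np.where(cyc_idx == k)[0]
        # subsample frames for the area oracle; extents vary slowly
        sub = sel[:: max(1, len(sel) // 20)]
        area[k] = float(np.mean([metrics.frontal_area(coords_mm[t], model) for t in sub]))
        angles = metrics.ski_angle_series(coords_mm[sel[::4]], model, side="left")
        angle[k] = float(np.nanmean(np.abs(angles)))
        up[k] = float(upper_w[sel].max())
        lo[k] = float(lower_w[sel].max())
    return GroundTruth(cycle_boundaries=boundaries, technique_labels=list(labels),
                       frontal_area_m2=area, ski_angle_deg=angle,
                       peak_upper_wkg=up, peak_lower_wkg=lo)


def generate_cohort(n_per_skill: int,
                    effects: SkillEffectProfile | None = None,
                    seed: int = 0,
                    n_cycles: int = 20,
                    base_config: SimConfig | None = None,
                    efforts: Sequence[str] = EFFORT_LEVELS
                    ) -> list[tuple[KinematicTrial, GroundTruth]]:
    """Trials for all four skill levels, techniques drawn from the mix.

    Per-trial seeds derive deterministically from the master seed; trials
    rotate through ``efforts`` (default easy/medium/hard, as in the field
    protocol; pass a single effort to hold it constant in controlled
    skill-contrast experiments).
    """
    if n_per_skill < 1:
        raise ValueError("n_per_skill must be >= 1")
    effects = effects or SkillEffectProfile()
    master = np.random.default_rng(seed)
    out = []
    for skill in SKILL_LEVELS:
        mix = effects.technique_mix[skill]
        techs = list(mix.keys())
        probs = np.array([mix[t] for t in techs])
        for i in range(n_per_skill):
            technique = str(master.choice(techs, p=probs / probs.sum()))
            trial_seed = int(master.integers(0, 2**31 - 1))
            cfg = base_config or SimConfig(technique=technique, skill=skill)
            cfg = replace(cfg, technique=technique, skill=skill, seed=trial_seed,
                          n_cycles=n_cycles, effort=efforts[i % len(efforts)],
                          participant=f"{skill[:2].upper()}{i:02d}",
                          body_mass_kg=70.0 + 2.5 * skill_rank(skill))
            out.append(generate_trial(cfg, effects))
    return out


# --------------------------------------------------------------------------
# GNSS track generator
# --------------------------------------------------------------------------

def generate_gnss_track(n_laps: int, lap_length_m: float = 1000.0,
                        elevation_change_m: float = 20.0, rate_hz: float = 4.0,
                        drift_m_per_s: float = 0.0, seed: int = 0,
                        lap_time_s: float = 150.0, noise_m: float = 0.0
                        ) -> tuple[GnssSeries, np.ndarray]:
    """Closed oval track repeated ``n_laps`` times with a sinusoidal elevation
    profile (amplitude elevation_change_m / 2), optional noise and linear
    positional drift. Returns the series and the ground-truth lap-start
    sample indices.
    """
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    rng = np.random.default_rng(seed)
    per_lap = int(round(lap_time_s * rate_hz))
    n = per_lap * n_laps
    time_s = np.arange(n) / rate_hz
    phi = 2.0 * np.pi * (np.arange(n) % per_lap) / per_lap
    # oval with 2:1 aspect, scaled so the perimeter matches lap_length_m
    b_over_a = 0.5
    h = ((1 - b_over_a) / (1 + b_over_a)) ** 2
    perim_unit = np.pi * (1 + b_over_a) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))
    a = lap_length_m / perim_unit
    x = a * np.cos(phi)
    y = a * b_over_a * np.sin(phi)
    elev = 0.5 * elevation_change_m * np.sin(phi)
    if noise_m > 0:
        x = x + rng.normal(0.0, noise_m, n)
        y = y + rng.normal(0.0, noise_m, n)
        elev = elev + rng.normal(0.0, noise_m / 2.0, n)
    if drift_m_per_s > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        x = x + drift_m_per_s * time_s * direction[0]
        y = y + drift_m_per_s * time_s * direction[1]
        elev = elev + drift_m_per_s * time_s * direction[2]
    boundaries = np.arange(n_laps) * per_lap
    return GnssSeries(time_s=time_s, x_m=x, y_m=y, elev_m=elev), boundaries
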