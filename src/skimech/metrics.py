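"""Interpretive per-cycle metrics: frontal area, ski external-rotation angle,
and mass-normalized joint power.

Conventions (aligned, pelvis-fixed frame): x forward, y left, z up.
Frontal area — the aerodynamic-drag proxy — is the sum of two rectangles in
the frontal (y-z) plane: mediolateral extent x vertical extent of the
upper-body point cloud plus the same product for the lower body. The ski
angle is the signed transverse-plane (x-y) rotation of the ski axis away
from the forward axis; positive angles point the tip leftward, so external
rotation is positive for the left ski and negative for the right one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import body
from .body import PointModel

log = logging.getLogger(__name__)

MM2_PER_M2 = 1e6


def frontal_area(points_mm: np.ndarray, model: PointModel) -> float:
    """Frontal area (m^2) of one frame's 76-point cloud.

    Sum of two rectangles: (ML extent x vertical extent) of the upper-body
    points plus the same for the lower-body points, extents as max - min per
    axis. Equipment points are excluded. A group collapsed to a point (zero
    extent on either axis) contributes zero area.
    """
    points_mm = np.asarray(points_mm, dtype=float)
    area_mm2 = 0.0
    for group in (body.UPPER, body.LOWER):
        idx = model.group_indices(group)
        if not idx:
            continue
        pts = points_mm[idx]
        ml = np.ptp(pts[:, 1])
        vert = np.ptp(pts[:, 2])
        area_mm2 += ml * vert
    return float(area_mm2 / MM2_PER_M2)


def frontal_area_series(coords_mm: np.ndarray, model: PointModel) -> np.ndarray:
    """Frontal area (m^2) at every sample of a (T, 76, 3) mm series."""
    coords_mm = np.asarray(coords_mm, dtype=float)
    out = np.empty(len(coords_mm))
    for t in range(len(coords_mm)):
        out[t] = frontal_area(coords_mm[t], model)
    return out


def ski_angle(tip_mm: np.ndarray, tail_mm: np.ndarray,
              min_proj_mm: float = 1.0) -> float:
    """Signed transverse-plane angle (degrees) of the ski axis vs forward (+x).

    The tip-minus-tail axis is projected onto the x-y plane; the signed angle
    is atan2(y, x) in (-180, 180], positive toward +y (skier's left). A ski
    pitched near vertical (projection shorter than ``min_proj_mm``) has no
    defined transverse angle and returns NaN.
    """
    axis = np.asarray(tip_mm, dtype=float) - np.asarray(tail_mm, dtype=float)
    proj = np.hypot(axis[0], axis[1])
    if proj < min_proj_mm:
        return float("nan")
    return float(np.degrees(np.arctan2(axis[1], axis[0])))


def ski_angle_series(coords_mm: np.ndarray, model: PointModel,
                     side: str = "left") -> np.ndarray:
    """Signed transverse ski angle (deg) per sample for one ski.

    Vertical-ski samples come back as NaN (skipped with a warning); callers
    summarize with nan-aware statistics.
    """
    tip_lbl, tail_lbl = ((body.SKI_L_TIP, body.SKI_L_TAIL) if side == "left"
                         else (body.SKI_R_TIP, body.SKI_R_TAIL))
    tips = coords_mm[:, model.index(tip_lbl), :]
    tails = coords_mm[:, model.index(tail_lbl), :]
    out = np.array([ski_angle(tip, tail) for tip, tail in zip(tips, tails)])
    n_bad = int(np.isnan(out).sum())
    if n_bad:
        log.warning("%d sample(s) skipped: ski projection degenerate", n_bad)
    return out


def summed_power(power_w: np.ndarray, body_mass_kg: float) -> tuple[np.ndarray, np.ndarray]:
    """Mass-normalized gross upper/lower power series (W/kg) from the 5-channel
    trial power (shoulder_l, shoulder_r, knee_l, knee_r, rta), in watts.

    Upper = both shoulders; lower = both knees + RTA (thorax-abdomen), the
    gross lower-body grouping used for reporting.
    """
    if not body_mass_kg > 0:
        raise ValueError(f"body mass must be positive, got {body_mass_kg}")
    power_w = np.asarray(power_w, dtype=float)
    upper = (power_w[:, 0] + power_w[:, 1]) / body_mass_kg
    lower = (power_w[:, 2] + power_w[:, 3] + power_w[:, 4]) / body_mass_kg
    return upper, lower


@dataclass
class CycleMetrics:
    """Per-cycle interpretive metrics (101-sample series + scalar summaries)."""

    frontal_area_m2: np.ndarray
    ski_angle_deg: np.ndarray  # left ski, signed
    upper_power_wkg: np.ndarray
    lower_power_wkg: np.ndarray
    peak_upper_wkg: float
    peak_lower_wkg: float
    mean_area_m2: float
    mean_abs_ski_angle_deg: float


def cycle_metrics(coords_mm: np.ndarray, power_w: np.ndarray,
                  body_mass_kg: float, model: PointModel) -> CycleMetrics:
    """All Fig-7-style metrics for one cycle given raw 5-channel power (W)."""
    upper, lower = summed_power(power_w, body_mass_kg)
    return _assemble(coords_mm, upper, lower, model)


def _assemble(coords_mm: np.ndarray, upper_wkg: np.ndarray, lower_wkg: np.ndarray,
              model: PointModel) -> CycleMetrics:
    area = frontal_area_series(coords_mm, model)
    angle = ski_angle_series(coords_mm, model, side="left")
    return CycleMetrics(
        frontal_area_m2=area,
        ski_angle_deg=angle,
        upper_power_wkg=upper_wkg,
        lower_power_wkg=lower_wkg,
        peak_upper_wkg=float(np.max(upper_wkg)),
        peak_lower_wkg=float(np.max(lower_wkg)),
        mean_area_m2=float(np.mean(area)),
        mean_abs_ski_angle_deg=float(np.nanmean(np.abs(angle))),
    )


def metrics_for_reconstruction(recon, model: PointModel) -> tuple[CycleMetrics, CycleMetrics]:
    """CycleMetrics for the (beginner, elite) avatar pair of a reconstruction.

    Avatar power lives in database form — upper, lower (knees) and RTA
    channels already in W/kg — so gross lower power is lower + RTA here.
    """
    out = []
    for which in ("beginner", "elite"):
        unscaled = recon.unscaled(which)
        power = unscaled["power"]  # (101, 3): upper, lower(knees), rta in W/kg
        upper = power[:, 0]
        lower = power[:, 1] + power[:, 2]
        out.append(_assemble(unscaled["coords"], upper, lower, model))
    return out[0], out[1]
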