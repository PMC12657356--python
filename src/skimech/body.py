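"""76-point full-body + equipment marker registry.

The motion-capture export used throughout the package carries 76 labelled
points: body landmarks, spine points, ski tip/tail pairs and pole points.
The exact label list of a given sensor suit export varies by vendor, so the
registry ships a documented default and accepts user remapping — the only
hard requirements are the pelvis triad (origin + both ASIS points), the T12
spinous process, the left toe (segmentation signal) and the ski axis pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

UPPER = "upper_body"
LOWER = "lower_body"
EQUIP = "equipment"

#: Labels that downstream operations address by name.
PELVIS_ORIGIN = "PELVIS_ORIGIN"
PELVIS_LASIS = "PELVIS_LASIS"
PELVIS_RASIS = "PELVIS_RASIS"
T12 = "T12"
TOE_L = "TOE_L"
TOE_R = "TOE_R"
SKI_L_TIP = "SKI_L_TIP"
SKI_L_TAIL = "SKI_L_TAIL"
SKI_R_TIP = "SKI_R_TIP"
SKI_R_TAIL = "SKI_R_TAIL"

MANDATORY_LABELS = (
    PELVIS_ORIGIN,
    PELVIS_LASIS,
    PELVIS_RASIS,
    T12,
    TOE_L,
    SKI_L_TIP,
    SKI_L_TAIL,
    SKI_R_TIP,
    SKI_R_TAIL,
)


def _default_registry() -> list[tuple[str, str]]:
    """(label, group) pairs for the default 76-point model."""
    upper = [
        "HEAD_TOP", "HEAD_FRONT", "HEAD_BACK", "HEAD_L", "HEAD_R",
        "EAR_L", "EAR_R", "JAW", "NECK_BASE",
        "C7", "T4", "T8", T12,
        "STERN_UP", "STERN_MID", "STERN_LOW", "XIPHOID",
        "CLAV_L", "CLAV_R", "SCAP_L", "SCAP_R",
        "SHOULDER_L", "SHOULDER_R",
        "UPPERARM_L", "UPPERARM_R",
        "ELBOW_L", "ELBOW_R",
        "FOREARM_L", "FOREARM_R",
        "WRIST_L", "WRIST_R",
        "HAND_L", "HAND_R",
        "FINGER_L", "FINGER_R",
        "ABDOMEN_UP", "ABDOMEN_LOW",
        "THORAX_L", "THORAX_R",
    ]
    lower = [
        "L3", "L5",
        PELVIS_ORIGIN, PELVIS_LASIS, PELVIS_RASIS, "PELVIS_LPSIS", "PELVIS_RPSIS",
        "HIP_L", "HIP_R",
        "THIGH_L", "THIGH_R",
        "KNEE_L", "KNEE_R",
        "SHANK_L", "SHANK_R",
        "ANKLE_L", "ANKLE_R",
        "HEEL_L", "HEEL_R",
        "MIDFOOT_L", "MIDFOOT_R",
        TOE_L, TOE_R,
        "TOE_TIP_L", "TOE_TIP_R",
    ]
    equip = [
        SKI_L_TIP, "SKI_L_MID", SKI_L_TAIL,
        SKI_R_TIP, "SKI_R_MID", SKI_R_TAIL,
        "POLE_L_GRIP", "POLE_L_MID", "POLE_L_TIP",
        "POLE_R_GRIP", "POLE_R_MID", "POLE_R_TIP",
    ]
    pairs = [(lbl, UPPER) for lbl in upper]
    pairs += [(lbl, LOWER) for lbl in lower]
    pairs += [(lbl, EQUIP) for lbl in equip]
    return pairs


@dataclass(frozen=True)
class PointModel:
    """Ordered label registry for the 76-point body/equipment model."""

    labels: tuple[str, ...]
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != 76:
            raise ValueError(f"point model needs exactly 76 labels, got {len(self.labels)}")
        if len(set(self.labels)) != 76:
            raise ValueError("point model labels must be unique")
        missing = [lbl for lbl in MANDATORY_LABELS if lbl not in self.labels]
        if missing:
            raise ValueError(f"point model missing mandatory labels: {missing}")
        unmapped = [lbl for lbl in self.labels if lbl not in self.groups]
        if unmapped:
            raise ValueError(f"labels without a group mapping: {unmapped[:5]}")
        bad = {g for g in self.groups.values()} - {UPPER, LOWER, EQUIP}
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in point model") from None

    def group_indices(self, group: str) -> list[int]:
        return [i for i, lbl in enumerate(self.labels) if self.groups[lbl] == group]

    def remap(self, mapping: Mapping[str, str]) -> "PointModel":
        """Rename labels (old -> new), keeping order and groups."""
        labels = tuple(mapping.get(lbl, lbl) for lbl in self.labels)
        groups = {mapping.get(lbl, lbl): g for lbl, g in self.groups.items()}
        return PointModel(labels=labels, groups=groups)


def default_point_model() -> PointModel:
    pairs = _default_registry()
    return PointModel(labels=tuple(lbl for lbl, _ in pairs), groups=dict(pairs))


#: Order of the five joint-power channels carried with every trial.
POWER_CHANNELS: Sequence[str] = ("shoulder_l", "shoulder_r", "knee_l", "knee_r", "rta")

#: Skill ordering used everywhere skill enters as an ordinal factor.
SKILL_LEVELS: Sequence[str] = ("beginner", "intermediate", "advanced", "elite")


def skill_rank(skill: str) -> int:
    try:
        return SKILL_LEVELS.index(skill)
    except ValueError:
        raise ValueError(f"unknown skill level {skill!r}; expected one of {SKILL_LEVELS}") from None
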