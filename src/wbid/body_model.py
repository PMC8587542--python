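"""Scaled 15-segment rigid-body model of the human body.

The body is modelled as 15 rigid segments (pelvis, torso, head, and paired
upper arms, forearms, hands, thighs, shanks, feet) connected by 14 joints
(L5/S1, neck, shoulders, elbows, wrists, hips, knees, ankles) in a tree
rooted at the pelvis.  Segment masses, centre-of-mass locations and inertia
tensors are obtained from sex-specific regression fractions scaled by the
subject's stature and body mass; segment masses are renormalized so that
they sum exactly to the measured subject mass.

Segment frames have their origin at the proximal joint centre and are
aligned with the global frame (X anterior, Y left, Z up) in the neutral
standing pose.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "SEGMENTS",
    "JOINTS",
    "SubjectRecord",
    "SegmentSpec",
    "JointSpec",
    "BodyModel",
    "build_body_model",
    "joint_tree",
    "load_parameter_table",
]

#: The 15 segment names.
SEGMENTS = (
    "pelvis", "torso", "head",
    "upper_arm_r", "forearm_r", "hand_r",
    "upper_arm_l", "forearm_l", "hand_l",
    "thigh_r", "shank_r", "foot_r",
    "thigh_l", "shank_l", "foot_l",
)

#: joint -> (parent segment, child segment).  The joint load convention is
#: the wrench the parent (proximal) segment applies to the child.
JOINTS = {
    "l5s1": ("pelvis", "torso"),
    "neck": ("torso", "head"),
    "shoulder_r": ("torso", "upper_arm_r"),
    "elbow_r": ("upper_arm_r", "forearm_r"),
    "wrist_r": ("forearm_r", "hand_r"),
    "shoulder_l": ("torso", "upper_arm_l"),
    "elbow_l": ("upper_arm_l", "forearm_l"),
    "wrist_l": ("forearm_l", "hand_l"),
    "hip_r": ("pelvis", "thigh_r"),
    "knee_r": ("thigh_r", "shank_r"),
    "ankle_r": ("shank_r", "foot_r"),
    "hip_l": ("pelvis", "thigh_l"),
    "knee_l": ("thigh_l", "shank_l"),
    "ankle_l": ("shank_l", "foot_l"),
}

_BASE_NAME = {  # model segment -> row of the parameter table
    "pelvis": "pelvis", "torso": "torso", "head": "head",
    "upper_arm_r": "upper_arm", "upper_arm_l": "upper_arm",
    "forearm_r": "forearm", "forearm_l": "forearm",
    "hand_r": "hand", "hand_l": "hand",
    "thigh_r": "thigh", "thigh_l": "thigh",
    "shank_r": "shank", "shank_l": "shank",
    "foot_r": "foot", "foot_l": "foot",
}


def load_parameter_table() -> dict:
    """Load the embedded segment inertial parameter regression table."""
    ref = importlib.resources.files("wbid.data") / "segment_parameters.yaml"
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class SubjectRecord:
    """Anthropometric record of one subject."""

    height: float  #: stature, m
    mass: float    #: body mass, kg
    sex: str       #: 'female' or 'male'

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height {self.height} m outside plausible range (0.5, 2.5)")
        if not 20.0 < self.mass < 200.0:
            raise ValueError(f"mass {self.mass} kg outside plausible range (20, 200)")


@dataclass
class SegmentSpec:
    """Inertial and geometric parameters of one rigid segment."""

    name: str
    mass: float               #: kg
    length: float             #: m, proximal-to-distal joint distance
    com_offset: np.ndarray    #: (3,) m, CoM in the segment frame
    inertia: np.ndarray       #: (3,3) kg·m², about the CoM, segment frame
    proximal_joint: str | None
    distal_joints: tuple[str, ...] = ()


@dataclass
class JointSpec:
    name: str
    parent_segment: str
    child_segment: str


@dataclass
class BodyModel:
    """15 scaled segments and the 14-joint tree rooted at the pelvis."""

    subject: SubjectRecord
    segments: dict[str, SegmentSpec]
    joints: dict[str, JointSpec]
    #: neutral-pose offset of each joint centre / end site from its parent
    #: node, in the parent segment frame (m).  Node names are joint names
    #: plus the end sites 'head_top', 'hand_tip_r/l', 'toe_r/l'.
    offsets: dict[str, np.ndarray] = field(default_factory=dict)
    #: landmark offsets in the owning segment frame, e.g. 'heel_r' on foot_r.
    landmarks: dict[str, tuple[str, np.ndarray]] = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def to_dict(self) -> dict:
        return {
            "subject": {"height": self.subject.height,
                        "mass": self.subject.mass,
                        "sex": self.subject.sex},
            "segments": {
                n: {"mass": float(s.mass), "length": float(s.length),
                    "com_offset": [float(v) for v in s.com_offset],
                    "inertia": [[float(v) for v in row] for row in s.inertia],
                    "proximal_joint": s.proximal_joint,
                    "distal_joints": list(s.distal_joints)}
                for n, s in self.segments.items()
            },
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _distal_joints(segment: str) -> tuple[str, ...]:
    return tuple(j for j, (parent, _) in JOINTS.items() if parent == segment)


def _proximal_joint(segment: str) -> str | None:
    for j, (_, child) in JOINTS.items():
        if child == segment:
            return j
    return None


def build_body_model(subject: SubjectRecord,
                     table: dict | None = None) -> BodyModel:
    """Build the scaled 15-segment model for a subject.

    Masses come from the sex-specific mass fractions and are renormalized
    so that they sum exactly to ``subject.mass``; segment lengths scale
    with stature; inertia tensors are diagonal in the segment frame with
    radii of gyration proportional to segment length.
    """
    tab = table if table is not None else load_parameter_table()
    sex_tab = tab[subject.sex]
    lengths = tab["length_fraction_of_height"]
    gyr = tab["gyration"]
    H = subject.height

    raw_masses = {s: sex_tab[_BASE_NAME[s]]["mass_fraction"] * subject.mass
                  for s in SEGMENTS}
    norm = subject.mass / sum(raw_masses.values())

    segments: dict[str, SegmentSpec] = {}
    for s in SEGMENTS:
        base = _BASE_NAME[s]
        L = lengths[base] * H
        m = raw_masses[s] * norm
        com = np.asarray(sex_tab[base]["com"], dtype=float) * L
        if s.endswith("_r"):
            com = com * np.array([1.0, -1.0, 1.0])
        r = np.asarray(gyr[base], dtype=float) * L
        inertia = np.diag(m * r**2)
        segments[s] = SegmentSpec(
            name=s, mass=m, length=L, com_offset=com, inertia=inertia,
            proximal_joint=_proximal_joint(s), distal_joints=_distal_joints(s),
        )

    joints = {j: JointSpec(j, p, c) for j, (p, c) in JOINTS.items()}

    hw = tab["half_hip_width_fraction"] * H
    sw = tab["half_shoulder_width_fraction"] * H
    sd = tab["shoulder_drop_fraction"] * H
    torso_L = segments["torso"].length
    foot_L = segments["foot_r"].length
    toe_drop = tab["toe_drop_fraction"] * foot_L
    offsets = {
        # from pelvis root
        "hip_r": np.array([0.0, -hw, 0.0]),
        "hip_l": np.array([0.0, hw, 0.0]),
        "l5s1": np.array([0.0, 0.0, segments["pelvis"].length]),
        # from l5s1 (torso frame)
        "neck": np.array([0.0, 0.0, torso_L]),
        "shoulder_r": np.array([0.0, -sw, torso_L - sd]),
        "shoulder_l": np.array([0.0, sw, torso_L - sd]),
        # from neck
        "head_top": np.array([0.0, 0.0, segments["head"].length]),
        # arms hang down in the neutral pose
        "elbow_r": np.array([0.0, 0.0, -segments["upper_arm_r"].length]),
        "elbow_l": np.array([0.0, 0.0, -segments["upper_arm_l"].length]),
        "wrist_r": np.array([0.0, 0.0, -segments["forearm_r"].length]),
        "wrist_l": np.array([0.0, 0.0, -segments["forearm_l"].length]),
        "hand_tip_r": np.array([0.0, 0.0, -segments["hand_r"].length]),
        "hand_tip_l": np.array([0.0, 0.0, -segments["hand_l"].length]),
        # legs
        "knee_r": np.array([0.0, 0.0, -segments["thigh_r"].length]),
        "knee_l": np.array([0.0, 0.0, -segments["thigh_l"].length]),
        "ankle_r": np.array([0.0, 0.0, -segments["shank_r"].length]),
        "ankle_l": np.array([0.0, 0.0, -segments["shank_l"].length]),
        # foot long axis is anterior
        "toe_r": np.array([np.sqrt(max(foot_L**2 - toe_drop**2, 0.0)), 0.0, -toe_drop]),
        "toe_l": np.array([np.sqrt(max(foot_L**2 - toe_drop**2, 0.0)), 0.0, -toe_drop]),
    }

    heel = np.asarray(tab["heel_offset_fractions"], dtype=float) * foot_L
    landmarks = {
        "heel_r": ("foot_r", heel * np.array([1.0, -1.0, 1.0])),
        "heel_l": ("foot_l", heel.copy()),
    }

    return BodyModel(subject=subject, segments=segments, joints=joints,
                     offsets=offsets, landmarks=landmarks)


def joint_tree(model: BodyModel) -> list[str]:
    """Distal-to-proximal segment evaluation order.

    Returns the 15 segment names ordered so that every segment appears
    after all segments distal to it: hands before forearms before upper
    arms, head, then torso (top-down chain); feet before shanks before
    thighs, with the pelvis last (bottom-up chain).
    """
    children = {s: [] for s in SEGMENTS}
    for parent, child in JOINTS.values():
        children[parent].append(child)

    order: list[str] = []

    def visit(seg: str):
        for c in children[seg]:
            visit(c)
        order.append(seg)

    visit("pelvis")
    return order
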