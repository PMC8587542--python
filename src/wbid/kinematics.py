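"""Per-frame segment kinematic states from motion and sensor streams.

The central quantity is the gravity-free centre-of-mass acceleration of
each segment, obtained from the segment-mounted IMU by

    a_i = a_si - alpha_i x r_si - omega_i x (omega_i x r_si)

where ``a_si`` is the (gravity-free) accelerometer reading, ``r_si`` the
IMU position relative to the segment CoM, and ``omega_i``/``alpha_i`` the
segment angular velocity/acceleration.  Angular acceleration is obtained
by numerically differentiating the angular velocity (central differences,
second-order accurate); signals are optionally low-pass filtered with a
zero-phase second-order Butterworth filter before differentiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .body_model import BodyModel
from .constants import G
from .errors import CoverageError, MappingError, ParameterError
from .formats_io import MotionSequence, SensorSeries

__all__ = [
    "SegmentKinematics", "SegmentStateSeries", "Pose",
    "lowpass_filter", "differentiate", "com_acceleration",
    "angular_velocity_from_rotations", "forward_kinematics", "build_states",
]

log = logging.getLogger(__name__)

#: segment -> skeleton node carrying its proximal joint centre and rotation.
SEGMENT_NODE = {
    "pelvis": "root", "torso": "l5s1", "head": "neck",
    "upper_arm_r": "shoulder_r", "forearm_r": "elbow_r", "hand_r": "wrist_r",
    "upper_arm_l": "shoulder_l", "forearm_l": "elbow_l", "hand_l": "wrist_l",
    "thigh_r": "hip_r", "shank_r": "knee_r", "foot_r": "ankle_r",
    "thigh_l": "hip_l", "shank_l": "knee_l", "foot_l": "ankle_l",
}


def lowpass_filter(x: np.ndarray, cutoff: float, frame_rate: float,
                   order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    A second-order filter applied in both directions: zero phase lag and
    an effective fourth-order magnitude response (the analytic single-pass
    attenuation squared).
    """
    x = np.asarray(x, dtype=float)
    nyq = frame_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ParameterError(f"cutoff {cutoff} Hz must lie in (0, {nyq}) Hz")
    if x.shape[0] <= 3 * (order + 1):
        raise ParameterError("series too short for the requested filter order")
    b, a = butter(order, cutoff / nyq)
    return filtfilt(b, a, x, axis=0)


def differentiate(x: np.ndarray, frame_rate: float, order: int = 1) -> np.ndarray:
    """Time derivative of a uniformly sampled series.

    Central differences at interior samples, one-sided at the endpoints.
    ``order`` > 1 applies the operator repeatedly.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 3:
        raise ParameterError("need at least 3 samples to differentiate")
    out = x
    for _ in range(order):
        out = np.gradient(out, 1.0 / frame_rate, axis=0)
    return out


def com_acceleration(a_si: np.ndarray, alpha: np.ndarray, omega: np.ndarray,
                     r_si: np.ndarray) -> np.ndarray:
    """Segment CoM acceleration from the IMU reading.

    Transfers the measured point acceleration from the sensor location to
    the centre of mass of the rigid segment by removing the tangential
    (``alpha x r``) and centripetal (``omega x (omega x r)``) terms.
    """
    a_si = np.asarray(a_si, dtype=float)
    return (a_si - np.cross(alpha, r_si)
            - np.cross(omega, np.cross(omega, r_si)))


def angular_velocity_from_rotations(R: np.ndarray, frame_rate: float) -> np.ndarray:
    """Global-frame angular velocity from an orientation series (n,3,3).

    Uses the skew-symmetric part of ``dR/dt R^T`` with central differences.
    """
    Rdot = np.gradient(R, 1.0 / frame_rate, axis=0)
    W = Rdot @ np.swapaxes(R, -1, -2)
    W = 0.5 * (W - np.swapaxes(W, -1, -2))
    return np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)


@dataclass
class Pose:
    """Forward-kinematics result: global joint centres and segment frames."""

    node_positions: dict[str, np.ndarray]      #: name -> (n,3) m
    orientations: dict[str, np.ndarray]        #: segment -> (n,3,3)
    com: dict[str, np.ndarray]                 #: segment -> (n,3) m


@dataclass
class SegmentKinematics:
    orientation: np.ndarray   #: (n,3,3) segment->global
    com: np.ndarray           #: (n,3) m, global
    acc: np.ndarray           #: (n,3) m/s^2, gravity-free CoM acceleration
    omega: np.ndarray         #: (n,3) rad/s
    alpha: np.ndarray         #: (n,3) rad/s^2


@dataclass
class SegmentStateSeries:
    """Per-frame kinematic state of all 15 segments."""

    frame_rate: float
    segments: dict[str, SegmentKinematics]
    node_positions: dict[str, np.ndarray] = field(default_factory=dict)
    root_position: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return next(iter(self.segments.values())).com.shape[0]

    def com_relative_to_root(self, segment: str) -> np.ndarray:
        """l_i: segment CoM relative to the pelvic frame origin."""
        return self.segments[segment].com - self.root_position

    def to_dataframe(self):
        """Tidy export: one row per (frame, segment, quantity)."""
        import pandas as pd

        rows = []
        for seg, kin in self.segments.items():
            for quantity, arr in (("com", kin.com), ("acc", kin.acc),
                                  ("omega", kin.omega), ("alpha", kin.alpha)):
                df = pd.DataFrame(arr, columns=["x", "y", "z"])
                df.insert(0, "frame", np.arange(arr.shape[0]))
                df.insert(1, "segment", seg)
                df.insert(2, "quantity", quantity)
                rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def zeroed(self) -> "SegmentStateSeries":
        """Copy with accelerations and angular rates set to zero.

        This is the posture-only ("static") flavour of the state series:
        positions and orientations are retained, all motion is discarded.
        """
        segs = {
            name: SegmentKinematics(
                orientation=k.orientation, com=k.com,
                acc=np.zeros_like(k.acc), omega=np.zeros_like(k.omega),
                alpha=np.zeros_like(k.alpha))
            for name, k in self.segments.items()
        }
        return SegmentStateSeries(frame_rate=self.frame_rate, segments=segs,
                                  node_positions=self.node_positions,
                                  root_position=self.root_position)


def forward_kinematics(motion: MotionSequence, model: BodyModel) -> Pose:
    """Global joint-centre, segment-frame and CoM series from a motion.

    Composes per-joint rotations from the pelvis root down the skeleton
    tree; segment CoM positions are placed by the model's regression
    offsets in each segment frame.
    """
    nodes = motion.skeleton.nodes
    n = motion.n_frames
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))

    R_glob: list[np.ndarray] = []
    p_glob: list[np.ndarray] = []
    for i, node in enumerate(nodes):
        R_loc = motion.rotations.get(node.name)
        if node.parent == -1:
            R = R_loc if R_loc is not None else eye
            p = motion.root_position + node.offset
        else:
            Rp, pp = R_glob[node.parent], p_glob[node.parent]
            p = pp + np.einsum("nij,j->ni", Rp, node.offset)
            R = Rp @ R_loc if R_loc is not None else Rp
        R_glob.append(R)
        p_glob.append(p)

    positions = {node.name: p_glob[i] for i, node in enumerate(nodes)}
    rot_by_node = {node.name: R_glob[i] for i, node in enumerate(nodes)}

    orientations: dict[str, np.ndarray] = {}
    com: dict[str, np.ndarray] = {}
    for seg, node_name in SEGMENT_NODE.items():
        if node_name not in positions:
            raise MappingError(f"skeleton lacks node {node_name!r} needed for "
                               f"segment {seg!r}")
        R = rot_by_node[node_name]
        orientations[seg] = R
        spec = model.segments[seg]
        com[seg] = positions[node_name] + np.einsum("nij,j->ni", R, spec.com_offset)

    for lname, (seg, offset) in model.landmarks.items():
        node = SEGMENT_NODE[seg]
        positions[lname] = positions[node] + np.einsum(
            "nij,j->ni", orientations[seg], offset)

    return Pose(node_positions=positions, orientations=orientations, com=com)


def build_states(motion: MotionSequence, sensors: SensorSeries | None,
                 model: BodyModel, cutoff: float | None = None,
                 gravity_included: bool = False) -> SegmentStateSeries:
    """Assemble the full segment kinematic state series.

    Angular velocity is taken from the sensor stream where available and
    otherwise derived from the motion orientations; angular acceleration
    is its numerical derivative.  CoM acceleration comes from the sensor
    acceleration via the rigid-body transfer (:func:`com_acceleration`),
    falling back to double-differentiated forward-kinematics positions for
    segments without a sensor.  ``cutoff`` (Hz) applies the zero-phase
    Butterworth filter to position and rate channels before any
    differentiation; ``None`` disables filtering (noiseless input).
    ``gravity_included`` declares that the accelerometer stream contains
    the +g static component, which is then removed so that downstream
    equations never double-count weight.
    """
    fs = motion.frame_rate
    pose = forward_kinematics(motion, model)

    def _f(x):
        return lowpass_filter(x, cutoff, fs) if cutoff is not None else x

    node_positions = {k: _f(v) for k, v in pose.node_positions.items()}
    root = node_positions["root"] if "root" in node_positions else _f(motion.root_position)

    segments: dict[str, SegmentKinematics] = {}
    for seg in model.segments:
        R = pose.orientations.get(seg)
        if R is None:
            raise CoverageError(f"segment {seg!r} has no kinematics")
        com = _f(pose.com[seg])
        rec = sensors.segments.get(seg) if sensors is not None else None
        if rec is not None:
            omega = _f(rec.angular_velocity)
            a_si = rec.acceleration.astype(float)
            if gravity_included:
                a_si = a_si - np.array([0.0, 0.0, G])
            a_si = _f(a_si)
            alpha = differentiate(omega, fs)
            r_si = _f(rec.position) - com
            acc = com_acceleration(a_si, alpha, omega, r_si)
        else:
            log.info("segment %s: no sensor record, deriving state from the "
                     "motion stream", seg)
            omega = angular_velocity_from_rotations(R, fs)
            if cutoff is not None:
                omega = _f(omega)
            alpha = differentiate(omega, fs)
            acc = differentiate(com, fs, order=2)
        segments[seg] = SegmentKinematics(orientation=R, com=com, acc=acc,
                                          omega=omega, alpha=alpha)

    return SegmentStateSeries(frame_rate=fs, segments=segments,
                              node_positions=node_positions,
                              root_position=root)
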