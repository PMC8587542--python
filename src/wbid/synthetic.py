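"""Synthetic trials with full ground truth.

Generators produce template-driven whole-body motions (quiet standing
with optional sway, gait-like stepping, stoop lifting with a hand-held
box) together with the IMU streams a motion-capture suit would deliver
and the ground-truth reactions, contacts and joint loads implied by the
model's own discrete kinematics — so every pipeline stage has an oracle
without any recorded data.

Truth construction is forward and self-consistent: segment kinematic
truth is defined on the sampling grid (discrete differentiation of the
template kinematics), total reactions follow from the whole-body Newton
balance, the double-stance split follows the same minimum-effort
criterion the estimator assumes, and truth joint loads are computed by an
independent subtree-aggregation route (not the per-segment recursion the
estimator uses).  Sensor streams are synthesized so that the rigid-body
acceleration transfer reproduces the truth CoM accelerations exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body_model import (JOINTS, BodyModel, SubjectRecord, build_body_model)
from .constants import G, GRAVITY
from .errors import WbidError
from .formats_io import (BvhNode, ForcePlateRecord, MotionSequence,
                         SensorRecord, SensorSeries, Skeleton, write_bvh,
                         write_forceplate, write_sensor_table)
from .grf import (ContactTimeline, ExternalLoad, GroundReaction,
                  contact_from_states, decompose_grf, hand_loads)
from .inverse_dynamics import JointLoadSeries, static_reactions
from .kinematics import SEGMENT_NODE, SegmentStateSeries, build_states

__all__ = [
    "SyntheticTrial", "generate_stand", "generate_gait", "generate_lift",
    "add_sensor_noise", "contact_profile", "write_fixture", "load_fixture",
    "truth_joint_loads", "truth_total_reaction",
]

#: default IMU placement in the segment frame, relative to the proximal
#: joint centre (m).  Placements are nominal suit positions.
IMU_PLACEMENT = {
    "pelvis": (-0.10, 0.0, 0.03), "torso": (-0.07, 0.0, 0.18),
    "head": (0.02, 0.0, 0.08),
    "upper_arm": (0.02, 0.0, -0.10), "forearm": (0.01, 0.0, -0.08),
    "hand": (0.01, 0.0, -0.04),
    "thigh": (0.04, 0.0, -0.12), "shank": (0.03, 0.0, -0.15),
    "foot": (0.06, 0.0, -0.02),
}

_BVH_NAME = {
    "root": "Hips", "l5s1": "Spine", "neck": "Neck",
    "shoulder_r": "RightArm", "elbow_r": "RightForeArm", "wrist_r": "RightHand",
    "shoulder_l": "LeftArm", "elbow_l": "LeftForeArm", "wrist_l": "LeftHand",
    "hip_r": "RightUpLeg", "knee_r": "RightLeg", "ankle_r": "RightFoot",
    "hip_l": "LeftUpLeg", "knee_l": "LeftLeg", "ankle_l": "LeftFoot",
}

# (node, parent, end_site_child) tree used for generated skeletons
_TREE = [
    ("root", None), ("l5s1", "root"), ("neck", "l5s1"), ("head_top", "neck"),
    ("shoulder_r", "l5s1"), ("elbow_r", "shoulder_r"), ("wrist_r", "elbow_r"),
    ("hand_tip_r", "wrist_r"),
    ("shoulder_l", "l5s1"), ("elbow_l", "shoulder_l"), ("wrist_l", "elbow_l"),
    ("hand_tip_l", "wrist_l"),
    ("hip_r", "root"), ("knee_r", "hip_r"), ("ankle_r", "knee_r"),
    ("toe_r", "ankle_r"),
    ("hip_l", "root"), ("knee_l", "hip_l"), ("ankle_l", "knee_l"),
    ("toe_l", "ankle_l"),
]
_END_SITES = {"head_top", "hand_tip_r", "hand_tip_l", "toe_r", "toe_l"}


@dataclass
class SyntheticTrial:
    """A generated trial and its forward-computed ground truth."""

    kind: str
    subject: SubjectRecord
    model: BodyModel
    motion: MotionSequence
    sensors: SensorSeries
    loads: list[ExternalLoad]
    states: SegmentStateSeries           #: truth kinematic states
    total_force: np.ndarray              #: truth total GRF (n,3)
    total_moment: np.ndarray             #: truth total GRM (n,3)
    contacts: ContactTimeline
    reactions: GroundReaction            #: truth per-foot reactions
    joint_loads: JointLoadSeries         #: truth dynamic joint loads
    joint_loads_static: JointLoadSeries  #: truth static joint loads
    manifest: dict = field(default_factory=dict)
    noise_spec: dict | None = None


# ---------------------------------------------------------------------------
# skeleton / motion assembly

def make_skeleton(model: BodyModel) -> Skeleton:
    """Skeleton for generated trials, offsets from the scaled model."""
    nodes: list[BvhNode] = []
    index = {}
    for name, parent in _TREE:
        offset = model.offsets.get(name, np.zeros(3))
        if name == "root":
            offset = np.zeros(3)
        is_end = name in _END_SITES
        nodes.append(BvhNode(
            name=name, bvh_name=_BVH_NAME.get(name, "End Site"),
            parent=-1 if parent is None else index[parent],
            offset=np.asarray(offset, dtype=float),
            channels=() if is_end else (
                ("Xposition", "Yposition", "Zposition",
                 "Zrotation", "Xrotation", "Yrotation")
                if parent is None else
                ("Zrotation", "Xrotation", "Yrotation")),
            is_end_site=is_end))
        index[name] = len(nodes) - 1
    return Skeleton(nodes)


def _rot_y(theta: np.ndarray) -> np.ndarray:
    """Rotation about the mediolateral (Y) axis, vectorized (n,3,3)."""
    c, s = np.cos(theta), np.sin(theta)
    n = len(theta)
    R = np.zeros((n, 3, 3))
    R[:, 0, 0] = c
    R[:, 0, 2] = s
    R[:, 1, 1] = 1.0
    R[:, 2, 0] = -s
    R[:, 2, 2] = c
    return R


def _motion(model: BodyModel, frame_rate: float, root_position: np.ndarray,
            rotations: dict[str, np.ndarray]) -> MotionSequence:
    return MotionSequence(skeleton=make_skeleton(model), frame_rate=frame_rate,
                          root_position=root_position, rotations=rotations)


def _standing_root_height(model: BodyModel) -> float:
    off = model.offsets
    return -(off["knee_r"][2] + off["ankle_r"][2] + off["toe_r"][2])


def _synth_sensors(states: SegmentStateSeries, model: BodyModel) -> SensorSeries:
    """IMU streams consistent with the truth states.

    The accelerometer reading is the rigid-body point acceleration at the
    sensor location (gravity-free convention); inverting the CoM transfer
    in the pipeline recovers the truth CoM acceleration exactly.
    """
    segments = {}
    for seg, kin in states.segments.items():
        base = seg.rsplit("_", 1)[0] if seg[-2:] in ("_r", "_l") else seg
        # IMU relative to the CoM, segment frame then global
        r_loc = np.asarray(IMU_PLACEMENT[base]) - model.segments[seg].com_offset
        r_si = np.einsum("nij,j->ni", kin.orientation, r_loc)
        pos = kin.com + r_si
        a_si = (kin.acc + np.cross(kin.alpha, r_si)
                + np.cross(kin.omega, np.cross(kin.omega, r_si)))
        segments[seg] = SensorRecord(position=pos, acceleration=a_si,
                                     angular_velocity=kin.omega.copy())
    return SensorSeries(frame_rate=states.frame_rate, segments=segments)


# ---------------------------------------------------------------------------
# independent truth routes

def truth_total_reaction(states: SegmentStateSeries, model: BodyModel,
                         loads: list[ExternalLoad] = ()):
    """Whole-body totals by direct summation (oracle route)."""
    n = states.n_frames
    origin = states.root_position
    F = np.zeros((n, 3))
    M = np.zeros((n, 3))
    for seg, spec in model.segments.items():
        kin = states.segments[seg]
        R = kin.orientation
        Ig = R @ spec.inertia @ np.swapaxes(R, -1, -2)
        spin = (np.einsum("nij,nj->ni", Ig, kin.alpha)
                + np.cross(kin.omega, np.einsum("nij,nj->ni", Ig, kin.omega)))
        W = spec.mass * GRAVITY
        l = kin.com - origin
        F += spec.mass * kin.acc - W
        M += spin + np.cross(l, spec.mass * kin.acc - W)
    for load in loads:
        F -= load.force
        M -= load.moment + np.cross(load.point - origin, load.force)
    return F, M


def _subtree_segments(joint: str) -> list[str]:
    children = {}
    for j, (parent, child) in JOINTS.items():
        children.setdefault(parent, []).append(child)
    out = []

    def visit(seg):
        out.append(seg)
        for c in children.get(seg, []):
            visit(c)

    visit(JOINTS[joint][1])
    return out


def truth_joint_loads(states: SegmentStateSeries, model: BodyModel,
                      loads: list[ExternalLoad], reactions: GroundReaction,
                      flavor: str = "dynamic") -> JointLoadSeries:
    """All 14 joint loads by subtree aggregation (oracle route).

    The wrench at a joint equals the net dynamic deficit of everything
    distal to it: inertial minus applied (weight, external, ground)
    wrenches summed over the distal subtree.  No per-segment recursion.
    """
    n = states.n_frames
    origin = states.root_position
    force, moment = {}, {}
    for joint in JOINTS:
        p_j = states.node_positions[joint]
        F = np.zeros((n, 3))
        M = np.zeros((n, 3))
        subtree = _subtree_segments(joint)
        for seg in subtree:
            spec = model.segments[seg]
            kin = states.segments[seg]
            R = kin.orientation
            Ig = R @ spec.inertia @ np.swapaxes(R, -1, -2)
            spin = (np.einsum("nij,nj->ni", Ig, kin.alpha)
                    + np.cross(kin.omega,
                               np.einsum("nij,nj->ni", Ig, kin.omega)))
            W = spec.mass * GRAVITY
            F += spec.mass * kin.acc - W
            M += spin + np.cross(kin.com - p_j, spec.mass * kin.acc - W)
            for load in loads:
                if load.segment == seg:
                    F -= load.force
                    M -= load.moment + np.cross(load.point - p_j, load.force)
            if seg in ("foot_r", "foot_l"):
                side = seg[-1]
                F -= reactions.force[side]
                M -= (reactions.moment[side]
                      + np.cross(origin - p_j, reactions.force[side]))
        force[joint] = F
        moment[joint] = M
    return JointLoadSeries(flavor=flavor, frame_rate=states.frame_rate,
                           force=force, moment=moment)


def _assemble(kind: str, subject: SubjectRecord, model: BodyModel,
              motion: MotionSequence, load_schedule: dict | None,
              v_th: float, manifest: dict) -> SyntheticTrial:
    states = build_states(motion, None, model)
    sensors = _synth_sensors(states, model)
    loads = []
    if load_schedule is not None and load_schedule.get("mass", 0) > 0:
        loads = hand_loads(states, load_schedule["mass"],
                           tuple(load_schedule["interval"]),
                           tuple(load_schedule.get("split", (0.5, 0.5))),
                           ramp_frames=int(load_schedule.get("ramp_frames", 0)))
    F, M = truth_total_reaction(states, model, loads)
    contacts = contact_from_states(states, v_th=v_th)
    reactions = decompose_grf(F, M, contacts, states, model)
    jl_dyn = truth_joint_loads(states, model, loads, reactions, "dynamic")
    react_static = static_reactions(states, model, loads, contacts)
    jl_stat = truth_joint_loads(states.zeroed(), model, loads, react_static,
                                "static")
    return SyntheticTrial(kind=kind, subject=subject, model=model,
                          motion=motion, sensors=sensors, loads=loads,
                          states=states, total_force=F, total_moment=M,
                          contacts=contacts, reactions=reactions,
                          joint_loads=jl_dyn, joint_loads_static=jl_stat,
                          manifest=manifest)


# ---------------------------------------------------------------------------
# generators

def generate_stand(subject: SubjectRecord, duration: float = 8.0,
                   sway_amplitude: float = 0.0, sway_freq: float = 0.3,
                   lateral_offset: float = 0.0,
                   frame_rate: float = 120.0, seed: int = 0) -> SyntheticTrial:
    """Quiet double stance with optional low-frequency anterior CoM sway.

    ``lateral_offset`` shifts the pelvis toward the right foot (negative
    Y), producing an asymmetric static weight distribution.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    model = build_body_model(subject)
    n = int(round(duration * frame_rate))
    t = np.arange(n) / frame_rate
    root = np.zeros((n, 3))
    root[:, 0] = sway_amplitude * np.sin(2 * np.pi * sway_freq * t)
    root[:, 1] = -lateral_offset
    root[:, 2] = _standing_root_height(model)
    motion = _motion(model, frame_rate, root, {})
    manifest = {"kind": "stand", "seed": seed, "duration": duration,
                "sway_amplitude": sway_amplitude, "sway_freq": sway_freq,
                "lateral_offset": lateral_offset, "frame_rate": frame_rate}
    return _assemble("stand", subject, model, motion, None, 1.2, manifest)


def generate_gait(subject: SubjectRecord, speed: float = 1.1,
                  cycle_duration: float = 1.1, n_cycles: int = 2,
                  hip_amplitude_deg: float | None = None,
                  knee_amplitude_deg: float = 25.0,
                  arm_amplitude_deg: float = 10.0,
                  frame_rate: float = 120.0, seed: int = 0) -> SyntheticTrial:
    """Template gait: forward progression with alternating leg swing.

    Sinusoid-composed hip/knee/arm angle trajectories with a vertical
    pelvis bob; foot-ground contact timing emerges from the toe/heel
    speed traces through the standard detector, which keeps the trial's
    truth self-consistent with its kinematics.  By default the hip
    amplitude is matched to the progression speed (peak backward foot
    speed equal to the forward speed), which makes the stance foot
    near-stationary and yields clean alternating single stances joined by
    short double-stance windows.
    """
    if not 0.3 <= speed <= 2.5:
        raise ValueError(f"gait speed {speed} m/s outside [0.3, 2.5]")
    model = build_body_model(subject)
    n = int(round(n_cycles * cycle_duration * frame_rate))
    t = np.arange(n) / frame_rate
    phi = 2 * np.pi * t / cycle_duration
    leg = -(model.offsets["knee_r"][2] + model.offsets["ankle_r"][2])
    if hip_amplitude_deg is None:
        A_h = speed * cycle_duration / (2 * np.pi * leg)
    else:
        A_h = np.deg2rad(hip_amplitude_deg)
    A_k = np.deg2rad(knee_amplitude_deg)
    A_a = np.deg2rad(arm_amplitude_deg)

    bob = leg * (1 - np.cos(A_h))
    root = np.zeros((n, 3))
    root[:, 0] = speed * t
    root[:, 2] = _standing_root_height(model) - 0.5 * bob * (1 - np.cos(2 * phi))

    rotations = {
        "hip_r": _rot_y(-A_h * np.sin(phi)),
        "hip_l": _rot_y(A_h * np.sin(phi)),
        "knee_r": _rot_y(A_k * (0.5 + 0.5 * np.cos(phi)) ** 2),
        "knee_l": _rot_y(A_k * (0.5 - 0.5 * np.cos(phi)) ** 2),
        "shoulder_r": _rot_y(A_a * np.sin(phi)),
        "shoulder_l": _rot_y(-A_a * np.sin(phi)),
    }
    motion = _motion(model, frame_rate, root, rotations)

    # feet must stay near the ground plane
    from .kinematics import forward_kinematics
    pose = forward_kinematics(motion, model)
    lowest = min(float(pose.node_positions[p][:, 2].min())
                 for p in ("toe_r", "toe_l", "heel_r", "heel_l"))
    if lowest < -0.12:
        raise WbidError(f"gait template penetrates the ground by {-lowest:.2f} m")

    manifest = {"kind": "gait", "seed": seed, "speed": speed,
                "cycle_duration": cycle_duration, "n_cycles": n_cycles,
                "hip_amplitude_deg": hip_amplitude_deg,
                "knee_amplitude_deg": knee_amplitude_deg,
                "frame_rate": frame_rate}
    return _assemble("gait", subject, model, motion, None, 1.2, manifest)


def generate_lift(subject: SubjectRecord, box_mass: float = 17.0,
                  phase_durations: tuple[float, float, float] = (1.0, 1.4, 1.0),
                  quiet: float = 0.8, torso_flexion_deg: float = 60.0,
                  shoulder_flexion_deg: float = 70.0, impact: bool = False,
                  frame_rate: float = 120.0, seed: int = 0) -> SyntheticTrial:
    """Stoop lift of a hand-held box: bend down, lift/carry, stand up.

    The box weight acts at the hand end points during the lift phase
    (symmetric two-handed carry) with a short cosine grip ramp; the
    ``impact`` toggle adds a brief high-frequency arm transient at box
    deposit, visible in the dynamic but not the static loads.
    """
    if box_mass < 0:
        raise ValueError("box_mass must be non-negative")
    model = build_body_model(subject)
    bend, lift, stand = phase_durations
    total = quiet + bend + lift + stand + quiet
    n = int(round(total * frame_rate))
    t = np.arange(n) / frame_rate

    def ease(t0, t1, a0, a1):
        out = np.zeros(n)
        out[t < t0] = a0
        sel = (t >= t0) & (t < t1)
        out[sel] = a0 + (a1 - a0) * (0.5 - 0.5 * np.cos(
            np.pi * (t[sel] - t0) / (t1 - t0)))
        out[t >= t1] = a1
        return out

    t0 = quiet
    t1 = quiet + bend          # grip begins
    t2 = t1 + lift             # deposit / release
    t3 = t2 + stand
    th_t = np.deg2rad(torso_flexion_deg)
    th_s = np.deg2rad(shoulder_flexion_deg)

    torso = ease(t0, t1, 0.0, th_t) + ease(t1, t2, 0.0, -0.8 * th_t) \
        + ease(t2, t3, 0.0, -0.2 * th_t)
    shoulder = -(ease(t0, t1, 0.0, th_s) + ease(t1, t2, 0.0, -0.5 * th_s)
                 + ease(t2, t3, 0.0, -0.5 * th_s))
    if impact:
        t_dep = t2 - 0.1
        wig = np.where(t >= t_dep,
                       np.deg2rad(3.0) * np.sin(2 * np.pi * 12 * (t - t_dep))
                       * np.exp(-(t - t_dep) / 0.08), 0.0)
        shoulder = shoulder + wig

    rotations = {
        "l5s1": _rot_y(torso),
        "shoulder_r": _rot_y(shoulder),
        "shoulder_l": _rot_y(shoulder),
        "elbow_r": _rot_y(0.3 * shoulder),
        "elbow_l": _rot_y(0.3 * shoulder),
    }
    root = np.zeros((n, 3))
    root[:, 2] = _standing_root_height(model)
    motion = _motion(model, frame_rate, root, rotations)

    grip = (int(round(t1 * frame_rate)), int(round(t2 * frame_rate)))
    schedule = {"mass": box_mass, "interval": list(grip),
                "split": [0.5, 0.5], "ramp_frames": int(0.15 * frame_rate)}
    manifest = {"kind": "lift", "seed": seed, "box_mass": box_mass,
                "phase_durations": list(phase_durations), "quiet": quiet,
                "impact": impact, "frame_rate": frame_rate,
                "load_schedule": schedule,
                "phases": {"bend": [int(t0 * frame_rate), grip[0]],
                           "lift": list(grip),
                           "stand": [grip[1], int(t3 * frame_rate)]}}
    return _assemble("lift", subject, model, motion, schedule, 1.2, manifest)


def add_sensor_noise(trial: SyntheticTrial, accel_sd: float = 0.0,
                     gyro_sd: float = 0.0, seed: int = 0) -> SyntheticTrial:
    """Additive Gaussian sensor noise; truth members are untouched."""
    if accel_sd < 0 or gyro_sd < 0:
        raise ValueError("noise SDs must be non-negative")
    rng = np.random.default_rng(seed)
    segments = {}
    for seg, rec in trial.sensors.segments.items():
        segments[seg] = SensorRecord(
            position=rec.position.copy(),
            acceleration=rec.acceleration
            + rng.normal(0.0, accel_sd, rec.acceleration.shape),
            angular_velocity=rec.angular_velocity
            + rng.normal(0.0, gyro_sd, rec.angular_velocity.shape))
    noisy = SensorSeries(frame_rate=trial.sensors.frame_rate, segments=segments)
    out = SyntheticTrial(**{**trial.__dict__, "sensors": noisy,
                            "noise_spec": {"accel_sd": accel_sd,
                                           "gyro_sd": gyro_sd, "seed": seed}})
    return out


# ---------------------------------------------------------------------------
# prescribed contact-event profiles

def _bump(t: np.ndarray, t0: float, t1: float, peak: float) -> np.ndarray:
    out = np.zeros_like(t)
    sel = (t >= t0) & (t <= t1)
    out[sel] = peak * np.sin(np.pi * (t[sel] - t0) / (t1 - t0)) ** 2
    return out


def contact_profile(kind: str = "gait", frame_rate: float = 120.0,
                    v_th: float = 1.2) -> dict:
    """Analytic toe/heel speed profiles with known transition frames.

    Kinds: ``gait`` (heel-rule toe-off then threshold heel-strike),
    ``leg_lift`` (slow lift: heel rule only), ``weight_shift`` (left foot
    unloads and re-plants).  Returns toe/heel speed traces, the expected
    stance-state transitions, and the designed event frames.
    """
    fs = frame_rate
    if kind == "gait":
        n = int(1.3 * fs)
        t = np.arange(n) / fs
        heel = _bump(t, 0.35, 0.65, 1.0) + _bump(t, 0.62, 1.0, 2.2)
        toe = 0.15 + _bump(t, 0.45, 0.95, 2.3)
        toe_off = int(np.ceil(0.5 * fs))  # heel-speed peak of the first bump
        # first sample after the toe peak with toe < v_th
        s = np.sqrt((v_th - 0.15) / 2.3)
        t_hs = 0.45 + 0.5 * (1 - np.arcsin(s) / np.pi)
        heel_strike = int(np.ceil(t_hs * fs))
        events = {"toe_off": toe_off, "heel_strike": heel_strike}
        truth = np.ones(n, dtype=bool)
        truth[toe_off:heel_strike] = False
    elif kind == "leg_lift":
        n = int(3.0 * fs)
        t = np.arange(n) / fs
        heel = _bump(t, 1.0, 1.6, 0.8)
        toe = heel.copy()
        lift = int(np.ceil(1.3 * fs))
        settle = int(np.ceil(1.6 * fs))
        events = {"lift": lift, "settle": settle}
        truth = np.ones(n, dtype=bool)
        truth[lift:settle] = False
    elif kind == "weight_shift":
        n = int(4.0 * fs)
        t = np.arange(n) / fs
        heel = _bump(t, 1.0, 1.5, 0.6) + _bump(t, 2.5, 3.0, 0.5)
        toe = heel.copy()
        events = {"window": (int(1.0 * fs), int(3.0 * fs)),
                  "lift": int(np.ceil(1.25 * fs)),
                  "replant": int(np.ceil(2.75 * fs))}
        truth = None
    else:
        raise ValueError(f"unknown profile kind {kind!r}")
    return {"toe_speed": toe, "heel_speed": heel, "truth_stance": truth,
            "events": events, "frame_rate": fs, "v_th": v_th}


# ---------------------------------------------------------------------------
# fixture directories

def write_fixture(trial: SyntheticTrial, outdir) -> Path:
    """Write a complete plain-text fixture directory for a trial."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_bvh(trial.motion, out / "motion.bvh")
    write_sensor_table(trial.sensors, out / "sensors.csv")

    root = trial.states.root_position
    plates = {}
    for side in "rl":
        F = trial.reactions.force[side]
        M0 = trial.reactions.moment[side] + np.cross(root, F)
        plates[side] = {"force": F, "moment": M0, "origin": np.zeros(3)}
    n = trial.states.n_frames
    record = ForcePlateRecord(
        time=np.arange(n) / trial.states.frame_rate, plates=plates)
    write_forceplate(record, out / "plates.csv")

    frames = np.arange(n)
    pd.DataFrame({
        "frame": frames,
        "fx": trial.total_force[:, 0], "fy": trial.total_force[:, 1],
        "fz": trial.total_force[:, 2],
        "mx": trial.total_moment[:, 0], "my": trial.total_moment[:, 1],
        "mz": trial.total_moment[:, 2],
        "stance_r": trial.contacts.stance["r"].astype(int),
        "stance_l": trial.contacts.stance["l"].astype(int),
    }).to_csv(out / "truth_totals.csv", index=False, float_format="%.17g")

    rows = []
    for jls, flavor in ((trial.joint_loads, "dynamic"),
                        (trial.joint_loads_static, "static")):
        for joint in jls.force:
            df = pd.DataFrame(
                np.hstack([jls.force[joint], jls.moment[joint]]),
                columns=["fx", "fy", "fz", "mx", "my", "mz"])
            df.insert(0, "frame", frames)
            df.insert(1, "joint", joint)
            df.insert(2, "flavor", flavor)
            rows.append(df)
    pd.concat(rows).to_csv(out / "truth_joint_loads.csv", index=False,
                           float_format="%.17g")

    manifest = dict(trial.manifest)
    manifest["subject"] = {"height": trial.subject.height,
                           "mass": trial.subject.mass,
                           "sex": trial.subject.sex}
    manifest["bvh_unit"] = 0.01
    manifest["files"] = {"motion": "motion.bvh", "sensors": "sensors.csv",
                         "plates": "plates.csv"}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def load_fixture(fixture_dir):
    """Read a fixture directory back: (subject, motion, sensors, manifest)."""
    from .formats_io import read_bvh, read_sensor_table
    d = Path(fixture_dir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    subject = SubjectRecord(**manifest["subject"])
    motion = read_bvh(d / manifest["files"]["motion"],
                      unit=manifest.get("bvh_unit", 0.01))
    sensors = read_sensor_table(d / manifest["files"]["sensors"])
    return subject, motion, sensors, manifest
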