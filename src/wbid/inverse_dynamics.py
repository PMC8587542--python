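"""Recursive Newton-Euler solution for the 14 net joint loads.

Two recursions meet at the trunk: the upper body is solved top-down
(hands -> wrists -> elbows -> shoulders, head -> neck, then torso ->
L5/S1) starting from the known weight of hand-held objects, and the lower
body bottom-up (feet -> ankles -> knees -> hips) starting from the
estimated per-foot ground reactions.  Every joint load is the wrench the
proximal segment applies to the distal segment at the joint centre;
moment balance is about each segment's CoM in the global frame.

The static flavour reruns the identical recursion on posture-only states
(all linear/angular accelerations and angular velocities zeroed) with the
ground reactions recomputed under the same zeroing, mirroring posture-
based static strength analysis.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass

from .body_model import BodyModel, joint_tree
from .errors import SolverError
from .grf import (ContactTimeline, ExternalLoad, GroundReaction,
                  decompose_grf, total_grf, total_grm)
from .kinematics import SegmentStateSeries
from .newton_euler import segment_wrench_balance

__all__ = ["JointLoadSeries", "segment_balance", "solve_dynamic",
           "solve_static", "static_reactions", "peak_ratio",
           "pelvis_residual"]

# re-exported primitive: one segment's balance solved for its proximal wrench
segment_balance = segment_wrench_balance


@dataclass
class JointLoadSeries:
    """Net 3-D force and moment at each of the 14 joints, per frame."""

    flavor: str                      #: 'dynamic' or 'static'
    frame_rate: float
    force: dict[str, np.ndarray]     #: joint -> (n,3) N
    moment: dict[str, np.ndarray]    #: joint -> (n,3) N*m

    @property
    def n_frames(self) -> int:
        return next(iter(self.force.values())).shape[0]

    @property
    def joints(self) -> list[str]:
        return list(self.force)

    def moment_norm(self, joint: str) -> np.ndarray:
        return np.linalg.norm(self.moment[joint], axis=1)


def _solve(states: SegmentStateSeries, model: BodyModel,
           loads: list[ExternalLoad], reactions: GroundReaction,
           flavor: str) -> JointLoadSeries:
    by_segment: dict[str, list[ExternalLoad]] = {}
    for load in loads:
        by_segment.setdefault(load.segment, []).append(load)

    force: dict[str, np.ndarray] = {}
    moment: dict[str, np.ndarray] = {}
    for seg in joint_tree(model):
        spec = model.segments[seg]
        if spec.proximal_joint is None:  # pelvis: no proximal joint to solve
            continue
        kin = states.segments[seg]
        children = []
        for j in spec.distal_joints:
            child = model.joints[j].child_segment
            if j not in force:
                raise SolverError(f"distal joint {j!r} unsolved before {seg!r}")
            children.append((force[j], moment[j], states.node_positions[j]))
        externals = [(l.force, l.moment, l.point) for l in by_segment.get(seg, [])]
        ground = None
        if seg in ("foot_r", "foot_l"):
            side = seg[-1]
            ground = (reactions.force[side], reactions.moment[side],
                      reactions.reference_point)
        j = spec.proximal_joint
        force[j], moment[j] = segment_wrench_balance(
            spec, kin, states.node_positions[j],
            children=children, externals=externals, ground=ground)

    return JointLoadSeries(flavor=flavor, frame_rate=states.frame_rate,
                           force=force, moment=moment)


def solve_dynamic(states: SegmentStateSeries, model: BodyModel,
                  loads: list[ExternalLoad],
                  reactions: GroundReaction) -> JointLoadSeries:
    """Net loads at all 14 joints with inertial terms retained."""
    if reactions is None:
        raise SolverError("per-foot ground reactions are required")
    return _solve(states, model, loads, reactions, "dynamic")


def static_reactions(states: SegmentStateSeries, model: BodyModel,
                     loads: list[ExternalLoad],
                     contacts: ContactTimeline) -> GroundReaction:
    """Ground reactions recomputed with all segment motion zeroed."""
    zeroed = states.zeroed()
    F_g = total_grf(zeroed, model, loads)
    M_g = total_grm(zeroed, model, loads)
    return decompose_grf(F_g, M_g, contacts, zeroed, model)


def solve_static(states: SegmentStateSeries, model: BodyModel,
                 loads: list[ExternalLoad],
                 contacts: ContactTimeline | None = None,
                 reactions: GroundReaction | None = None) -> JointLoadSeries:
    """Posture-only net joint loads.

    Identical recursion with every segment's accelerations and angular
    velocity set to zero.  The per-foot reactions are recomputed under the
    same zeroing, either from ``contacts`` (preferred) or reusing the
    stance states of precomputed ``reactions``.
    """
    if contacts is None and reactions is None:
        raise SolverError("solve_static needs a contact timeline or reactions")
    zeroed = states.zeroed()
    if contacts is not None:
        stat_reactions = static_reactions(states, model, loads, contacts)
    else:
        timeline = ContactTimeline(
            v_th=np.nan, stance=reactions.stance,
            toe_speed={}, heel_speed={}, heel_accel={})
        stat_reactions = static_reactions(states, model, loads, timeline)
    result = _solve(zeroed, model, loads, stat_reactions, "static")
    return result


def peak_ratio(dynamic: JointLoadSeries, static: JointLoadSeries,
               joint: str) -> float:
    """Peak dynamic over peak static net-moment magnitude for a joint."""
    peak_d = float(dynamic.moment_norm(joint).max())
    peak_s = float(static.moment_norm(joint).max())
    if peak_s == 0.0:
        raise ZeroDivisionError(f"joint {joint!r}: zero static peak moment")
    return peak_d / peak_s


def pelvis_residual(states: SegmentStateSeries, model: BodyModel,
                    loads: list[ExternalLoad], jls: JointLoadSeries):
    """Force/moment closure residual of the pelvis equations of motion.

    The pelvis is the only segment never solved for: its balance, using
    the L5/S1 wrench from the top-down chain and the hip wrenches from the
    bottom-up chain, closes to zero exactly when the per-foot reactions
    are consistent with the whole-body totals.
    """
    from .constants import GRAVITY

    spec = model.segments["pelvis"]
    kin = states.segments["pelvis"]
    com = kin.com
    F = spec.mass * kin.acc - spec.mass * GRAVITY
    from .newton_euler import spin_moment
    M = spin_moment(spec, kin)
    for j in ("l5s1", "hip_r", "hip_l"):
        F = F + jls.force[j]
        M = M + jls.moment[j] + np.cross(states.node_positions[j] - com,
                                         jls.force[j])
    for load in loads:
        if load.segment == "pelvis":
            F = F - load.force
            M = M - load.moment - np.cross(load.point - com, load.force)
    return F, M
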