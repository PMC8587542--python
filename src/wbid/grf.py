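"""Ground reaction estimation: totals, foot contact, and decomposition.

The total ground reaction force is the whole-body Newton balance

    F_g = sum_i (m_i a_i - W_i - F_ex,i)

and the total reaction moment about the pelvic frame origin is

    M_g = sum_i (M*_i + l_i x m_i a_i - l_i x W_i - M_ex,i - l_ex,i x F_ex,i)

with ``l_i`` the segment CoM relative to the pelvic origin and
``M*_i = I_i alpha_i + omega_i x I_i omega_i``.

Per-foot contact is detected by a velocity-threshold state machine: a foot
enters stance when its toe speed drops below ``v_th`` and leaves stance
when the toe speed exceeds ``v_th`` or — to separate toe-off from a slow
leg lift — when the heel tangential acceleration switches sign from
positive to negative while the toe stays slow (the heel reaches its
maximum speed at toe-off).

During double stance the split of (F_g, M_g) between the feet is
statically indeterminate and is resolved by minimizing the sum of squared
net joint moments of the closed stance chain (both ankles, knees, hips)
subject to the force/moment totals and non-negative vertical components —
a convex QP with exactly one box-constrained coordinate, solved exactly by
bounded least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .body_model import BodyModel
from .constants import G, GRAVITY
from .errors import SolverError
from .kinematics import SegmentStateSeries, differentiate, lowpass_filter
from .newton_euler import segment_wrench_balance, spin_moment

__all__ = [
    "ExternalLoad", "GroundReaction", "ContactTimeline",
    "hand_loads", "total_grf", "total_grm",
    "detect_contact", "contact_from_states", "decompose_grf",
    "stance_moment_map",
]

log = logging.getLogger(__name__)

_LEG = {"r": ("foot_r", "shank_r", "thigh_r", "ankle_r", "knee_r", "hip_r"),
        "l": ("foot_l", "shank_l", "thigh_l", "ankle_l", "knee_l", "hip_l")}


@dataclass
class ExternalLoad:
    """An external wrench applied to one segment over an interval."""

    segment: str
    force: np.ndarray    #: (n,3) N, zero outside the active interval
    moment: np.ndarray   #: (n,3) N*m
    point: np.ndarray    #: (n,3) m, global application point
    name: str = "load"


def hand_loads(states: SegmentStateSeries, mass: float,
               interval: tuple[int, int], split: tuple[float, float] = (0.5, 0.5),
               ramp_frames: int = 0) -> list[ExternalLoad]:
    """Hand-held object of ``mass`` kg carried between two frames.

    The object's weight is applied at the hand end points, divided
    right/left by ``split`` (default symmetric two-handed carry), with an
    optional cosine on/off ramp.
    """
    n = states.n_frames
    window = np.zeros(n)
    a, b = interval
    window[a:b] = 1.0
    if ramp_frames > 0:
        r = 0.5 - 0.5 * np.cos(np.linspace(0.0, np.pi, ramp_frames))
        window[a:min(a + ramp_frames, n)] = r[:max(0, min(a + ramp_frames, n) - a)]
        if b - ramp_frames >= 0 and b <= n:
            window[max(b - ramp_frames, 0):b] = r[::-1][:b - max(b - ramp_frames, 0)]
    loads = []
    for side, frac in zip("rl", split):
        force = np.zeros((n, 3))
        force[:, 2] = -mass * frac * G * window
        loads.append(ExternalLoad(
            segment=f"hand_{side}", force=force, moment=np.zeros((n, 3)),
            point=states.node_positions[f"hand_tip_{side}"],
            name=f"held_mass_{side}"))
    return loads


@dataclass
class ContactTimeline:
    """Per-frame stance/swing state per foot with the traces behind it."""

    v_th: float
    stance: dict[str, np.ndarray]      #: foot -> (n,) bool
    toe_speed: dict[str, np.ndarray]
    heel_speed: dict[str, np.ndarray]
    heel_accel: dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return next(iter(self.stance.values())).shape[0]

    def transitions(self, foot: str) -> list[tuple[int, str]]:
        s = self.stance[foot].astype(int)
        out = []
        for t in np.flatnonzero(np.diff(s)) + 1:
            out.append((int(t), "stance" if s[t] else "swing"))
        return out


@dataclass
class GroundReaction:
    """Total and per-foot ground reaction series.

    Per-foot moments are expressed about the pelvic frame origin (same
    convention as the total), so that right + left equals the total
    identically; ``app_point`` carries the nominal centre of application
    (vertical projection of the ankle onto the ground plane).
    """

    frame_rate: float
    force_total: np.ndarray                #: (n,3) N
    moment_total: np.ndarray               #: (n,3) N*m, about pelvic origin
    force: dict[str, np.ndarray]           #: foot -> (n,3)
    moment: dict[str, np.ndarray]          #: foot -> (n,3), about pelvic origin
    app_point: dict[str, np.ndarray]       #: foot -> (n,3)
    stance: dict[str, np.ndarray]          #: foot -> (n,) bool
    residual_force: np.ndarray = None      #: (n,3), unassigned total (flight)
    reference_point: np.ndarray = None     #: (n,3) pelvic origin used for moments


def total_grf(states: SegmentStateSeries, model: BodyModel,
              loads: list[ExternalLoad] = ()) -> np.ndarray:
    """Total ground reaction force per frame (reaction on the body, +Z up)."""
    n = states.n_frames
    F = np.zeros((n, 3))
    for seg, spec in model.segments.items():
        kin = states.segments[seg]
        F += spec.mass * kin.acc - spec.mass * GRAVITY
    for load in loads:
        F -= load.force
    return F


def total_grm(states: SegmentStateSeries, model: BodyModel,
              loads: list[ExternalLoad] = ()) -> np.ndarray:
    """Total ground reaction moment about the pelvic frame origin."""
    n = states.n_frames
    origin = states.root_position
    M = np.zeros((n, 3))
    for seg, spec in model.segments.items():
        kin = states.segments[seg]
        l = kin.com - origin
        M += spin_moment(spec, kin)
        M += np.cross(l, spec.mass * kin.acc)
        M -= np.cross(l, spec.mass * GRAVITY)
    for load in loads:
        M -= load.moment
        M -= np.cross(load.point - origin, load.force)
    return M


# ---------------------------------------------------------------------------
# contact detection

def _foot_states(toe_speed: np.ndarray, heel_speed: np.ndarray,
                 heel_accel: np.ndarray, v_th: float,
                 heel_min: float = 0.0, accel_tol: float = 1e-8) -> np.ndarray:
    n = len(toe_speed)
    stance = np.empty(n, dtype=bool)
    stance[0] = toe_speed[0] < v_th
    lifted = False  # swing entered through the heel-acceleration rule
    for t in range(1, n):
        if stance[t - 1]:
            if toe_speed[t] >= v_th:
                stance[t] = False
                lifted = False
            elif (heel_speed[t] >= heel_min
                  and heel_accel[t - 1] >= -accel_tol
                  and heel_accel[t] < -accel_tol):
                # heel speed peaked: toe-off / leg lift while the toe is slow
                stance[t] = False
                lifted = True
            else:
                stance[t] = True
        else:
            if toe_speed[t] < v_th:
                if not lifted:
                    stance[t] = True
                elif heel_accel[t] >= -accel_tol and heel_speed[t] < v_th:
                    # foot has stopped decelerating: settled again
                    stance[t] = True
                    lifted = False
                else:
                    stance[t] = False
            else:
                stance[t] = False
                lifted = False
    return stance


def detect_contact(toe_speed: dict[str, np.ndarray],
                   heel_speed: dict[str, np.ndarray],
                   v_th: float = 1.2, frame_rate: float = 120.0,
                   heel_min_fraction: float = 0.25) -> ContactTimeline:
    """Run the per-foot contact state machine on speed traces.

    ``toe_speed``/``heel_speed`` map foot labels to 1-D speed magnitude
    traces (m/s) or (n,3) velocity vectors (norm taken).  The default
    threshold is 1.2 m/s, the average walking speed of a healthy adult.
    The heel-acceleration (toe-off / leg-lift) rule only fires when the
    heel speed at its peak reaches ``heel_min_fraction * v_th`` — a
    prominence guard against millimetre-scale stance micro-motion.
    """
    if v_th <= 0:
        raise ValueError("v_th must be positive")
    toe = {f: _as_speed(v) for f, v in toe_speed.items()}
    heel = {f: _as_speed(v) for f, v in heel_speed.items()}
    for f in toe:
        if toe[f].shape != heel[f].shape:
            raise ValueError(f"foot {f!r}: toe and heel traces differ in length")
    accel = {f: differentiate(heel[f], frame_rate) for f in heel}
    stance = {f: _foot_states(toe[f], heel[f], accel[f], v_th,
                              heel_min=heel_min_fraction * v_th)
              for f in toe}
    return ContactTimeline(v_th=v_th, stance=stance, toe_speed=toe,
                           heel_speed=heel, heel_accel=accel)


def _as_speed(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return np.linalg.norm(v, axis=1) if v.ndim == 2 else v


def contact_from_states(states: SegmentStateSeries, v_th: float = 1.2,
                        cutoff: float | None = None) -> ContactTimeline:
    """Contact timeline from toe/heel landmark trajectories of the states."""
    fs = states.frame_rate
    toe, heel = {}, {}
    for side in "rl":
        pt = states.node_positions[f"toe_{side}"]
        ph = states.node_positions[f"heel_{side}"]
        if cutoff is not None:
            pt = lowpass_filter(pt, cutoff, fs)
            ph = lowpass_filter(ph, cutoff, fs)
        toe[side] = np.linalg.norm(differentiate(pt, fs), axis=1)
        heel[side] = np.linalg.norm(differentiate(ph, fs), axis=1)
    return detect_contact(toe, heel, v_th=v_th, frame_rate=fs)


# ---------------------------------------------------------------------------
# double-stance decomposition

def _leg_chain_moments(states, model, side, F_foot, M_foot, origin):
    """Ankle/knee/hip net moments of one leg given its ground wrench.

    ``M_foot`` is about the pelvic origin series ``origin``.  Returns a
    (n, 3, 3) array (joint, component) stacked [ankle, knee, hip].
    """
    foot, shank, thigh, ankle, knee, hip = _LEG[side]
    np_ = states.node_positions
    F_a, M_a = segment_wrench_balance(
        model.segments[foot], states.segments[foot], np_[ankle],
        ground=(F_foot, M_foot, origin))
    F_k, M_k = segment_wrench_balance(
        model.segments[shank], states.segments[shank], np_[knee],
        children=[(F_a, M_a, np_[ankle])])
    F_h, M_h = segment_wrench_balance(
        model.segments[thigh], states.segments[thigh], np_[hip],
        children=[(F_k, M_k, np_[knee])])
    return np.stack([M_a, M_k, M_h], axis=1)


def stance_moment_map(states: SegmentStateSeries, model: BodyModel,
                      F_g: np.ndarray, M_g: np.ndarray):
    """Affine map from the right-foot wrench to the six stance-chain moments.

    The decomposition unknown is x = (F_rg, M_rg) with the left wrench
    eliminated through the totals.  Every chain moment is affine in x, so
    stacking the six joint moments gives per-frame matrices A (n, 18, 6)
    and offsets c0 (n, 18) with  m(x) = c0 + A x.
    """
    n = states.n_frames
    origin = states.root_position
    zeros = np.zeros((n, 3))

    def chain(x):
        F_r = np.broadcast_to(x[:3], (n, 3))
        M_r = np.broadcast_to(x[3:], (n, 3))
        right = _leg_chain_moments(states, model, "r", F_r, M_r, origin)
        left = _leg_chain_moments(states, model, "l", F_g - F_r, M_g - M_r, origin)
        return np.concatenate([right, left], axis=1).reshape(n, 18)

    c0 = chain(np.zeros(6))
    A = np.empty((n, 18, 6))
    for k in range(6):
        e = np.zeros(6)
        e[k] = 1.0
        A[:, :, k] = chain(e) - c0
    return A, c0


def _solve_bounded_lsq(A, b, lo, hi, reg):
    """argmin ||A x - b||^2 + reg ||x||^2  s.t.  lo <= x[2] <= hi.

    With a single box-constrained coordinate the solution is exact: solve
    unconstrained; if x[2] violates a bound, clamp it there and re-solve
    the remaining coordinates (the partially minimized cost is a 1-D
    convex quadratic in x[2], so clamping to the nearest bound is optimal).
    """
    Aa = np.vstack([A, np.sqrt(reg) * np.eye(6)])
    ba = np.concatenate([b, np.zeros(6)])
    x, *_ = np.linalg.lstsq(Aa, ba, rcond=None)
    if lo <= x[2] <= hi:
        return x
    z = float(np.clip(x[2], lo, hi))
    keep = [0, 1, 3, 4, 5]
    xr, *_ = np.linalg.lstsq(Aa[:, keep], ba - Aa[:, 2] * z, rcond=None)
    out = np.empty(6)
    out[keep] = xr
    out[2] = z
    return out


def decompose_grf(F_g: np.ndarray, M_g: np.ndarray, contacts: ContactTimeline,
                  states: SegmentStateSeries, model: BodyModel,
                  reg: float = 1e-12) -> GroundReaction:
    """Split the total ground reaction between the feet.

    Single stance assigns the full total to the stance foot; flight frames
    leave both feet unloaded and log the residual; double-stance frames
    minimize the summed squared net moments of the closed stance chain
    (ankles, knees, hips) subject to the totals and to non-negative
    vertical components on both feet.
    """
    n = F_g.shape[0]
    origin = states.root_position
    force = {f: np.zeros((n, 3)) for f in "rl"}
    moment = {f: np.zeros((n, 3)) for f in "rl"}
    residual = np.zeros((n, 3))

    s_r, s_l = contacts.stance["r"], contacts.stance["l"]
    single_r = s_r & ~s_l
    single_l = s_l & ~s_r
    double = s_r & s_l
    flight = ~s_r & ~s_l

    force["r"][single_r] = F_g[single_r]
    moment["r"][single_r] = M_g[single_r]
    force["l"][single_l] = F_g[single_l]
    moment["l"][single_l] = M_g[single_l]
    residual[flight] = F_g[flight]
    if flight.any():
        log.info("flight phase on %d frames; residual total GRF left "
                 "unassigned (max %.1f N)", int(flight.sum()),
                 float(np.abs(F_g[flight]).max()))

    if double.any():
        A, c0 = stance_moment_map(states, model, F_g, M_g)
        idx = np.flatnonzero(double)
        for t in idx:
            lo, hi = sorted((0.0, float(F_g[t, 2])))
            try:
                x = _solve_bounded_lsq(A[t], -c0[t], lo, hi, reg)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SolverError(f"decomposition failed at frame {t}: {exc}")
            force["r"][t], moment["r"][t] = x[:3], x[3:]
            force["l"][t] = F_g[t] - x[:3]
            moment["l"][t] = M_g[t] - x[3:]

    app = {}
    for side in "rl":
        ankle = states.node_positions[f"ankle_{side}"]
        app[side] = np.column_stack([ankle[:, 0], ankle[:, 1], np.zeros(n)])

    return GroundReaction(frame_rate=states.frame_rate, force_total=F_g,
                          moment_total=M_g, force=force, moment=moment,
                          app_point=app, stance={"r": s_r, "l": s_l},
                          residual_force=residual, reference_point=origin)
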