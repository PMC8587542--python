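"""Single-segment Newton-Euler balance, vectorized over frames.

Joint-load convention: the wrench at a joint is the force/moment the
proximal (parent) segment applies to the distal (child) segment at the
joint centre.  Solving a segment's equations of motion for its proximal
joint wrench, given the wrenches it applies to its children and any
external or ground wrenches acting on it, is the primitive both recursion
directions (top-down from the hands, bottom-up from the feet) are built
from.  Moment balance is taken about the segment CoM in the global frame.
"""

from __future__ import annotations

import numpy as np

from .constants import GRAVITY

__all__ = ["segment_wrench_balance", "spin_moment"]


def spin_moment(spec, kin) -> np.ndarray:
    """Rate of change of angular momentum about the CoM, global frame.

    M* = I_g alpha + omega x (I_g omega), with I_g = R I_local R^T.
    """
    R = kin.orientation
    Ig = R @ spec.inertia @ np.swapaxes(R, -1, -2)
    Iw = np.einsum("nij,nj->ni", Ig, kin.omega)
    Ia = np.einsum("nij,nj->ni", Ig, kin.alpha)
    return Ia + np.cross(kin.omega, Iw)


def segment_wrench_balance(spec, kin, p_prox, children=(), externals=(),
                           ground=None):
    """Solve one segment's equations of motion for its proximal wrench.

    Parameters
    ----------
    spec : SegmentSpec
        Mass and inertia of the segment.
    kin : SegmentKinematics
        Per-frame orientation, CoM position/acceleration, angular rates.
    p_prox : (n,3)
        Global position of the proximal joint centre.
    children : iterable of (F, M, p)
        Wrenches this segment applies to its children, each applied at the
        child joint centre ``p`` (all (n,3)).
    externals : iterable of (F, M, p)
        External wrenches applied *to* this segment at point ``p``.
    ground : (F, M_ref, p_ref), optional
        Ground reaction on this segment: force ``F`` and moment ``M_ref``
        expressed about the reference point ``p_ref`` (all (n,3)).

    Returns
    -------
    F_prox, M_prox : (n,3), (n,3)
        Wrench the parent segment applies to this one at ``p_prox``.
    """
    m = spec.mass
    com = kin.com
    W = m * GRAVITY

    F = m * kin.acc - W
    M = spin_moment(spec, kin)

    for Fc, Mc, pc in children:
        F = F + Fc
        M = M + Mc + np.cross(pc - com, Fc)
    for Fe, Me, pe in externals:
        F = F - Fe
        M = M - Me - np.cross(pe - com, Fe)
    if ground is not None:
        Fg, Mg_ref, p_ref = ground
        F = F - Fg
        M = M - Mg_ref - np.cross(p_ref - com, Fg)

    M_prox = M - np.cross(p_prox - com, F)
    return F, M_prox
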