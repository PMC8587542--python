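"""End-to-end orchestration: streams in, reactions and joint loads out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .body_model import BodyModel, SubjectRecord, build_body_model
from .formats_io import MotionSequence, SensorSeries
from .grf import (ContactTimeline, GroundReaction, contact_from_states,
                  decompose_grf, hand_loads, total_grf, total_grm)
from .inverse_dynamics import (JointLoadSeries, peak_ratio, solve_dynamic,
                               solve_static)
from .kinematics import SegmentStateSeries, build_states, differentiate

__all__ = ["RunConfig", "RunResult", "run_pipeline", "export_reactions_csv",
           "export_joint_loads_csv", "export_bundle_hdf5"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Processing options for one trial."""

    cutoff: float | None = 10.0        #: low-pass cutoff, Hz (None: off)
    v_th: float = 1.2                  #: contact threshold speed, m/s
    v_th_mode: str = "fixed"           #: 'fixed' or 'pelvis_mean'
    gravity_included: bool = False     #: accelerometers report +g
    flavor: str = "both"               #: 'dynamic', 'static' or 'both'
    load_schedule: dict | None = None  #: {'mass','interval','split','ramp_frames'}
    seed: int = 0


@dataclass
class RunResult:
    states: SegmentStateSeries
    total_force: np.ndarray
    total_moment: np.ndarray
    contacts: ContactTimeline
    reactions: GroundReaction
    joint_loads: dict[str, JointLoadSeries] = field(default_factory=dict)
    peak_ratios: dict[str, float] = field(default_factory=dict)
    v_th_used: float = np.nan
    config: RunConfig | None = None


def run_pipeline(motion: MotionSequence, sensors: SensorSeries | None,
                 subject: SubjectRecord | BodyModel,
                 config: RunConfig | None = None) -> RunResult:
    """Run the full estimation chain on one trial.

    Stages: state assembly (filtering, CoM-acceleration transfer) ->
    whole-body totals -> contact detection -> double-stance decomposition
    -> joint-load recursion in the requested flavours.
    """
    cfg = config or RunConfig()
    model = subject if isinstance(subject, BodyModel) else build_body_model(subject)
    states = build_states(motion, sensors, model, cutoff=cfg.cutoff,
                          gravity_included=cfg.gravity_included)

    loads = []
    if cfg.load_schedule and cfg.load_schedule.get("mass", 0) > 0:
        s = cfg.load_schedule
        loads = hand_loads(states, s["mass"], tuple(s["interval"]),
                           tuple(s.get("split", (0.5, 0.5))),
                           ramp_frames=int(s.get("ramp_frames", 0)))

    F_g = total_grf(states, model, loads)
    M_g = total_grm(states, model, loads)

    v_th = cfg.v_th
    if cfg.v_th_mode == "pelvis_mean":
        pelvis_speed = np.linalg.norm(
            differentiate(states.root_position, states.frame_rate)[:, :2], axis=1)
        v_th = float(pelvis_speed.mean())
        log.info("per-trial threshold: mean pelvis speed %.3f m/s", v_th)
    contacts = contact_from_states(states, v_th=v_th, cutoff=cfg.cutoff)
    reactions = decompose_grf(F_g, M_g, contacts, states, model)

    result = RunResult(states=states, total_force=F_g, total_moment=M_g,
                       contacts=contacts, reactions=reactions,
                       v_th_used=v_th, config=cfg)
    if cfg.flavor in ("dynamic", "both"):
        result.joint_loads["dynamic"] = solve_dynamic(states, model, loads,
                                                      reactions)
    if cfg.flavor in ("static", "both"):
        result.joint_loads["static"] = solve_static(states, model, loads,
                                                    contacts=contacts)
    if cfg.flavor == "both":
        dyn, stat = result.joint_loads["dynamic"], result.joint_loads["static"]
        for joint in dyn.force:
            try:
                result.peak_ratios[joint] = peak_ratio(dyn, stat, joint)
            except ZeroDivisionError:
                result.peak_ratios[joint] = np.nan
    return result


# ---------------------------------------------------------------------------
# exports

def export_reactions_csv(result: RunResult, path) -> None:
    r = result.reactions
    n = r.force_total.shape[0]
    data = {"frame": np.arange(n), "time": np.arange(n) / r.frame_rate}
    for tag, arr in (("total_f", r.force_total), ("total_m", r.moment_total),
                     ("right_f", r.force["r"]), ("right_m", r.moment["r"]),
                     ("left_f", r.force["l"]), ("left_m", r.moment["l"])):
        for k, ax in enumerate("xyz"):
            data[f"{tag}{ax}"] = arr[:, k]
    data["contact_R"] = r.stance["r"].astype(int)
    data["contact_L"] = r.stance["l"].astype(int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def export_joint_loads_csv(series: dict[str, JointLoadSeries], path) -> None:
    rows = []
    for flavor, jls in series.items():
        n = jls.n_frames
        for joint in jls.force:
            df = pd.DataFrame(
                np.hstack([jls.force[joint], jls.moment[joint]]),
                columns=["fx", "fy", "fz", "mx", "my", "mz"])
            df.insert(0, "frame", np.arange(n))
            df.insert(1, "joint", joint)
            df.insert(2, "flavor", flavor)
            rows.append(df)
    pd.concat(rows).to_csv(path, index=False, float_format="%.10g")


def export_bundle_hdf5(result: RunResult, path) -> None:
    """Single-file HDF5 bundle of states, reactions and joint loads."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["frame_rate"] = result.states.frame_rate
        h5.attrs["v_th"] = result.v_th_used
        g = h5.create_group("reactions")
        g.create_dataset("force_total", data=result.reactions.force_total)
        g.create_dataset("moment_total", data=result.reactions.moment_total)
        for side in "rl":
            g.create_dataset(f"force_{side}", data=result.reactions.force[side])
            g.create_dataset(f"moment_{side}", data=result.reactions.moment[side])
            g.create_dataset(f"stance_{side}",
                             data=result.reactions.stance[side].astype("i1"))
        for flavor, jls in result.joint_loads.items():
            gj = h5.create_group(f"joint_loads/{flavor}")
            for joint in jls.force:
                gj.create_dataset(f"{joint}/force", data=jls.force[joint])
                gj.create_dataset(f"{joint}/moment", data=jls.moment[joint])
        gs = h5.create_group("states")
        for seg, kin in result.states.segments.items():
            gseg = gs.create_group(seg)
            gseg.create_dataset("com", data=kin.com)
            gseg.create_dataset("acc", data=kin.acc)
            gseg.create_dataset("omega", data=kin.omega)
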