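"""Readers and writers for the motion, sensor and force-plate formats.

All dialect decisions live here.  The internal global frame is Z-up,
X-anterior (see :mod:`wbid.constants`); BVH files are Y-up and are mapped
through a fixed axis permutation at ingest.  BVH positions default to
centimetres (common inertial-mocap export convention) and are scaled to
metres by a configurable unit factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from scipy.spatial.transform import Rotation

from .errors import (AlignmentError, BvhParseError, DataQualityError,
                     FormatError, MappingError, SchemaError)

__all__ = [
    "BvhNode", "Skeleton", "MotionSequence",
    "SensorRecord", "SensorSeries", "ForcePlateRecord",
    "read_bvh", "write_bvh",
    "read_sensor_table", "write_sensor_table",
    "read_forceplate", "write_forceplate", "resample_plates",
    "align_streams", "CANONICAL_NODE",
]

# internal -> BVH axis permutation: v_bvh = C @ v_int
# (internal X anterior, Y left, Z up;  BVH X left, Y up, Z anterior)
_C = np.array([[0.0, 1.0, 0.0],
               [0.0, 0.0, 1.0],
               [1.0, 0.0, 0.0]])

#: BVH joint-name aliases -> canonical node names of the 15-segment model.
CANONICAL_NODE = {
    "hips": "root", "hip": "root", "pelvis": "root", "root": "root",
    "spine": "l5s1", "chest": "l5s1", "spine1": "l5s1", "torso": "l5s1",
    "neck": "neck", "head": "neck",
    "rightarm": "shoulder_r", "rightshoulder": "shoulder_r",
    "rightforearm": "elbow_r", "rightelbow": "elbow_r",
    "righthand": "wrist_r", "rightwrist": "wrist_r",
    "leftarm": "shoulder_l", "leftshoulder": "shoulder_l",
    "leftforearm": "elbow_l", "leftelbow": "elbow_l",
    "lefthand": "wrist_l", "leftwrist": "wrist_l",
    "rightupleg": "hip_r", "righthip": "hip_r",
    "rightleg": "knee_r", "rightknee": "knee_r",
    "rightfoot": "ankle_r", "rightankle": "ankle_r",
    "leftupleg": "hip_l", "lefthip": "hip_l",
    "leftleg": "knee_l", "leftknee": "knee_l",
    "leftfoot": "ankle_l", "leftankle": "ankle_l",
}

#: end-site canonical names, keyed by the canonical name of the parent node.
_END_SITE_NAME = {
    "neck": "head_top",
    "wrist_r": "hand_tip_r", "wrist_l": "hand_tip_l",
    "ankle_r": "toe_r", "ankle_l": "toe_l",
}

_CHANNEL_AXIS = {"Xrotation": "X", "Yrotation": "Y", "Zrotation": "Z"}
_POS_CHANNELS = ("Xposition", "Yposition", "Zposition")


@dataclass
class BvhNode:
    """One joint (or end site) of a BVH hierarchy."""

    name: str                 #: canonical node name
    bvh_name: str             #: name as written in the file
    parent: int               #: index of parent node, -1 for root
    offset: np.ndarray        #: (3,) m, internal frame, relative to parent
    channels: tuple[str, ...] = ()
    is_end_site: bool = False


@dataclass
class Skeleton:
    nodes: list[BvhNode]

    def index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]


@dataclass
class MotionSequence:
    """A parsed motion trial: skeleton plus per-frame root pose and joint
    rotations (3x3 matrices, child relative to parent, internal frame)."""

    skeleton: Skeleton
    frame_rate: float
    root_position: np.ndarray            #: (n, 3) m, internal frame
    rotations: dict[str, np.ndarray]     #: node name -> (n, 3, 3)

    @property
    def n_frames(self) -> int:
        return self.root_position.shape[0]

    def validate(self, tol: float = 1e-6) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        eye = np.eye(3)
        for name, R in self.rotations.items():
            err = np.abs(np.swapaxes(R, -1, -2) @ R - eye).max()
            if err > tol:
                raise ValueError(f"non-orthonormal rotations for node {name!r} "
                                 f"(max |R^T R - I| = {err:.2e})")


@dataclass
class SensorRecord:
    """Global-frame series of one segment-mounted IMU."""

    position: np.ndarray          #: (n, 3) m
    acceleration: np.ndarray      #: (n, 3) m/s^2
    angular_velocity: np.ndarray  #: (n, 3) rad/s


@dataclass
class SensorSeries:
    frame_rate: float
    segments: dict[str, SensorRecord] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        rec = next(iter(self.segments.values()))
        return rec.position.shape[0]


@dataclass
class ForcePlateRecord:
    """Native-rate force-plate record, one entry per plate."""

    time: np.ndarray                           #: (m,) s
    plates: dict[str, dict[str, np.ndarray]]   #: id -> force/moment/origin

    @property
    def rate(self) -> float:
        dt = np.diff(self.time)
        return 1.0 / float(np.median(dt))


# ---------------------------------------------------------------------------
# BVH

def _euler_seq(channels: tuple[str, ...]) -> str:
    return "".join(_CHANNEL_AXIS[c] for c in channels if c in _CHANNEL_AXIS)


def read_bvh(path, unit: float = 0.01, strict_mapping: bool = True) -> MotionSequence:
    """Parse a BVH file into a :class:`MotionSequence`.

    Euler channels are converted to rotation matrices honouring the
    channel order declared per joint; positions are scaled to metres by
    ``unit`` and axes mapped from BVH Y-up to the internal Z-up frame.
    With ``strict_mapping`` every non-end-site joint must map onto the
    15-segment model, otherwise a :class:`MappingError` is raised.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    tokens: list[tuple[int, str]] = []
    for ln, line in enumerate(lines, start=1):
        for tok in line.replace("{", " { ").replace("}", " } ").split():
            tokens.append((ln, tok))

    pos = 0

    def peek():
        return tokens[pos][1] if pos < len(tokens) else None

    def take(expect: str | None = None) -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise BvhParseError("unexpected end of file")
        ln, tok = tokens[pos]
        pos += 1
        if expect is not None and tok.upper() != expect.upper():
            raise BvhParseError(f"line {ln}: expected {expect!r}, got {tok!r}")
        return tok

    def take_float() -> float:
        ln, tok = tokens[pos]
        try:
            return float(take())
        except ValueError:
            raise BvhParseError(f"line {ln}: expected a number, got {tok!r}") from None

    take("HIERARCHY")
    nodes: list[BvhNode] = []
    unmatched: list[str] = []

    def parse_joint(parent: int, is_root: bool):
        ln, kw = tokens[pos]
        kw_u = take().upper()
        if is_root and kw_u != "ROOT":
            raise BvhParseError(f"line {ln}: expected ROOT, got {kw!r}")
        if kw_u == "END":
            take("Site")
            bvh_name = "End Site"
            parent_cname = nodes[parent].name
            cname = _END_SITE_NAME.get(parent_cname, f"{parent_cname}_end")
            is_end = True
        else:
            if kw_u not in ("ROOT", "JOINT"):
                raise BvhParseError(f"line {ln}: expected JOINT/End Site, got {kw!r}")
            bvh_name = take()
            cname = CANONICAL_NODE.get(bvh_name.lower(), None)
            if cname is None:
                unmatched.append(bvh_name)
                cname = bvh_name
            is_end = False
        take("{")
        take("OFFSET")
        off_bvh = np.array([take_float(), take_float(), take_float()])
        offset = _C.T @ off_bvh * unit
        channels: tuple[str, ...] = ()
        if not is_end:
            ln_c, nxt = tokens[pos]
            if nxt.upper() == "CHANNELS":
                take()
                nchan = int(take_float())
                chans = []
                for _ in range(nchan):
                    ln_t, tok = tokens[pos]
                    c = take()
                    if c not in _POS_CHANNELS and c not in _CHANNEL_AXIS:
                        raise BvhParseError(f"line {ln_t}: unknown channel token {c!r}")
                    chans.append(c)
                channels = tuple(chans)
            elif not is_root:
                raise BvhParseError(f"line {ln_c}: joint {bvh_name!r} lacks CHANNELS")
        idx = len(nodes)
        nodes.append(BvhNode(name=cname, bvh_name=bvh_name, parent=parent,
                             offset=offset, channels=channels, is_end_site=is_end))
        while peek() != "}":
            if peek() is None:
                raise BvhParseError("unexpected end of file inside joint block")
            parse_joint(idx, is_root=False)
        take("}")

    parse_joint(-1, is_root=True)

    if strict_mapping and unmatched:
        raise MappingError("BVH joints not mappable to the 15-segment model: "
                           + ", ".join(sorted(unmatched)))

    take("MOTION")
    take("Frames:")
    n_frames = int(take_float())
    take("Frame")
    take("Time:")
    frame_time = take_float()
    if frame_time <= 0:
        raise BvhParseError("Frame Time must be positive")

    n_chan = sum(len(n.channels) for n in nodes)
    data = np.empty((n_frames, n_chan))
    for f in range(n_frames):
        for c in range(n_chan):
            data[f, c] = take_float()

    root_position = np.zeros((n_frames, 3))
    rotations: dict[str, np.ndarray] = {}
    col = 0
    for node in nodes:
        if not node.channels:
            continue
        base = col
        for i, c in enumerate(node.channels):
            if c in _POS_CHANNELS and node.parent == -1:
                axis = "XYZ".index(c[0])
                vec = np.zeros((n_frames, 3))
                vec[:, axis] = data[:, base + i]
                root_position += (vec * unit) @ _C  # v_int = C^T v_bvh
        rot_idx = [i for i, c in enumerate(node.channels) if c in _CHANNEL_AXIS]
        if rot_idx:
            angles = data[:, [base + i for i in rot_idx]]
            seq = _euler_seq(node.channels)
            R_bvh = Rotation.from_euler(seq, angles, degrees=True).as_matrix()
            rotations[node.name] = _C.T @ R_bvh @ _C
        col += len(node.channels)

    return MotionSequence(skeleton=Skeleton(nodes), frame_rate=1.0 / frame_time,
                          root_position=root_position, rotations=rotations)


def write_bvh(motion: MotionSequence, path, unit: float = 0.01) -> None:
    """Write a :class:`MotionSequence` as a Y-up BVH file.

    Rotation channels are written in the Perception-Neuron-style default
    order ``Zrotation Xrotation Yrotation``; positions are divided by
    ``unit`` (default: centimetres).  Angles are written with 17
    significant digits so that write-then-read round-trips to 1e-9.
    """
    nodes = motion.skeleton.nodes
    n_frames = motion.n_frames

    columns: list[np.ndarray] = []
    for node in nodes:
        if node.is_end_site:
            continue
        if node.parent == -1:
            pos_bvh = (_C @ motion.root_position.T).T / unit
            columns.append(pos_bvh)
        R = motion.rotations.get(node.name)
        if R is None:
            R = np.broadcast_to(np.eye(3), (n_frames, 3, 3))
        R_bvh = _C @ R @ _C.T
        ang = Rotation.from_matrix(R_bvh).as_euler("ZXY", degrees=True)
        columns.append(ang)
    frame_data = np.hstack(columns)

    out: list[str] = ["HIERARCHY"]

    def emit(idx: int, depth: int):
        node = nodes[idx]
        pad = "  " * depth
        off = _C @ node.offset / unit
        if node.is_end_site:
            out.append(f"{pad}End Site")
            out.append(f"{pad}{{")
            out.append(f"{pad}  OFFSET {off[0]:.17g} {off[1]:.17g} {off[2]:.17g}")
            out.append(f"{pad}}}")
            return
        kw = "ROOT" if node.parent == -1 else "JOINT"
        out.append(f"{pad}{kw} {node.bvh_name}")
        out.append(f"{pad}{{")
        out.append(f"{pad}  OFFSET {off[0]:.17g} {off[1]:.17g} {off[2]:.17g}")
        if node.parent == -1:
            out.append(f"{pad}  CHANNELS 6 Xposition Yposition Zposition "
                       "Zrotation Xrotation Yrotation")
        else:
            out.append(f"{pad}  CHANNELS 3 Zrotation Xrotation Yrotation")
        for j, other in enumerate(nodes):
            if other.parent == idx:
                emit(j, depth + 1)
        out.append(f"{pad}}}")

    emit(0, 0)
    out.append("MOTION")
    out.append(f"Frames: {n_frames}")
    out.append(f"Frame Time: {1.0 / motion.frame_rate:.17g}")
    for f in range(n_frames):
        out.append(" ".join(f"{v:.17g}" for v in frame_data[f]))
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# sensor ("CALC"-style) tables

_SENSOR_FIELDS = (("position", "p"), ("acceleration", "a"),
                  ("angular_velocity", "w"))


def write_sensor_table(series: SensorSeries, path) -> None:
    """Write per-segment IMU series as a wide CSV.

    Columns are ``frame, time`` then ``<segment>__{p,a,w}{x,y,z}`` for the
    sensor position (m), linear acceleration (m/s^2) and angular velocity
    (rad/s), all in the global frame.
    """
    n = series.n_frames
    data = {"frame": np.arange(n),
            "time": np.arange(n) / series.frame_rate}
    for seg, rec in series.segments.items():
        for attr, tag in _SENSOR_FIELDS:
            arr = getattr(rec, attr)
            for k, ax in enumerate("xyz"):
                data[f"{seg}__{tag}{ax}"] = arr[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_sensor_table(path, frame_rate: float | None = None,
                      max_gap: float = 0.1) -> SensorSeries:
    """Read a sensor CSV written by :func:`write_sensor_table`.

    NaN runs no longer than ``max_gap`` seconds are linearly interpolated;
    longer dropouts raise :class:`DataQualityError`.
    """
    df = pd.read_csv(path)
    for col in ("frame", "time"):
        if col not in df.columns:
            raise SchemaError(f"sensor table missing required column {col!r}")
    if frame_rate is None:
        dt = np.diff(df["time"].to_numpy())
        if len(dt) == 0 or np.median(dt) <= 0:
            raise SchemaError("cannot infer frame rate from 'time' column")
        frame_rate = 1.0 / float(np.median(dt))

    seg_names = sorted({c.split("__")[0] for c in df.columns if "__" in c})
    if not seg_names:
        raise SchemaError("sensor table has no '<segment>__<field>' columns")

    max_gap_frames = int(round(max_gap * frame_rate))
    segments: dict[str, SensorRecord] = {}
    for seg in seg_names:
        arrays = {}
        for attr, tag in _SENSOR_FIELDS:
            cols = [f"{seg}__{tag}{ax}" for ax in "xyz"]
            for c in cols:
                if c not in df.columns:
                    raise SchemaError(f"sensor table missing column {c!r}")
            arr = df[cols].to_numpy(dtype=float)
            arrays[attr] = _fill_gaps(arr, max_gap_frames, seg)
        segments[seg] = SensorRecord(**arrays)
    return SensorSeries(frame_rate=frame_rate, segments=segments)


def _fill_gaps(arr: np.ndarray, max_gap_frames: int, seg: str) -> np.ndarray:
    out = arr.copy()
    n = len(out)
    for k in range(out.shape[1]):
        col = out[:, k]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        # locate NaN runs
        idx = np.flatnonzero(isnan)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            if len(run) > max_gap_frames:
                raise DataQualityError(
                    f"segment {seg!r}: dropout of {len(run)} frames exceeds "
                    f"the {max_gap_frames}-frame gap tolerance")
            if run[0] == 0 or run[-1] == n - 1:
                raise DataQualityError(
                    f"segment {seg!r}: dropout touches the series boundary")
        good = ~isnan
        col[isnan] = np.interp(np.flatnonzero(isnan), np.flatnonzero(good),
                               col[good])
    return out


# ---------------------------------------------------------------------------
# force plates

def write_forceplate(record: ForcePlateRecord, path) -> None:
    """Write a force-plate record as a long CSV (one block per plate)."""
    frames = []
    for pid, plate in record.plates.items():
        df = pd.DataFrame({
            "plate": pid, "time": record.time,
            "fx": plate["force"][:, 0], "fy": plate["force"][:, 1],
            "fz": plate["force"][:, 2],
            "mx": plate["moment"][:, 0], "my": plate["moment"][:, 1],
            "mz": plate["moment"][:, 2],
            "ox": plate["origin"][0], "oy": plate["origin"][1],
            "oz": plate["origin"][2],
        })
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_forceplate(path, expected_plates: tuple[str, ...] | None = None
                    ) -> ForcePlateRecord:
    """Read a force-plate CSV (columns plate,time,fx..fz,mx..mz,ox..oz)."""
    df = pd.read_csv(path)
    required = {"plate", "time", "fx", "fy", "fz", "mx", "my", "mz"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"force-plate table missing columns {sorted(missing)}")
    if not np.isfinite(df[["fx", "fy", "fz", "mx", "my", "mz"]].to_numpy()).all():
        raise FormatError("force-plate record contains non-finite values")

    plates: dict[str, dict[str, np.ndarray]] = {}
    time_ref = None
    for pid, block in df.groupby("plate", sort=False):
        t = block["time"].to_numpy(dtype=float)
        if len(t) == 0:
            raise FormatError(f"plate {pid!r}: empty block")
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"plate {pid!r}: time vector not strictly increasing")
        origin = np.zeros(3)
        if {"ox", "oy", "oz"} <= set(df.columns):
            origin = block[["ox", "oy", "oz"]].to_numpy(dtype=float)[0]
        plates[str(pid)] = {
            "force": block[["fx", "fy", "fz"]].to_numpy(dtype=float),
            "moment": block[["mx", "my", "mz"]].to_numpy(dtype=float),
            "origin": origin,
        }
        time_ref = t
    if expected_plates is not None:
        for pid in expected_plates:
            if str(pid) not in plates:
                raise FormatError(f"plate {pid!r}: empty block")
    return ForcePlateRecord(time=time_ref, plates=plates)


def resample_plates(record: ForcePlateRecord, target_rate: float,
                    lowpass=None) -> ForcePlateRecord:
    """Resample a native-rate plate record to the motion rate.

    Optionally low-pass filter first (callable applied per channel), then
    polyphase-resample each channel.
    """
    native = record.rate
    frac = Fraction(target_rate / native).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    plates = {}
    for pid, plate in record.plates.items():
        force = plate["force"]
        moment = plate["moment"]
        if lowpass is not None:
            force = lowpass(force)
            moment = lowpass(moment)
        plates[pid] = {
            "force": resample_poly(force, up, down, axis=0),
            "moment": resample_poly(moment, up, down, axis=0),
            "origin": plate["origin"],
        }
    n = next(iter(plates.values()))["force"].shape[0]
    time = record.time[0] + np.arange(n) / target_rate
    return ForcePlateRecord(time=time, plates=plates)


# ---------------------------------------------------------------------------
# stream alignment

def align_streams(reference: np.ndarray, other: np.ndarray,
                  max_lag: int | None = None, threshold: float = 0.5) -> int:
    """Integer lag (frames) aligning ``other`` to ``reference``.

    Both inputs are 1-D series of a shared landmark trajectory (typically
    the vertical coordinate of a pelvis marker) at the same rate.  Returns
    the lag maximizing the normalized cross-correlation; a peak below
    ``threshold`` raises :class:`AlignmentError`.  Positive lag means
    ``other`` starts ``lag`` frames later than ``reference``.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(other, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        raise AlignmentError("landmark series has zero variance")
    corr = np.correlate(a, b, mode="full") / denom
    # index k corresponds to displacing `other` by (len(b)-1-k) frames
    lags = -np.arange(-(len(b) - 1), len(a))
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        corr, lags = corr[keep], lags[keep]
    best = int(np.argmax(corr))
    if corr[best] < threshold:
        raise AlignmentError(
            f"cross-correlation peak {corr[best]:.3f} below threshold {threshold}")
    return int(lags[best])
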