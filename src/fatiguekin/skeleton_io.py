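"""Skeleton and Borg CR10 file I/O.

Skeleton recordings are flat CSV files, one row per frame: a ``t_s`` column
(seconds from trial start) followed by ``<JOINT>_x, <JOINT>_y, <JOINT>_z``
columns in millimeters for each of the 32 joints of the Azure Kinect Body
Tracking hierarchy, in SDK order. Missing (dropped-out) joints appear as
empty cells; optional ``<JOINT>_valid`` columns (0/1) may state validity
explicitly. A single leading comment line carries metadata, e.g.::

    # units=mm fps=30.0 subject=S03

CR10 logs are two-column CSVs (``t_s, cr10``) with one integer rating in
[0, 10] per row.

Internally the axis convention is x rightward, y upward, z from the camera
toward the subject; device recordings with different axes are brought into
this frame at ingest via an explicit ``axis_map`` (never guessed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: The 32 joints of the Azure Kinect Body Tracking SDK, in SDK index order.
JOINT_NAMES: tuple[str, ...] = (
    "PELVIS", "SPINE_NAVEL", "SPINE_CHEST", "NECK",
    "CLAVICLE_LEFT", "SHOULDER_LEFT", "ELBOW_LEFT", "WRIST_LEFT",
    "HAND_LEFT", "HANDTIP_LEFT", "THUMB_LEFT",
    "CLAVICLE_RIGHT", "SHOULDER_RIGHT", "ELBOW_RIGHT", "WRIST_RIGHT",
    "HAND_RIGHT", "HANDTIP_RIGHT", "THUMB_RIGHT",
    "HIP_LEFT", "KNEE_LEFT", "ANKLE_LEFT", "FOOT_LEFT",
    "HIP_RIGHT", "KNEE_RIGHT", "ANKLE_RIGHT", "FOOT_RIGHT",
    "HEAD", "NOSE", "EYE_LEFT", "EAR_LEFT", "EYE_RIGHT", "EAR_RIGHT",
)

N_JOINTS = len(JOINT_NAMES)
JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(JOINT_NAMES)}

#: Joints that define the four limb abduction angles.
LIMB_DEFINING_JOINTS = (
    "SHOULDER_LEFT", "ELBOW_LEFT", "SHOULDER_RIGHT", "ELBOW_RIGHT",
    "HIP_LEFT", "KNEE_LEFT", "HIP_RIGHT", "KNEE_RIGHT",
)


class SchemaError(ValueError):
    """Input file does not match the 32-joint skeleton schema."""


class FormatError(ValueError):
    """Input file is schema-conformant but internally inconsistent."""


@dataclass
class SkeletonSequence:
    """A timestamped 32-joint 3D position stream for one subject.

    positions has shape (n_frames, 32, 3); invalid (dropped-out) samples are
    NaN and flagged False in ``valid``. Units are "mm" on ingest and "m"
    after :func:`to_meters`.
    """

    subject_id: str
    timestamps: np.ndarray          # (n,) seconds, strictly increasing
    positions: np.ndarray           # (n, 32, 3)
    valid: np.ndarray               # (n, 32) bool
    fps: float
    units: str = "mm"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.timestamps)
        if self.positions.shape != (n, N_JOINTS, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} != ({n}, {N_JOINTS}, 3)"
            )
        if self.valid.shape != (n, N_JOINTS):
            raise ValueError("valid flag shape mismatch")
        if n > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
        if self.units not in ("mm", "m"):
            raise ValueError(f"unknown units {self.units!r}")

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def joint(self, name: str) -> np.ndarray:
        """(n, 3) positions of one joint by SDK name."""
        return self.positions[:, JOINT_INDEX[name], :]

    def joint_valid(self, name: str) -> np.ndarray:
        return self.valid[:, JOINT_INDEX[name]]


@dataclass
class CR10Log:
    """Ordered Borg CR10 ratings, one per 30-s protocol mark."""

    times: np.ndarray               # (k,) seconds, strictly increasing
    ratings: np.ndarray             # (k,) int in [0, 10]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=int)
        if self.times.shape != self.ratings.shape:
            raise ValueError("times/ratings length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise FormatError("CR10 timestamps must be strictly increasing")
        if len(self.ratings) and (
            self.ratings.min() < 0 or self.ratings.max() > 10
        ):
            raise ValueError("CR10 ratings must lie in [0, 10]")

    def __len__(self) -> int:
        return len(self.times)


_AXIS_RE = re.compile(r"^(-?)([xyz])$")


def _axis_transform(axis_map: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    """Permutation/sign arrays mapping source columns to internal axes."""
    perm = np.zeros(3, dtype=int)
    sign = np.zeros(3)
    for i, ax in enumerate("xyz"):
        m = _AXIS_RE.match(axis_map.get(ax, ax).strip())
        if not m:
            raise ValueError(f"bad axis_map entry for {ax!r}: {axis_map.get(ax)!r}")
        sign[i] = -1.0 if m.group(1) else 1.0
        perm[i] = "xyz".index(m.group(2))
    if sorted(perm.tolist()) != [0, 1, 2]:
        raise ValueError("axis_map must be a signed permutation of x, y, z")
    return perm, sign


def read_skeleton_csv(
    path: str | Path,
    axis_map: dict[str, str] | None = None,
) -> SkeletonSequence:
    """Read one subject's skeleton CSV into an mm-unit :class:`SkeletonSequence`.

    Empty or non-finite coordinate cells mark the joint invalid at that
    frame; explicit ``<JOINT>_valid`` columns take precedence. ``axis_map``
    maps internal axes to (possibly negated) source axes, e.g.
    ``{"y": "-z", "z": "y"}``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first.lstrip("#").split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    df = pd.read_csv(path, comment="#")

    if "t_s" not in df.columns:
        raise SchemaError("missing timestamp column 't_s'")
    expected = {f"{j}_{ax}" for j in JOINT_NAMES for ax in "xyz"}
    present = set(df.columns) - {"t_s"}
    coord_cols = {c for c in present if not c.endswith("_valid")}
    missing = sorted(expected - coord_cols)
    if missing:
        raise SchemaError(f"missing joint columns: {missing[:3]}"
                          + ("..." if len(missing) > 3 else ""))
    unknown = sorted(coord_cols - expected)
    if unknown:
        raise SchemaError(f"unknown columns: {unknown[:3]}"
                          + ("..." if len(unknown) > 3 else ""))

    t = df["t_s"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise FormatError(f"{path.name}: non-monotone timestamps")

    n = len(df)
    pos = np.empty((n, N_JOINTS, 3))
    for j, name in enumerate(JOINT_NAMES):
        for a, ax in enumerate("xyz"):
            pos[:, j, a] = df[f"{name}_{ax}"].to_numpy(dtype=float)
    valid = np.all(np.isfinite(pos), axis=2)
    for j, name in enumerate(JOINT_NAMES):
        col = f"{name}_valid"
        if col in df.columns:
            valid[:, j] &= df[col].to_numpy(dtype=float) > 0.5
    pos[~valid] = np.nan

    if axis_map:
        perm, sign = _axis_transform(axis_map)
        pos = pos[:, :, perm] * sign

    fps = float(meta.get("fps", 0)) or _infer_fps(t)
    _check_frame_interval(t, fps, path.name)
    return SkeletonSequence(
        subject_id=meta.get("subject", path.stem),
        timestamps=t,
        positions=pos,
        valid=valid,
        fps=fps,
        units=meta.get("units", "mm"),
    )


def _infer_fps(t: np.ndarray) -> float:
    if len(t) < 2:
        return 30.0
    return 1.0 / float(np.median(np.diff(t)))


def _check_frame_interval(t: np.ndarray, fps: float, name: str) -> None:
    """Nominal frame interval must be held within 10% throughout."""
    if len(t) < 2:
        return
    dt = np.diff(t)
    nominal = 1.0 / fps
    if np.any(np.abs(dt - nominal) > 0.1 * nominal):
        raise FormatError(f"{name}: frame interval deviates >10% from 1/fps")


def write_skeleton_csv(seq: SkeletonSequence, path: str | Path) -> None:
    """Write the flat CSV dialect; invalid samples become empty cells.

    Coordinates are formatted to 6 significant digits, the documented
    round-trip precision.
    """
    path = Path(path)
    cols: dict[str, np.ndarray] = {"t_s": seq.timestamps}
    for j, name in enumerate(JOINT_NAMES):
        for a, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = seq.positions[:, j, a]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# units={seq.units} fps={seq.fps:g} subject={seq.subject_id}\n")
        df.to_csv(fh, index=False, float_format="%.6g", na_rep="")


def to_meters(seq: SkeletonSequence) -> SkeletonSequence:
    """Convert a millimeter sequence to meters (divide by 1000).

    Raises ``ValueError`` if the sequence is already in meters, so the
    conversion cannot silently be applied twice.
    """
    if seq.units == "m":
        raise ValueError("sequence already in meters; refusing to rescale")
    return replace(seq, positions=seq.positions / 1000.0, units="m")


def read_cr10_log(path: str | Path) -> CR10Log:
    """Read a CR10 CSV (columns ``t_s, cr10``); ratings validated to [0, 10]."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        import warnings

        warnings.warn(f"{Path(path).name}: empty CR10 log", stacklevel=2)
        return CR10Log(times=np.array([]), ratings=np.array([], dtype=int))
    if not {"t_s", "cr10"} <= set(df.columns):
        raise SchemaError("CR10 log must have columns t_s, cr10")
    ratings = df["cr10"].to_numpy()
    if np.any((ratings < 0) | (ratings > 10)):
        bad = ratings[(ratings < 0) | (ratings > 10)][0]
        raise ValueError(f"CR10 rating {bad} outside [0, 10]")
    return CR10Log(times=df["t_s"].to_numpy(dtype=float),
                   ratings=ratings.astype(int))


def write_cr10_log(log: CR10Log, path: str | Path) -> None:
    pd.DataFrame({"t_s": log.times, "cr10": log.ratings}).to_csv(
        path, index=False
    )
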