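"""Per-limb abduction angles and angular velocities.

The abduction angle theta is measured between the proximal-to-distal limb
vector (shoulder->elbow for arms, hip->knee for legs), projected onto the
frontal plane, and the downward vertical: theta = 0 with the limb hanging
straight down, pi/2 horizontal. The construction uses only the vector's
direction, so it is invariant to limb length, global translation and
uniform scaling, and taking |x| makes left and right mirror-symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import JOINT_INDEX, SkeletonSequence

LIMB_IDS = ("left_arm", "right_arm", "left_leg", "right_leg")


class DegenerateGeometryError(ValueError):
    """Limb vector has (near-)zero planar length at some frame."""


@dataclass(frozen=True)
class LimbDef:
    limb_id: str
    proximal_joint: str
    distal_joint: str

    def __post_init__(self) -> None:
        for j in (self.proximal_joint, self.distal_joint):
            if j not in JOINT_INDEX:
                raise ValueError(f"unknown joint {j!r}")
        if self.proximal_joint == self.distal_joint:
            raise ValueError("proximal and distal joints must differ")


#: Default limb definitions matching the feature table's named joints.
DEFAULT_LIMBS: dict[str, LimbDef] = {
    "left_arm": LimbDef("left_arm", "SHOULDER_LEFT", "ELBOW_LEFT"),
    "right_arm": LimbDef("right_arm", "SHOULDER_RIGHT", "ELBOW_RIGHT"),
    "left_leg": LimbDef("left_leg", "HIP_LEFT", "KNEE_LEFT"),
    "right_leg": LimbDef("right_leg", "HIP_RIGHT", "KNEE_RIGHT"),
}


@dataclass
class AngleSeries:
    limb_id: str
    timestamps: np.ndarray
    theta: np.ndarray           # radians, in [0, pi]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.timestamps.shape != self.theta.shape:
            raise ValueError("timestamps/theta length mismatch")


@dataclass
class AngularVelocitySeries:
    limb_id: str
    timestamps: np.ndarray
    omega: np.ndarray           # rad/s


def limb_abduction_angle(
    seq: SkeletonSequence,
    limb: LimbDef,
    angle_mode: str = "frontal",
    min_length: float = 1e-6,
) -> AngleSeries:
    """Abduction angle of one limb at every frame of a meter-unit sequence.

    ``angle_mode="frontal"`` (default) drops the depth axis before
    measuring; ``"3d"`` uses the full 3D vector against the vertical.
    Dropouts in the two limb joints must be interpolated beforehand.
    """
    if seq.units != "m":
        raise ValueError("sequence must be in meters (call to_meters first)")
    v = seq.joint(limb.distal_joint) - seq.joint(limb.proximal_joint)
    if angle_mode == "frontal":
        lateral = np.abs(v[:, 0])
    elif angle_mode == "3d":
        lateral = np.hypot(v[:, 0], v[:, 2])
    else:
        raise ValueError(f"unknown angle_mode {angle_mode!r}")
    down = -v[:, 1]
    norm = np.hypot(lateral, down)
    finite = np.isfinite(norm)
    bad = np.flatnonzero(finite & ~(norm > min_length))
    if bad.size:
        raise DegenerateGeometryError(
            f"{limb.limb_id}: zero-length limb vector at frame {bad[0]}"
        )
    # Frames with un-interpolated dropouts propagate as NaN for the caller
    # to gap-fill or discard.
    theta = np.where(finite, np.arctan2(lateral, down), np.nan)
    return AngleSeries(limb_id=limb.limb_id, timestamps=seq.timestamps,
                       theta=theta)


def angular_velocity(angles: AngleSeries, fps: float) -> AngularVelocitySeries:
    """omega = d(theta)/dt by central differences; one-sided at the edges."""
    theta = angles.theta
    if len(theta) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    omega = np.empty_like(theta)
    omega[1:-1] = (theta[2:] - theta[:-2]) * fps / 2.0
    omega[0] = (theta[1] - theta[0]) * fps
    omega[-1] = (theta[-1] - theta[-2]) * fps
    return AngularVelocitySeries(
        limb_id=angles.limb_id, timestamps=angles.timestamps, omega=omega
    )
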