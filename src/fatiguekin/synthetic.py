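"""Synthetic cohort generator for cyclic whole-body abduction trials.

Emulates the study conditions the pipeline assumes: each subject alternates
between a neutral stance (limbs hanging, "close") and a spread posture
(arms and legs abducted, "open") for up to 180 s in front of a frontal
depth camera, while a latent fatigue level F(t) rises and is verbally
reported on the Borg CR10 scale every 30 s.

The movement model is deliberately simple and fully analytic so that it can
double as a test oracle:

* latent fatigue        F(t) = min(1, r * t / 180)
* instantaneous period  T(t) = T0 * (1 + beta_T * F(t))        (slowing)
* instantaneous amplitude A(t) = A0 * (1 - beta_A * F(t))      (shrinking)
* limb abduction angle  theta(t) = A(t) * (1 - cos phi(t)) / 2,
  with the phase phi advancing at rate 2*pi/T(t),

so theta oscillates between 0 ("close") and A(t) ("open"), with cycles
lengthening and flattening as fatigue accumulates — the drift the cycle-
timing and velocity features are designed to pick up. Joint positions come
from planar forward kinematics in the frontal (x-y) plane on a static
pelvis-rooted skeleton; the remaining joints of the 32-joint set are static
apart from sensor noise. CR10 reports are clip(round(10*F) + jitter, 0, 10).

Coordinates are emitted in millimeters (x rightward, y upward, z from the
camera toward the subject, pelvis at the origin), matching what a body-
tracking ingest would provide.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .skeleton_io import (
    CR10Log,
    JOINT_INDEX,
    JOINT_NAMES,
    N_JOINTS,
    SkeletonSequence,
    write_cr10_log,
    write_skeleton_csv,
)

FATIGUE_HORIZON_S = 180.0   # F(t) ramps over the nominal 3-min trial
CR10_CADENCE_S = 30.0


@dataclass(frozen=True)
class MotionParams:
    """Per-subject movement and fatigue-drift parameters.

    base_period
        T0, seconds for one full open-close cycle at zero fatigue.
    arm_amplitude, leg_amplitude
        A0 per limb pair, radians of maximum abduction from vertical.
    period_growth
        beta_T >= 0; fractional period increase at full fatigue.
    amplitude_decay
        beta_A in [0, 1); fractional amplitude loss at full fatigue.
    fatigue_rate
        r > 0; latent fatigue F(t) = min(1, r*t/180).
    limb_lengths
        meters: (upper_arm, forearm, thigh, shank).
    phase_offsets
        radians per limb, order (left_arm, right_arm, left_leg, right_leg).
    """

    base_period: float = 2.2
    arm_amplitude: float = 1.25
    leg_amplitude: float = 0.45
    period_growth: float = 0.35
    amplitude_decay: float = 0.22
    fatigue_rate: float = 1.05
    limb_lengths: tuple[float, float, float, float] = (0.30, 0.26, 0.42, 0.40)
    phase_offsets: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.base_period <= 0:
            raise ValueError("base_period must be > 0")
        for a in (self.arm_amplitude, self.leg_amplitude):
            if not 0 < a < np.pi / 2:
                raise ValueError("amplitudes must lie in (0, pi/2)")
        if self.period_growth < 0:
            raise ValueError("period_growth must be >= 0")
        if not 0 <= self.amplitude_decay < 1:
            raise ValueError("amplitude_decay must lie in [0, 1)")
        if self.fatigue_rate <= 0:
            raise ValueError("fatigue_rate must be > 0")


@dataclass(frozen=True)
class NoiseParams:
    """Sensor-noise model: isotropic jitter, dropouts, CR10 report jitter."""

    position_noise_sd: float = 3.0      # mm, per joint per frame
    dropout_prob: float = 0.01          # per joint per frame, run start
    dropout_max_run: int = 5            # frames
    cr10_jitter_prob: float = 0.1       # chance of a +/-1 report error

    def __post_init__(self) -> None:
        if self.position_noise_sd < 0:
            raise ValueError("position_noise_sd must be >= 0")
        for p in (self.dropout_prob, self.cr10_jitter_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dropout_max_run < 0:
            raise ValueError("dropout_max_run must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseParams":
        return cls(position_noise_sd=0.0, dropout_prob=0.0,
                   cr10_jitter_prob=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings; per-subject parameters are drawn
    uniformly from the stated (low, high) ranges using the cohort seed."""

    n_subjects: int = 10
    duration: float = 180.0
    fps: float = 30.0
    seed: int = 42
    base_period_range: tuple[float, float] = (1.9, 2.5)
    arm_amplitude_range: tuple[float, float] = (1.15, 1.4)
    leg_amplitude_range: tuple[float, float] = (0.38, 0.52)
    period_growth_range: tuple[float, float] = (0.45, 0.65)
    amplitude_decay_range: tuple[float, float] = (0.30, 0.45)
    fatigue_rate_range: tuple[float, float] = (1.0, 1.5)
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2 (LOSO needs >= 2)")
        if self.duration < 60:
            raise ValueError("duration must be >= 60 s (>= 2 CR10 reports)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Closed-form instantaneous kinematic truth at one time point."""

    period: float               # T(t), s
    arm_amplitude: float        # A_arm(t), rad
    leg_amplitude: float        # A_leg(t), rad
    peak_arm_velocity: float    # A_arm(t)*pi/T(t), rad/s
    peak_leg_velocity: float


@dataclass
class SubjectRecording:
    subject_id: str
    sequence: SkeletonSequence
    cr10: CR10Log
    params: MotionParams
    noise: NoiseParams


@dataclass
class Cohort:
    config: CohortConfig
    subjects: list[SubjectRecording]


# Limb kinematic chains: (root joint, chain joints, lateral sign, kind).
# Internal x is rightward in the camera image; the subject's left side sits
# at negative x. Lateral sign is the abduction direction away from midline.
_LIMBS = (
    ("left_arm", "SHOULDER_LEFT", ("ELBOW_LEFT", "WRIST_LEFT"), -1.0, "arm"),
    ("right_arm", "SHOULDER_RIGHT", ("ELBOW_RIGHT", "WRIST_RIGHT"), +1.0, "arm"),
    ("left_leg", "HIP_LEFT", ("KNEE_LEFT", "ANKLE_LEFT"), -1.0, "leg"),
    ("right_leg", "HIP_RIGHT", ("KNEE_RIGHT", "ANKLE_RIGHT"), +1.0, "leg"),
)

# Static landmarks (meters, pelvis at origin) for the torso/head/extremity
# joints that the abduction task leaves essentially stationary.
_STATIC_POSE: dict[str, tuple[float, float, float]] = {
    "PELVIS": (0.0, 0.0, 0.0),
    "SPINE_NAVEL": (0.0, 0.16, 0.0),
    "SPINE_CHEST": (0.0, 0.34, 0.0),
    "NECK": (0.0, 0.52, 0.0),
    "CLAVICLE_LEFT": (-0.08, 0.50, 0.0),
    "CLAVICLE_RIGHT": (0.08, 0.50, 0.0),
    "SHOULDER_LEFT": (-0.20, 0.48, 0.0),
    "SHOULDER_RIGHT": (0.20, 0.48, 0.0),
    "HIP_LEFT": (-0.10, -0.02, 0.0),
    "HIP_RIGHT": (0.10, -0.02, 0.0),
    "HEAD": (0.0, 0.62, 0.0),
    "NOSE": (0.0, 0.64, 0.06),
    "EYE_LEFT": (-0.03, 0.66, 0.05),
    "EYE_RIGHT": (0.03, 0.66, 0.05),
    "EAR_LEFT": (-0.07, 0.64, 0.0),
    "EAR_RIGHT": (0.07, 0.64, 0.0),
}


def fatigue_level(t, fatigue_rate: float):
    """Latent fatigue F(t) = min(1, r*t/180), elementwise."""
    return np.minimum(1.0, fatigue_rate * np.asarray(t, dtype=float)
                      / FATIGUE_HORIZON_S)


def analytic_truth(params: MotionParams, t: float,
                   duration: float = FATIGUE_HORIZON_S) -> TruthRecord:
    """Closed-form T(t), A(t) and peak opening velocity A(t)*pi/T(t)."""
    if not 0 <= t <= duration:
        raise ValueError(f"t={t} outside [0, {duration}]")
    f = float(fatigue_level(t, params.fatigue_rate))
    period = params.base_period * (1 + params.period_growth * f)
    a_arm = params.arm_amplitude * (1 - params.amplitude_decay * f)
    a_leg = params.leg_amplitude * (1 - params.amplitude_decay * f)
    return TruthRecord(
        period=period,
        arm_amplitude=a_arm,
        leg_amplitude=a_leg,
        peak_arm_velocity=a_arm * np.pi / period,
        peak_leg_velocity=a_leg * np.pi / period,
    )


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x) + 0.5).astype(int)


def simulate_subject(
    params: MotionParams,
    noise: NoiseParams,
    duration: float = 180.0,
    fps: float = 30.0,
    seed: int = 0,
    subject_id: str = "S00",
) -> tuple[SkeletonSequence, CR10Log]:
    """Simulate one subject's skeleton stream (mm) and CR10 report log.

    Deterministic given ``seed``; identical calls give identical arrays.
    """
    if duration <= 0 or fps <= 0:
        raise ValueError("duration and fps must be > 0")
    rng = np.random.default_rng(seed)

    n = int(round(duration * fps))
    t = np.arange(n) / fps
    f = fatigue_level(t, params.fatigue_rate)
    period = params.base_period * (1 + params.period_growth * f)

    # Phase advances at the instantaneous rate 2*pi/T(t).
    dphi = 2 * np.pi / (period * fps)
    phase_base = np.concatenate(([0.0], np.cumsum(dphi[:-1])))

    amp = {
        "arm": params.arm_amplitude * (1 - params.amplitude_decay * f),
        "leg": params.leg_amplitude * (1 - params.amplitude_decay * f),
    }

    pos = np.empty((n, N_JOINTS, 3))
    for name, xyz in _STATIC_POSE.items():
        pos[:, JOINT_INDEX[name], :] = xyz
    # Distal static joints default to their parent chain tip; filled below.

    seg = params.limb_lengths
    seg_by_kind = {"arm": (seg[0], seg[1]), "leg": (seg[2], seg[3])}
    for (limb_id, root, chain, lateral, kind), offset in zip(
        _LIMBS, params.phase_offsets
    ):
        theta = amp[kind] * (1 - np.cos(phase_base + offset)) / 2
        direction = np.stack(
            [lateral * np.sin(theta), -np.cos(theta), np.zeros(n)], axis=1
        )
        p = np.array(_STATIC_POSE[root])[None, :].repeat(n, axis=0)
        for joint, length in zip(chain, seg_by_kind[kind]):
            p = p + length * direction
            pos[:, JOINT_INDEX[joint], :] = p
        # Hands/feet ride on the chain tip with a small fixed offset.
        if kind == "arm":
            side = "LEFT" if lateral < 0 else "RIGHT"
            for extra, ext_len in (("HAND", 0.08), ("HANDTIP", 0.15),
                                   ("THUMB", 0.10)):
                pos[:, JOINT_INDEX[f"{extra}_{side}"], :] = (
                    p + ext_len * direction
                )
        else:
            side = "LEFT" if lateral < 0 else "RIGHT"
            pos[:, JOINT_INDEX[f"FOOT_{side}"], :] = p + np.array(
                [0.0, -0.05, 0.12]
            )

    pos_mm = pos * 1000.0
    if noise.position_noise_sd > 0:
        pos_mm = pos_mm + rng.normal(
            0.0, noise.position_noise_sd, size=pos_mm.shape
        )

    valid = np.ones((n, N_JOINTS), dtype=bool)
    if noise.dropout_prob > 0 and noise.dropout_max_run > 0:
        starts = rng.random((n, N_JOINTS)) < noise.dropout_prob
        runs = rng.integers(1, noise.dropout_max_run + 1, size=(n, N_JOINTS))
        for i, j in zip(*np.nonzero(starts)):
            valid[i : i + runs[i, j], j] = False
    pos_mm[~valid] = np.nan

    report_times = np.arange(CR10_CADENCE_S, duration + 1e-9, CR10_CADENCE_S)
    ratings = _round_half_up(10 * fatigue_level(report_times,
                                                params.fatigue_rate))
    if noise.cr10_jitter_prob > 0:
        jitter_mask = rng.random(len(ratings)) < noise.cr10_jitter_prob
        jitter = rng.choice([-1, 1], size=len(ratings))
        ratings = ratings + jitter_mask * jitter
    ratings = np.clip(ratings, 0, 10)

    seq = SkeletonSequence(
        subject_id=subject_id,
        timestamps=t,
        positions=pos_mm,
        valid=valid,
        fps=fps,
        units="mm",
    )
    return seq, CR10Log(times=report_times, ratings=ratings)


def _draw_params(rng: np.random.Generator, cfg: CohortConfig) -> MotionParams:
    u = lambda lo_hi: float(rng.uniform(*lo_hi))  # noqa: E731
    return MotionParams(
        base_period=u(cfg.base_period_range),
        arm_amplitude=u(cfg.arm_amplitude_range),
        leg_amplitude=u(cfg.leg_amplitude_range),
        period_growth=u(cfg.period_growth_range),
        amplitude_decay=u(cfg.amplitude_decay_range),
        fatigue_rate=u(cfg.fatigue_rate_range),
        phase_offsets=tuple(rng.uniform(-0.3, 0.3, size=4)),
    )


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``n_subjects`` independent recordings, deterministic in seed.

    Each subject's randomness comes from a stream derived from
    (cohort seed, subject index), so cohorts are reproducible regardless of
    generation order.
    """
    subjects = []
    for i in range(config.n_subjects):
        ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        draw_rng = np.random.default_rng(ss)
        params = _draw_params(draw_rng, config)
        subj_seed = int(ss.generate_state(1)[0] % (2**31))
        sid = f"S{i + 1:02d}"
        seq, log = simulate_subject(
            params, config.noise, config.duration, config.fps,
            seed=subj_seed, subject_id=sid,
        )
        subjects.append(
            SubjectRecording(subject_id=sid, sequence=seq, cr10=log,
                             params=params, noise=config.noise)
        )
    return Cohort(config=config, subjects=subjects)


def write_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    """Write per-subject skeleton/CR10 CSVs plus a JSON manifest.

    The manifest records the drawn motion parameters per subject so that
    truth-based tests can recover the generating model.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort.subjects:
        skel = outdir / f"{rec.subject_id}_skeleton.csv"
        cr10 = outdir / f"{rec.subject_id}_cr10.csv"
        write_skeleton_csv(rec.sequence, skel)
        write_cr10_log(rec.cr10, cr10)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "skeleton": skel.name,
                "cr10": cr10.name,
                "motion_params": dataclasses.asdict(rec.params),
                "noise_params": dataclasses.asdict(rec.noise),
            }
        )
    manifest = {
        "n_subjects": cohort.config.n_subjects,
        "duration_s": cohort.config.duration,
        "fps": cohort.config.fps,
        "seed": cohort.config.seed,
        "subjects": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path
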