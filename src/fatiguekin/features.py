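"""The 24-feature kinematic representation and CR10 labeling.

Six per-cycle quantities are computed on each of the four limbs:

=========  =============================================  =========
quantity   definition                                     units
=========  =============================================  =========
angle      mean abduction angle over close->open          rad
peak_vel   max angular velocity over close->open          rad/s
t_open     close->open phase duration                     s
min_vel    min angular velocity over open->close          rad/s
t_close    open->close phase duration                     s
t_cycle    open->open inter-cycle interval                s
=========  =============================================  =========

Feature IDs f01..f24 follow a fixed table: within each quantity block the
limb order is left leg, right leg, left arm, right arm (f01-f04 angles,
f05-f08 peak velocities, f09-f12 t_open, f13-f16 min velocities, f17-f20
t_close, f21-f24 inter-cycle intervals).

Per-cycle features are averaged over non-overlapping windows of three
consecutive cycles, and each window takes the class label of the Borg CR10
report owning the 30-s protocol segment that contains its midpoint
(Low: CR10 0-3, Medium: 4-6, High: >= 7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cycles import CycleEvent
from .kinematics import AngleSeries, AngularVelocitySeries
from .skeleton_io import CR10Log

CLASSES = ("Low", "Medium", "High")
HIGH_CR10_THRESHOLD = 7
MEDIUM_CR10_THRESHOLD = 4
CR10_SEGMENT_S = 30.0

#: Limb order within each quantity block of the feature table.
LIMB_ORDER = ("left_leg", "right_leg", "left_arm", "right_arm")
_QUANTITIES = ("angle", "peak_vel", "t_open", "min_vel", "t_close", "t_cycle")

#: Feature id (f01..f24) -> (quantity, limb).
FEATURE_TABLE: dict[str, tuple[str, str]] = {
    f"f{q * 4 + l + 1:02d}": (quantity, limb)
    for q, quantity in enumerate(_QUANTITIES)
    for l, limb in enumerate(LIMB_ORDER)
}
FEATURE_IDS = tuple(FEATURE_TABLE)          # f01..f24
N_FEATURES = len(FEATURE_IDS)

#: Anatomical segment -> feature ids, for grouped importance summaries.
SEGMENT_FEATURES: dict[str, tuple[str, ...]] = {
    limb: tuple(fid for fid, (_, lb) in FEATURE_TABLE.items() if lb == limb)
    for limb in LIMB_ORDER
}


@dataclass(frozen=True)
class PerCycleFeatures:
    limb_id: str
    cycle_index: int
    t_start: float          # close event opening the cycle
    t_end: float            # next open event closing the o->o interval
    mean_open_angle: float
    peak_open_velocity: float
    min_close_velocity: float
    t_open: float
    t_close: float
    t_cycle: float


@dataclass
class FeatureWindow:
    subject_id: str
    window_index: int
    t_start: float
    t_end: float
    features: dict[str, float]      # exactly the 24 FEATURE_IDS
    cr10: int | None = None
    label: str | None = None


def per_cycle_features(
    angles: AngleSeries,
    velocities: AngularVelocitySeries,
    events: list[CycleEvent],
) -> list[PerCycleFeatures]:
    """One record per complete cycle on one limb.

    A complete cycle is a close->open phase, its following open->close
    phase, and the enclosing open->open interval: the event pattern
    (close, open, close, open). Trailing cycles missing any component are
    dropped.
    """
    if len(events) < 4:
        warnings.warn(f"{angles.limb_id}: fewer than 4 events, no complete "
                      "cycles", stacklevel=2)
        return []
    t = angles.timestamps
    out: list[PerCycleFeatures] = []
    cycle_index = 0
    for i in range(len(events) - 3):
        kinds = tuple(e.kind for e in events[i : i + 4])
        if kinds != ("close", "open", "close", "open"):
            continue
        c0, o0, c1, o1 = events[i : i + 4]
        open_mask = (t >= c0.time) & (t <= o0.time)
        close_mask = (t >= o0.time) & (t <= c1.time)
        if not open_mask.any() or not close_mask.any():
            continue
        out.append(
            PerCycleFeatures(
                limb_id=angles.limb_id,
                cycle_index=cycle_index,
                t_start=c0.time,
                t_end=o1.time,
                mean_open_angle=float(angles.theta[open_mask].mean()),
                peak_open_velocity=float(velocities.omega[open_mask].max()),
                min_close_velocity=float(velocities.omega[close_mask].min()),
                t_open=o0.time - c0.time,
                t_close=c1.time - o0.time,
                t_cycle=o1.time - o0.time,
            )
        )
        cycle_index += 1
    return out


_QUANTITY_ATTR = {
    "angle": "mean_open_angle",
    "peak_vel": "peak_open_velocity",
    "t_open": "t_open",
    "min_vel": "min_close_velocity",
    "t_close": "t_close",
    "t_cycle": "t_cycle",
}


def build_windows(
    per_limb: dict[str, list[PerCycleFeatures]],
    subject_id: str,
    n_cycles: int = 3,
) -> list[FeatureWindow]:
    """Average consecutive disjoint groups of ``n_cycles`` cycles per limb.

    Window k uses each limb's cycle indices [k*n, (k+1)*n); the number of
    windows is limited by the limb with fewest complete cycles, and a
    trailing remainder of fewer than ``n_cycles`` cycles is dropped.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    missing = [l for l in LIMB_ORDER if not per_limb.get(l)]
    if missing:
        raise ValueError(f"{subject_id}: no complete cycles for {missing}")
    n_windows = min(len(per_limb[l]) for l in LIMB_ORDER) // n_cycles
    windows: list[FeatureWindow] = []
    for k in range(n_windows):
        feats: dict[str, float] = {}
        t0, t1 = np.inf, -np.inf
        for fid, (quantity, limb) in FEATURE_TABLE.items():
            group = per_limb[limb][k * n_cycles : (k + 1) * n_cycles]
            attr = _QUANTITY_ATTR[quantity]
            feats[fid] = float(np.mean([getattr(c, attr) for c in group]))
            t0 = min(t0, min(c.t_start for c in group))
            t1 = max(t1, max(c.t_end for c in group))
        windows.append(
            FeatureWindow(subject_id=subject_id, window_index=k,
                          t_start=t0, t_end=t1, features=feats)
        )
    return windows


def label_from_cr10(rating: int) -> str:
    """Map a Borg CR10 rating to Low (0-3), Medium (4-6) or High (>= 7)."""
    if not 0 <= rating <= 10:
        raise ValueError(f"CR10 rating {rating} outside [0, 10]")
    if rating >= HIGH_CR10_THRESHOLD:
        return "High"
    if rating >= MEDIUM_CR10_THRESHOLD:
        return "Medium"
    return "Low"


def assign_labels(
    windows: list[FeatureWindow], log: CR10Log
) -> list[FeatureWindow]:
    """Attach the CR10 rating and class owning each window's midpoint.

    A report at time t_r labels the immediately preceding protocol segment
    (t_r - 30, t_r]. Windows whose midpoint precedes the first segment take
    the first report; midpoints past the last report take the last.
    """
    if len(log) == 0:
        raise ValueError("empty CR10 log; cannot label windows")
    for w in windows:
        mid = 0.5 * (w.t_start + w.t_end)
        owner = None
        for t_r, rating in zip(log.times, log.ratings):
            if t_r - CR10_SEGMENT_S < mid <= t_r:
                owner = rating
                break
        if owner is None:
            owner = log.ratings[0] if mid <= log.times[0] else log.ratings[-1]
        w.cr10 = int(owner)
        w.label = label_from_cr10(w.cr10)
    return windows


def windows_to_frame(windows: list[FeatureWindow]) -> pd.DataFrame:
    """Flatten labeled windows into the classifier's input table."""
    rows = []
    for w in windows:
        row = {
            "subject_id": w.subject_id,
            "window_index": w.window_index,
            "t_start": w.t_start,
            "t_end": w.t_end,
            **w.features,
        }
        row["cr10"] = w.cr10
        row["label"] = w.label
        rows.append(row)
    return pd.DataFrame(rows)
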