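"""Movement-cycle event detection and phase segmentation.

"Open" events are prominent local maxima of the abduction angle (limbs
spread), "close" events the corresponding minima (neutral stance). A
prominence threshold expressed as a fraction of the trace's angle range
makes detection robust to the amplitude decay that accompanies fatigue —
a fixed angle threshold would start missing cycles late in the trial.

From the alternating event stream come the two half-cycle phases
(close->open, open->close) and the open->open inter-cycle intervals that
the timing features are built on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .kinematics import AngleSeries


class NoMovementError(ValueError):
    """Angle range too small to contain any movement cycles."""


@dataclass(frozen=True)
class CycleDetectConfig:
    prominence_frac: float = 0.2    # of the trace's angle range
    min_separation: float = 0.5     # seconds between same-kind events
    min_range: float = 0.05         # rad; below this, no-movement error

    def __post_init__(self) -> None:
        if not 0 < self.prominence_frac < 1:
            raise ValueError("prominence_frac must lie in (0, 1)")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be > 0")


@dataclass(frozen=True)
class CycleEvent:
    limb_id: str
    kind: str               # "open" | "close"
    time: float             # seconds
    index: int              # frame index
    theta_at_event: float   # radians


@dataclass(frozen=True)
class Phase:
    limb_id: str
    kind: str               # "closing_to_open" | "opening_to_close"
    t_start: float
    t_end: float

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def _fps_of(angles: AngleSeries) -> float:
    dt = np.diff(angles.timestamps)
    return 1.0 / float(np.median(dt))


def detect_events(
    angles: AngleSeries, cfg: CycleDetectConfig = CycleDetectConfig()
) -> list[CycleEvent]:
    """Detect alternating open/close events on a smoothed angle trace.

    Between consecutive same-kind extrema only the more extreme one is
    kept, enforcing strict open/close alternation; plateau extrema resolve
    to their earliest frame (find_peaks' left edge).
    """
    theta = angles.theta
    rng = float(theta.max() - theta.min())
    if rng < cfg.min_range:
        raise NoMovementError(
            f"{angles.limb_id}: angle range {rng:.4f} rad below "
            f"{cfg.min_range} rad"
        )
    fps = _fps_of(angles)
    distance = max(1, int(round(cfg.min_separation * fps)))
    prominence = cfg.prominence_frac * rng

    opens, _ = find_peaks(theta, prominence=prominence, distance=distance)
    closes, _ = find_peaks(-theta, prominence=prominence, distance=distance)

    events = sorted(
        [CycleEvent(angles.limb_id, "open", float(angles.timestamps[i]),
                    int(i), float(theta[i])) for i in opens]
        + [CycleEvent(angles.limb_id, "close", float(angles.timestamps[i]),
                      int(i), float(theta[i])) for i in closes],
        key=lambda e: e.time,
    )

    # Enforce alternation: among consecutive same-kind events keep the more
    # extreme (higher theta for open, lower for close; ties -> earliest).
    filtered: list[CycleEvent] = []
    for ev in events:
        if filtered and filtered[-1].kind == ev.kind:
            prev = filtered[-1]
            better = (
                ev.theta_at_event > prev.theta_at_event
                if ev.kind == "open"
                else ev.theta_at_event < prev.theta_at_event
            )
            if better:
                filtered[-1] = ev
        else:
            filtered.append(ev)
    return filtered


def segment_phases(events: list[CycleEvent]) -> list[Phase]:
    """Pair alternating events into close->open and open->close phases."""
    if len(events) < 2:
        warnings.warn("fewer than 2 cycle events; no phases", stacklevel=2)
        return []
    phases = []
    for a, b in zip(events[:-1], events[1:]):
        kind = ("closing_to_open" if (a.kind, b.kind) == ("close", "open")
                else "opening_to_close")
        phases.append(Phase(a.limb_id, kind, a.time, b.time))
    return phases


def open_to_open_intervals(
    events: list[CycleEvent],
) -> list[tuple[float, float]]:
    """Consecutive (t_open_i, t_open_{i+1}) pairs; empty below 2 opens."""
    opens = [e.time for e in events if e.kind == "open"]
    return list(zip(opens[:-1], opens[1:]))
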