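"""Dropout interpolation and pre-differentiation smoothing.

Depth-based skeleton tracking loses joints for short runs of frames;
those gaps are filled by linear interpolation before any smoothing or
differentiation. Smoothing defaults to a Savitzky-Golay filter (window
15 frames = 0.5 s at 30 fps, polynomial order 3), which preserves the
velocity peaks the downstream features depend on far better than a wide
moving average would.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter


class UnrecoverableSeriesError(ValueError):
    """Every sample in the series is missing; nothing to interpolate from."""


@dataclass(frozen=True)
class SmoothingConfig:
    method: str = "savitzky_golay"      # or "moving_average"
    window: int = 15                    # frames, odd, >= 3
    polyorder: int = 3                  # SG only, < window
    max_gap: int = 10                   # longest dropout run to interpolate

    def __post_init__(self) -> None:
        if self.method not in ("savitzky_golay", "moving_average"):
            raise ValueError(f"unknown smoothing method {self.method!r}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.method == "savitzky_golay" and self.polyorder >= self.window:
            raise ValueError("polyorder must be < window")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")


def interpolate_dropouts(
    values: np.ndarray,
    max_gap: int,
    missing: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill missing runs of length <= max_gap by linear interpolation.

    Longer runs are left missing (NaN) and reported in the returned mask.
    Leading/trailing missing values are filled with the nearest valid
    sample regardless of run length (there is no second anchor to
    interpolate against).

    Returns ``(filled, still_missing)``.
    """
    values = np.asarray(values, dtype=float).copy()
    if missing is None:
        missing = ~np.isfinite(values)
    else:
        missing = np.asarray(missing, dtype=bool) | ~np.isfinite(values)
    if missing.all():
        raise UnrecoverableSeriesError("all samples missing")
    if not missing.any():
        return values, missing

    idx = np.arange(len(values))
    valid_idx = idx[~missing]
    still_missing = np.zeros_like(missing)

    # Identify contiguous missing runs.
    starts = np.flatnonzero(missing & ~np.roll(missing, 1))
    if missing[0]:
        starts = np.unique(np.concatenate(([0], starts)))
    for s in starts:
        e = s
        while e + 1 < len(values) and missing[e + 1]:
            e += 1
        interior = s > 0 and e < len(values) - 1
        run = e - s + 1
        if not interior:
            # Edge run: extend the nearest valid value.
            fill = values[valid_idx[0]] if s == 0 else values[valid_idx[-1]]
            values[s : e + 1] = fill
        elif run <= max_gap:
            values[s : e + 1] = np.interp(
                idx[s : e + 1], [s - 1, e + 1], [values[s - 1], values[e + 1]]
            )
        else:
            values[s : e + 1] = np.nan
            still_missing[s : e + 1] = True
    return values, still_missing


def smooth(values: np.ndarray, config: SmoothingConfig) -> np.ndarray:
    """Smooth a gap-free series; output has the same length as the input.

    Savitzky-Golay handles edges by fitting the edge polynomial
    (``mode="interp"``), so polynomials up to ``polyorder`` — constants
    and linear trends included — pass through unchanged everywhere. The
    moving average pads by mirror reflection, which preserves constants.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("series still contains missing values; "
                         "run interpolate_dropouts first")
    if len(values) < config.window:
        raise ValueError(
            f"series length {len(values)} < window {config.window}"
        )
    if config.method == "savitzky_golay":
        return savgol_filter(values, config.window, config.polyorder,
                             mode="interp")
    # Moving average with mirror padding to preserve length and constants.
    half = config.window // 2
    padded = np.pad(values, half, mode="reflect")
    kernel = np.ones(config.window) / config.window
    return np.convolve(padded, kernel, mode="valid")
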