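"""EMG conditioning, normalization, and preactivation-onset detection.

Onset detection follows the cumulative-integration principle: over the
aerial phase, the running integral C(t) of the rectified, normalized EMG is
compared with the chord joining its endpoints; the sample of maximum
downward deviation from that chord is the elbow where electrical activity
most rapidly increases, i.e. the preactivation onset. Three inclusion gates
accommodate low activation levels:

1. no-late-max  — the 1 Hz-lowpassed aerial trace must have its latest
   local maximum within 150 ms of landing;
2. too-early    — onsets more than 150 ms before landing are outside the
   physiological preactivation range and are rejected;
3. sub-1-percent — the mean normalized activity between onset and landing
   must reach 1% of the muscle's maximal activation.

All magnitudes are expressed relative to the peak 100 ms sliding-window
average of the rectified EMG on maximal-jump calibration trials.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .filters import emg_band, gaussian_lowpass, sliding_average

ONSET_GATE_MS = 150.0
MAGNITUDE_GATE = 0.01
GATE_LOWPASS_HZ = 1.0


class ExclusionRule(str, Enum):
    NONE = "none"
    NO_LATE_MAX = "no-late-max"
    TOO_EARLY = "too-early"
    SUB_1_PERCENT = "sub-1-percent"


class SilentReferenceError(ValueError):
    """Normalization reference channel contains no activity."""


@dataclass
class PreactivationResult:
    onset_ms_before_landing: float | None
    magnitude: float | None  # mean normalized EMG over [onset, touchdown]
    iemg: float | None  # normalized * s over the same window
    exclusion_rule: ExclusionRule
    onset_index: int | None = None  # sample index within the full channel

    @property
    def included(self) -> bool:
        return self.exclusion_rule is ExclusionRule.NONE


def preprocess(raw: np.ndarray, fs: float) -> np.ndarray:
    """Band-limit (5-450 Hz, zero-phase) and full-wave rectify raw EMG."""
    return np.abs(emg_band(np.asarray(raw, dtype=float), fs))


def normalization_peak(
    max_jump_rectified: Iterable[np.ndarray] | np.ndarray, fs: float, window_s: float = 0.1
) -> float:
    """Peak activation: the maximum, over all maximal-jump trials, of the
    centered 100 ms sliding-window average of the rectified EMG."""
    if isinstance(max_jump_rectified, np.ndarray) and max_jump_rectified.ndim == 1:
        max_jump_rectified = [max_jump_rectified]
    peak = 0.0
    n_trials = 0
    for trial in max_jump_rectified:
        trial = np.asarray(trial, dtype=float)
        if trial.size < int(round(window_s * fs)):
            raise ValueError("reference trial shorter than the averaging window")
        peak = max(peak, float(np.max(sliding_average(trial, fs, window_s))))
        n_trials += 1
    if n_trials == 0:
        raise ValueError("at least one maximal-jump trial required")
    if peak <= 0.0:
        raise SilentReferenceError("silent reference channel: normalization peak is zero")
    return peak


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau takes its last sample, and the
    first/last samples count when they top their single neighbour (the burst
    ramping into ground contact peaks at the aerial-window edge)."""
    idx = []
    n = x.size
    # comparisons with tolerance: the 1 Hz smoother can flatten the window
    # to a numerical plateau where raw <, > would chase rounding noise
    eps = 1e-8 * float(np.max(np.abs(x))) if n else 0.0
    for i in range(1, n - 1):
        if x[i] >= x[i - 1] - eps and x[i] > x[i + 1] + eps:
            idx.append(i)
    if n >= 2 and x[0] > x[1] + eps:
        idx.append(0)
    if n >= 2 and x[-1] >= x[-2] - eps:
        idx.append(n - 1)
    return np.sort(np.array(idx, dtype=int))


def detect_onset(
    rectified_norm: np.ndarray,
    fs: float,
    aerial: tuple[int, int],
) -> PreactivationResult:
    """Preactivation onset (ms before landing) for one muscle and jump.

    ``aerial`` is the (liftoff, touchdown) sample pair on this channel's
    clock. The returned result carries the exclusion rule that fired, or
    the onset/magnitude/iEMG triple when the jump is included.
    """
    x = np.asarray(rectified_norm, dtype=float)
    lo, td = aerial
    if not (0 <= lo < td < x.size):
        raise ValueError("aerial window out of range")
    seg = x[lo : td + 1]
    if seg.size / fs < 0.05:
        raise ValueError("aerial window shorter than 50 ms")

    # Gate 1: overall burst shape near landing.
    smooth = gaussian_lowpass(seg, fs, GATE_LOWPASS_HZ)
    maxima = _local_maxima(smooth)
    if maxima.size == 0:
        return PreactivationResult(None, None, None, ExclusionRule.NO_LATE_MAX)
    latest_ms = (seg.size - 1 - maxima[-1]) / fs * 1000.0
    if latest_ms > ONSET_GATE_MS:
        return PreactivationResult(None, None, None, ExclusionRule.NO_LATE_MAX)

    # Core: maximum downward deviation of the cumulative integral from its
    # endpoint chord; ties resolve to the latest sample.
    c = cumulative_trapezoid(seg, dx=1.0 / fs, initial=0.0)
    chord = np.linspace(c[0], c[-1], c.size)
    dev = c - chord
    onset_rel = int(c.size - 1 - np.argmin(dev[::-1]))
    onset_ms = (seg.size - 1 - onset_rel) / fs * 1000.0

    if onset_ms > ONSET_GATE_MS:
        return PreactivationResult(onset_ms, None, None, ExclusionRule.TOO_EARLY)

    window = seg[onset_rel:]
    magnitude = float(np.mean(window))
    if magnitude < MAGNITUDE_GATE:
        return PreactivationResult(onset_ms, magnitude, None, ExclusionRule.SUB_1_PERCENT)

    if window.size >= 2:
        iemg = float(np.trapezoid(window, dx=1.0 / fs))
    else:
        iemg = 0.0
    return PreactivationResult(
        onset_ms, magnitude, iemg, ExclusionRule.NONE, onset_index=lo + onset_rel
    )


def preactivation_metrics(
    rectified_norm: np.ndarray, fs: float, onset_index: int, touchdown_index: int
) -> tuple[float, float]:
    """Preactivation magnitude (mean normalized EMG) and iEMG (trapezoidal
    integral, normalized*s) over [onset, touchdown]."""
    if onset_index >= touchdown_index:
        raise ValueError("onset must precede touchdown")
    window = np.asarray(rectified_norm, dtype=float)[onset_index : touchdown_index + 1]
    return float(np.mean(window)), float(np.trapezoid(window, dx=1.0 / fs))


def triceps_surae_preactivity(
    iemg_by_muscle: Mapping[str, float | None], allow_partial: bool = False
) -> tuple[float | None, str | None]:
    """Mean iEMG over the MG/LG/SOL of one leg for one jump.

    Defined as a three-muscle average; when any member muscle was excluded
    the value is missing with the reason propagated, unless
    ``allow_partial`` permits averaging the remaining muscles.
    """
    values = {k: v for k, v in iemg_by_muscle.items() if v is not None}
    missing = [k for k, v in iemg_by_muscle.items() if v is None]
    if missing and not allow_partial:
        return None, f"excluded muscles: {', '.join(sorted(missing))}"
    if not values:
        return None, "all muscles excluded"
    return float(np.mean(list(values.values()))), None
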