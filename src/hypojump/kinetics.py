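"""Jump phase segmentation from vertical GRF, impulses, and ballistic timing.

Phase conventions: the aerial interval is the longest contiguous run of
samples with total vertical GRF below 25 N; the lift phase starts at the
last upward crossing of body weight before the push-off peak and ends at
liftoff; the land phase starts at touchdown and ends at the first downward
crossing of body weight after the landing peak. Crossing indices are the
sample on the lower side of the interpolated crossing (floor); plateaus
exactly at body weight resolve to their earliest sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AERIAL_THRESHOLD_N = 25.0


class NoAerialPhaseError(ValueError):
    """No sub-25 N run: the trial contains no flight phase."""


class DegenerateTrialError(ValueError):
    """Body-weight crossings required for segmentation are absent."""


@dataclass
class JumpPhases:
    lift_start: int
    liftoff: int
    touchdown: int
    land_end: int
    fs: float

    def __post_init__(self) -> None:
        if not (self.lift_start < self.liftoff < self.touchdown <= self.land_end):
            raise ValueError("phase indices out of order")

    @property
    def liftoff_t(self) -> float:
        return self.liftoff / self.fs

    @property
    def touchdown_t(self) -> float:
        return self.touchdown / self.fs


@dataclass
class JumpKinetics:
    lift_impulse: float  # N*s
    land_impulse: float  # N*s
    jump_height: float  # m
    target_error: float  # m, signed
    abs_target_error: float  # m
    aerial_g_estimate: float  # m/s^2, signed (negative downward)


def segment_phases(grf_z: np.ndarray, body_weight: float, fs: float) -> JumpPhases:
    """Locate lift/aerial/land boundaries on a 25 Hz lowpassed GRF trace."""
    grf = np.asarray(grf_z, dtype=float)
    below = grf < AERIAL_THRESHOLD_N
    if not below.any():
        raise NoAerialPhaseError("no aerial phase: GRF never drops below 25 N")
    # longest contiguous sub-threshold run
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    k = int(np.argmax(stops - starts))
    liftoff, touchdown = int(starts[k]), int(stops[k])
    if touchdown >= grf.size:
        raise NoAerialPhaseError("aerial run extends to end of recording (no touchdown)")

    # push-off peak before liftoff
    if liftoff < 2:
        raise DegenerateTrialError("no ground phase before liftoff")
    push_peak = int(np.argmax(grf[:liftoff]))
    lift_start = _last_upcrossing(grf, body_weight, push_peak)
    if lift_start is None:
        raise DegenerateTrialError("no body-weight upcrossing before push-off peak")

    land_peak = touchdown + int(np.argmax(grf[touchdown:]))
    land_end = _first_downcrossing(grf, body_weight, land_peak)
    if land_end is None:
        raise DegenerateTrialError("no body-weight downcrossing after landing peak")
    return JumpPhases(lift_start, liftoff, touchdown, land_end, fs)


def _last_upcrossing(grf: np.ndarray, bw: float, before: int) -> int | None:
    for i in range(before - 1, -1, -1):
        if grf[i] <= bw < grf[i + 1]:
            # a plateau exactly at bw resolves to its earliest sample
            while i > 0 and grf[i - 1] == bw:
                i -= 1
            return i
    return None


def _first_downcrossing(grf: np.ndarray, bw: float, after: int) -> int | None:
    for i in range(after, grf.size - 1):
        if grf[i] >= bw > grf[i + 1]:
            while i > after and grf[i - 1] == bw:
                i -= 1
            return i
    return None


def compute_impulses(
    grf_z: np.ndarray, phases: JumpPhases, fs: float, net: bool = False, body_weight: float = 0.0
) -> tuple[float, float]:
    """Trapezoidal area under GRFz over the lift and land windows (N*s).

    ``net=True`` integrates GRFz - body_weight instead (impulse-momentum
    bookkeeping); the default is the gross area under the curve.
    """
    grf = np.asarray(grf_z, dtype=float)
    if net:
        grf = grf - body_weight
    lift = grf[phases.lift_start : phases.liftoff + 1]
    land = grf[phases.touchdown : phases.land_end + 1]
    if lift.size < 2 or land.size < 2:
        raise ValueError("empty impulse window")
    return float(np.trapezoid(lift, dx=1.0 / fs)), float(np.trapezoid(land, dx=1.0 / fs))


def jump_metrics(
    marker_z: np.ndarray,
    fs_marker: float,
    phases: JumpPhases,
    standing_height: float,
    target_height: float,
) -> tuple[float, float]:
    """Jump height (aerial marker peak minus standing reference) and signed
    target error. A non-positive height is returned as-is; callers flag it."""
    marker = np.asarray(marker_z, dtype=float)
    i0 = int(np.ceil(phases.liftoff_t * fs_marker))
    i1 = int(np.floor(phases.touchdown_t * fs_marker))
    if i1 <= i0:
        raise ValueError("aerial window empty on marker clock")
    height = float(np.max(marker[i0 : i1 + 1]) - standing_height)
    return height, height - target_height


def aerial_acceleration(marker_z: np.ndarray, fs_marker: float, phases: JumpPhases) -> float:
    """Least-squares quadratic fit of the aerial marker trajectory; returns
    2x the quadratic coefficient (the constant vertical acceleration)."""
    marker = np.asarray(marker_z, dtype=float)
    i0 = int(np.ceil(phases.liftoff_t * fs_marker)) + 1
    i1 = int(np.floor(phases.touchdown_t * fs_marker)) - 1
    if i1 - i0 + 1 < 5:
        raise ValueError("aerial window too short for quadratic fit")
    t = (np.arange(i0, i1 + 1) - i0) / fs_marker
    coef = np.polynomial.polynomial.polyfit(t, marker[i0 : i1 + 1], 2)
    return float(2.0 * coef[2])


def fall_time(height: float, g: float) -> float:
    """Free-fall duration from ``height`` under gravity ``g``: sqrt(2h/g)."""
    if g <= 0:
        raise ValueError("g must be positive")
    if height < 0:
        raise ValueError("height must be non-negative")
    return float(np.sqrt(2.0 * height / g))


def delay_prediction(height: float, g_ref: float, g_alt: float) -> float:
    """Extra fall time expected at ``g_alt`` relative to ``g_ref``."""
    return fall_time(height, g_alt) - fall_time(height, g_ref)


def delay_mitigation_percent(predicted: float, observed: float) -> float:
    """Percent of a predicted timing delay removed by feedback:
    100 * (predicted - observed) / predicted."""
    if predicted <= 0:
        raise ValueError("predicted delay must be positive")
    return 100.0 * (predicted - observed) / predicted
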