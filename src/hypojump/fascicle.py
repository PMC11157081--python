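"""Muscle-tendon-junction geometry, muscle length/velocity, force, and the
group-Ia afferent firing-rate estimate.

The MTJ is tracked as a pixel coordinate in an ultrasound image whose
columns are captured sequentially (rolling shutter); each frame's sample
time is therefore shifted by (u / image_width) * frame_period before the
track is interpolated onto the kinematic clock. The MTJ is projected
orthogonally onto the muscle-tendon-unit line (knee center to Achilles
insertion); the medial-gastrocnemius length is knee-to-projection and the
tendon length projection-to-insertion.

The Ia firing-rate model combines a sub-linear lengthening-velocity term, a
linear stretch term and a central-drive (alpha-gamma coactivation) term:

    R_Ia = 65 * (V/L0)^0.5 + 200 * (L - L0)/L0 + k_u_max * u + R_Ia0

with the velocity clamped to lengthening (V >= 0), R_Ia0 = 0, and the total
rate floored at zero. A strict-literal variant with the stretch term in
absolute meters (200 * (L - L0)) is selectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .filters import lowpass

IA_VELOCITY_GAIN = 65.0
IA_LENGTH_GAIN = 200.0
K_U_MAX = 100.0
MIN_MOMENT_ARM = 1.0e-3


@dataclass
class MuscleState:
    t: np.ndarray  # kinematic clock, s
    l_mg: np.ndarray  # m
    l_tendon: np.ndarray  # m
    l_mtu: np.ndarray  # m
    v_mg: np.ndarray  # m/s, lengthening positive
    l0: float  # m
    f_mg: np.ndarray | None = None  # N
    activation: np.ndarray | None = None  # normalized, [0, 1]
    r_ia: np.ndarray | None = None  # impulses/s
    out_of_segment: np.ndarray | None = None  # bool flags per frame


def rolling_shutter_offsets(
    u_px: np.ndarray, image_width: int, frame_period: float
) -> np.ndarray:
    """Per-frame capture-time offsets, (u / width) * frame_period, seconds."""
    if image_width <= 0:
        raise ValueError("image_width must be positive")
    u = np.asarray(u_px, dtype=float)
    if np.any((u < 0) | (u > image_width)):
        warnings.warn("MTJ pixel coordinates outside the image; clamped", stacklevel=2)
        u = np.clip(u, 0.0, image_width)
    return (u / image_width) * frame_period


def pixels_to_lab(
    u_px: np.ndarray,
    v_px: np.ndarray,
    px_scale: float,
    probe_r: np.ndarray,
    probe_t: np.ndarray,
) -> np.ndarray:
    """Map image coordinates to 3-D lab points via the probe's rigid pose."""
    p = np.stack(
        [np.asarray(u_px, float) * px_scale, np.asarray(v_px, float) * px_scale,
         np.zeros_like(np.asarray(u_px, float))],
        axis=-1,
    )
    return p @ np.asarray(probe_r).T + np.asarray(probe_t)


def project_mtj(
    mtj_lab: np.ndarray, knee_center: np.ndarray, insertion: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Orthogonal projection of the MTJ onto the knee-insertion line.

    Returns (L_MG, L_tendon, L_MTU, out_of_segment). L_MG + L_tendon equals
    L_MTU exactly for in-segment projections; out-of-segment projections are
    reported untruncated but flagged.
    """
    knee = np.asarray(knee_center, dtype=float)
    ins = np.asarray(insertion, dtype=float)
    d = ins - knee
    l_mtu = float(np.linalg.norm(d))
    if l_mtu == 0.0:
        raise ValueError("knee and insertion coincide")
    mtj = np.atleast_2d(np.asarray(mtj_lab, dtype=float))
    frac = (mtj - knee) @ d / l_mtu**2
    proj = knee + frac[:, None] * d
    l_mg = np.linalg.norm(proj - knee, axis=1)
    l_tendon = np.linalg.norm(ins - proj, axis=1)
    out = (frac < 0.0) | (frac > 1.0)
    l_mtu_arr = np.full(l_mg.shape, l_mtu)
    if np.asarray(mtj_lab).ndim == 1:
        return float(l_mg[0]), float(l_tendon[0]), l_mtu, bool(out[0])
    return l_mg, l_tendon, l_mtu_arr, out


def lengths_and_velocity(l_mg_raw: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """6 Hz zero-phase lowpass of the length series and its first derivative
    (central differences; lengthening positive)."""
    l = np.asarray(l_mg_raw, dtype=float)
    if l.size < 5:
        raise ValueError("length series too short")
    if fs <= 12.0:
        raise ValueError("sampling rate must exceed 12 Hz for the 6 Hz filter")
    lf = lowpass(l, fs, 6.0)
    v = np.gradient(lf, 1.0 / fs)
    return lf, v


def interpolate_track(
    frame_times: np.ndarray, values: np.ndarray, target_times: np.ndarray
) -> np.ndarray:
    """Cubic interpolation of (shutter-corrected) frame samples onto the
    kinematic clock, clamped to the covered time span."""
    cs = CubicSpline(frame_times, values)
    t = np.clip(target_times, frame_times[0], frame_times[-1])
    return cs(t)


def ia_rate(
    v_mg: np.ndarray | float,
    l_mg: np.ndarray | float,
    l0: float,
    u: np.ndarray | float,
    k_u_max: float = K_U_MAX,
    r_ia0: float = 0.0,
    normalized_length_term: bool = True,
) -> np.ndarray | float:
    """Group-Ia afferent firing rate estimate (impulses/s)."""
    if l0 <= 0:
        raise ValueError("L0 must be positive")
    v = np.clip(np.asarray(v_mg, dtype=float), 0.0, None)  # lengthening only
    l = np.asarray(l_mg, dtype=float)
    uu = np.asarray(u, dtype=float)
    stretch = (l - l0) / l0 if normalized_length_term else (l - l0)
    rate = IA_VELOCITY_GAIN * np.sqrt(v / l0) + IA_LENGTH_GAIN * stretch + k_u_max * uu + r_ia0
    rate = np.maximum(rate, 0.0)
    if np.isscalar(v_mg) and np.isscalar(l_mg) and np.isscalar(u):
        return float(rate)
    return rate


def moment_arm(
    ankle_center: np.ndarray, knee_center: np.ndarray, insertion: np.ndarray
) -> float:
    """Orthogonal distance from the ankle joint center to the MTU line."""
    knee = np.asarray(knee_center, float)
    ins = np.asarray(insertion, float)
    ankle = np.asarray(ankle_center, float)
    d = ins - knee
    ld = np.linalg.norm(d)
    if ld == 0:
        raise ValueError("degenerate MTU line")
    return float(np.linalg.norm(np.cross(ankle - knee, d)) / ld)


def muscle_force(
    ankle_torque: np.ndarray | float, arm: np.ndarray | float
) -> tuple[np.ndarray | float, bool]:
    """MG force required to produce the ankle torque about the given moment
    arm. Returns (force, unreliable) where ``unreliable`` flags arms below
    1 mm."""
    arm_arr = np.asarray(arm, dtype=float)
    if np.any(arm_arr <= 0):
        raise ValueError("moment arm must be positive")
    unreliable = bool(np.any(arm_arr < MIN_MOMENT_ARM))
    force = np.asarray(ankle_torque, dtype=float) / arm_arr
    if np.isscalar(ankle_torque) and np.isscalar(arm):
        return float(force), unreliable
    return force, unreliable
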