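"""Synthetic countermovement-jump trial generator.

Each trial is built from a piecewise closed-form center-of-mass (COM)
trajectory: quiet standing, a raised-cosine unload (the countermovement
dip), a raised-cosine push-off ending at takeoff with the velocity needed
to reach the requested jump height, ballistic flight under the trial's
effective gravity, and a critically-damped spring landing. The vertical
ground reaction force is m*(a + g_eff) throughout, so impulse-momentum and
flight-time/height identities hold exactly at the continuum level; takeoff
and touchdown appear as force steps rather than finite ramps so that the
25 N aerial threshold recovers the ballistic boundaries to the sample.

EMG is a band-limited (20-450 Hz) noise carrier multiplied by burst
envelopes: a push-off burst confined to the push window and a preactivation
burst that is identically zero until the injected onset time, rises over a
20 ms smoothstep, and holds through landing. Muscle-tendon-junction
channels are emitted as pixel tracks in a static probe frame with a
rolling-shutter timestamp model, in a shank-fixed coordinate frame.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import (
    CONDITIONS,
    MUSCLES,
    CohortConfig,
    ConfigError,
    ParticipantParams,
)
from .filters import bandpass

# Ground-phase shape parameters (s / rad s^-1): unload and push durations,
# quiet-stance lead-in, landing spring rate, post-landing tail.
UNLOAD_T = 0.45
PUSH_T = 0.25
QUIET_T = 0.6
LANDING_OMEGA = 12.0
LANDING_TAIL = 1.2
BURST_RISE_S = 0.012  # preactivation envelope smoothstep rise
LIFT_BURST_AMP = 0.8
POST_LAND_HOLD = 0.10
POST_LAND_DECAY = 0.15

# MTJ geometry (shank-fixed frame, meters).
KNEE = np.array([0.0, 0.0, 0.45])
INSERTION = np.array([0.0, 0.06, 0.02])
MTJ_PERP_OFFSET = 0.002
PX_SCALE = 1.0e-4  # m per pixel
IMAGE_WIDTH = 640
IMAGE_HEIGHT = 480
ANKLE_ARM = 0.05  # orthogonal ankle-center -> MTU distance, m
ANKLE_LEVER = 0.12  # GRF lever for the synthetic ankle torque, m


@dataclass
class MtjChannels:
    u_px: np.ndarray
    v_px: np.ndarray
    image_width: int
    image_height: int
    frame_period: float
    px_scale: float
    probe_r: np.ndarray  # (3, 3), static probe->lab rotation
    probe_t: np.ndarray  # (3,), static probe origin in lab
    knee: np.ndarray  # (3,)
    insertion: np.ndarray  # (3,)
    ankle: np.ndarray  # (3,)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.u_px.size) * self.frame_period


@dataclass
class TrialRecording:
    grf_z: np.ndarray
    fs_grf: float
    emg: dict[str, np.ndarray]
    fs_emg: float
    marker_z: np.ndarray
    fs_marker: float
    body_weight: float  # standing plate reading m*g_eff, N
    condition: str
    participant_id: str
    jump_index: int
    mtj: MtjChannels | None = None
    ankle_torque: np.ndarray | None = None  # marker clock, N*m
    is_max_jump: bool = False


@dataclass
class GroundTruth:
    true_onset_ms: dict[str, float]
    true_burst_amplitude: dict[str, float]
    true_liftoff: float  # s
    true_touchdown: float  # s
    true_jump_height: float  # m
    true_effective_g: float  # m/s^2
    v_takeoff: float  # m/s
    movement_start: float  # s, end of quiet stance
    target_height: float  # m
    true_muscle_length: np.ndarray | None = None  # marker clock, m
    l0_mg: float | None = None

    @property
    def flight_duration(self) -> float:
        return self.true_touchdown - self.true_liftoff


@dataclass
class CohortDataset:
    config: CohortConfig
    participants: list[ParticipantParams]
    trials: list[TrialRecording]
    truths: list[GroundTruth]
    max_jumps: dict[str, list[TrialRecording]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# COM closed forms


def _rc(tau, T):
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / T))


def _rc_v(tau, T):
    return tau / 2.0 - (T / (4.0 * np.pi)) * np.sin(2.0 * np.pi * tau / T)


def _rc_x(tau, T):
    return tau**2 / 4.0 + (T**2 / (8.0 * np.pi**2)) * (np.cos(2.0 * np.pi * tau / T) - 1.0)


@dataclass
class _ComModel:
    g: float
    v_to: float
    a1: float
    a2: float
    t_quiet: float
    t_unload: float
    t_push: float
    t_flight: float
    omega: float

    @property
    def t_liftoff(self) -> float:
        return self.t_quiet + self.t_unload + self.t_push

    @property
    def t_touchdown(self) -> float:
        return self.t_liftoff + self.t_flight

    def accel(self, t: np.ndarray) -> np.ndarray:
        """COM vertical acceleration at times ``t`` (m/s^2)."""
        return self._eval(t)[1]

    def displacement(self, t: np.ndarray) -> np.ndarray:
        """COM vertical displacement from standing at times ``t`` (m)."""
        return self._eval(t)[0]

    def _eval(self, t: np.ndarray):
        t = np.asarray(t, dtype=float)
        u = np.zeros_like(t)
        a = np.zeros_like(t)
        tq, T1, T2 = self.t_quiet, self.t_unload, self.t_push
        tlo, ttd = self.t_liftoff, self.t_touchdown
        v1 = -self.a1 * T1 / 2.0
        u1 = -self.a1 * T1**2 / 4.0

        m = (t >= tq) & (t < tq + T1)
        tau = t[m] - tq
        a[m] = -self.a1 * _rc(tau, T1)
        u[m] = -self.a1 * _rc_x(tau, T1)

        m = (t >= tq + T1) & (t < tlo)
        tau = t[m] - (tq + T1)
        a[m] = self.a2 * _rc(tau, T2)
        u[m] = u1 + v1 * tau + self.a2 * _rc_x(tau, T2)

        m = (t >= tlo) & (t < ttd)
        tau = t[m] - tlo
        a[m] = -self.g
        u[m] = self.v_to * tau - 0.5 * self.g * tau**2

        m = t >= ttd
        tau = t[m] - ttd
        w = self.omega
        e = np.exp(-w * tau)
        u[m] = -self.v_to * tau * e
        a[m] = self.v_to * w * e * (2.0 - w * tau)
        return u, a


def _solve_com(jump_height: float, g: float) -> _ComModel:
    if jump_height <= 0:
        raise ConfigError(f"jump height {jump_height:.3f} m is not positive")
    v_to = math.sqrt(2.0 * g * jump_height)
    t1, t2 = UNLOAD_T, PUSH_T
    for _ in range(8):
        a1 = 2.0 * t2 * v_to / (t1 * (t1 + t2))
        if a1 < 0.85 * g:
            break
        t1 *= 1.35  # gentler countermovement keeps GRF positive at low g
    else:
        raise ConfigError(f"cannot build a positive-GRF countermovement at g={g:.2f}")
    a2 = (2.0 / t2) * (v_to + a1 * t1 / 2.0)
    return _ComModel(
        g=g,
        v_to=v_to,
        a1=a1,
        a2=a2,
        t_quiet=QUIET_T,
        t_unload=t1,
        t_push=t2,
        t_flight=2.0 * v_to / g,
        omega=LANDING_OMEGA,
    )


# ---------------------------------------------------------------------------
# EMG envelopes


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _preactivation_envelope(
    t: np.ndarray, onset_t: float, touchdown_t: float, amp: float
) -> np.ndarray:
    """Zero before ``onset_t``; smoothstep rise; plateau through landing."""
    env = np.zeros_like(t)
    rise = _smoothstep((t - onset_t) / BURST_RISE_S)
    hold_end = touchdown_t + POST_LAND_HOLD
    decay = 0.5 * (1.0 + np.cos(np.pi * np.clip((t - hold_end) / POST_LAND_DECAY, 0.0, 1.0)))
    env = amp * rise * np.where(t <= hold_end, 1.0, decay)
    env[t < onset_t] = 0.0
    return env


def _lift_envelope(t: np.ndarray, push_start: float, liftoff_t: float, amp: float) -> np.ndarray:
    """Raised-cosine push-off burst, exactly zero outside the push window."""
    width = liftoff_t - push_start
    tau = (t - push_start) / width
    env = amp * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(tau, 0.0, 1.0)))
    env[(tau < 0.0) | (tau > 1.0)] = 0.0
    return env


def _max_jump_envelope(t: np.ndarray, push_start: float, touchdown_t: float) -> np.ndarray:
    """Maximal-effort burst with a plateau long enough for the 100 ms
    sliding-window normalization to read the full amplitude."""
    rise = _smoothstep((t - push_start) / 0.05)
    plateau_end = push_start + 0.35
    decay = 0.5 * (1.0 + np.cos(np.pi * np.clip((t - plateau_end) / 0.1, 0.0, 1.0)))
    env = rise * np.where(t <= plateau_end, 1.0, decay)
    env = env + _preactivation_envelope(t, touchdown_t - 0.1, touchdown_t, 0.9)
    return np.minimum(env, 1.0)


def _carrier(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    x = rng.standard_normal(n)
    x = bandpass(x, fs, 20.0, min(450.0, 0.45 * fs))
    rms = np.sqrt(np.mean(x**2))
    return x / rms


# ---------------------------------------------------------------------------
# MTJ channels


def _probe_rotation() -> np.ndarray:
    d = INSERTION - KNEE
    e1 = d / np.linalg.norm(d)
    ref = np.array([1.0, 0.0, 0.0])
    n = ref - np.dot(ref, e1) * e1
    e2 = n / np.linalg.norm(n)
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def _mg_length(t: np.ndarray, com: _ComModel, l0: float, stretch_amp: float) -> np.ndarray:
    """MG length: shortening during push-off, stretch transient at landing."""
    t = np.asarray(t, dtype=float)
    push_start = com.t_quiet + com.t_unload
    shorten = 0.012 * _rc(
        np.clip(t - push_start, 0.0, com.t_push), com.t_push
    ) * ((t >= push_start) & (t <= com.t_liftoff))
    tau = np.clip(t - com.t_touchdown, 0.0, None)
    tp = 0.08
    stretch = stretch_amp * (tau / tp) * np.exp(1.0 - tau / tp) * (t >= com.t_touchdown)
    return l0 - shorten + stretch


def _make_mtj(com: _ComModel, l0: float, frame_rate: float, duration: float) -> MtjChannels:
    d = INSERTION - KNEE
    l_mtu = np.linalg.norm(d)
    e1 = d / l_mtu
    rot = _probe_rotation()
    e2 = rot[:, 1]
    # Probe origin placed so the MTJ stays inside the image.
    c0 = l0 - 0.032
    origin = KNEE + c0 * e1
    period = 1.0 / frame_rate
    n_frames = int(duration * frame_rate)
    frame_t = np.arange(n_frames) * period

    def pixel_u(t):
        l_mg = _mg_length(np.atleast_1d(t), com, l0, 0.02)
        return (l_mg - c0) / PX_SCALE

    # Rolling shutter: the MTJ column is captured at
    # frame_time + (u / width) * frame_period; fixed-point iterate.
    u = pixel_u(frame_t)
    for _ in range(3):
        capture_t = frame_t + (np.clip(u, 0, IMAGE_WIDTH) / IMAGE_WIDTH) * period
        u = pixel_u(capture_t)
    v = np.full_like(u, MTJ_PERP_OFFSET / PX_SCALE)
    ankle = KNEE + 0.93 * d + ANKLE_ARM * e2
    return MtjChannels(
        u_px=u,
        v_px=v,
        image_width=IMAGE_WIDTH,
        image_height=IMAGE_HEIGHT,
        frame_period=period,
        px_scale=PX_SCALE,
        probe_r=rot,
        probe_t=origin,
        knee=KNEE.copy(),
        insertion=INSERTION.copy(),
        ankle=ankle,
    )


# ---------------------------------------------------------------------------
# Trials


def generate_trial(
    participant: ParticipantParams,
    condition: str,
    seed: int,
    config: CohortConfig | None = None,
    jump_index: int = 0,
    max_jump: bool = False,
) -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic jump trial with its ground truth.

    ``condition`` is one of PRE/ADAPT/POST (or any key of
    ``config.effects``); ``max_jump`` produces a maximal-effort calibration
    trial at 1 g used for EMG normalization.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    if max_jump:
        g = config.effective_g["PRE"]
        onset_base, mag, bias = 100.0, 1.0, 0.0
        height = participant.max_jump_height
    else:
        if condition not in config.effects:
            raise ConfigError(f"unknown condition {condition!r}")
        g = participant.hypo_g if condition == "ADAPT" else config.effective_g[condition]
        onset_base, mag, bias = config.effects[condition].at_jump(jump_index)
        height = (
            participant.target_for(config)
            + bias
            + rng.normal(0.0, config.jump_height_sd)
        )
        height = max(height, 0.03)

    com = _solve_com(height, g)
    duration = com.t_touchdown + LANDING_TAIL
    mass = participant.body_mass
    bw = mass * g

    # GRF channel
    t_grf = np.arange(int(duration * config.fs_grf)) / config.fs_grf
    grf = mass * (com.accel(t_grf) + g)
    if config.grf_noise_sd > 0:
        grf = grf + rng.normal(0.0, config.grf_noise_sd, grf.size)
    grf = np.maximum(grf, -5.0)

    # Marker channel
    t_mk = np.arange(int(duration * config.fs_marker)) / config.fs_marker
    marker = participant.standing_height + com.displacement(t_mk)
    if config.marker_noise_sd > 0:
        marker = marker + rng.normal(0.0, config.marker_noise_sd, marker.size)

    # EMG channels
    t_emg = np.arange(int(duration * config.fs_emg)) / config.fs_emg
    push_start = com.t_quiet + com.t_unload
    onsets: dict[str, float] = {}
    amps: dict[str, float] = {}
    emg: dict[str, np.ndarray] = {}
    for muscle in MUSCLES:
        if max_jump:
            env = _max_jump_envelope(t_emg, push_start, com.t_touchdown)
            onset_ms = 100.0
            amp = 1.0
        else:
            onset_ms = onset_base + rng.normal(0.0, config.onset_jitter_ms)
            onset_ms = float(np.clip(onset_ms, 10.0, 150.0))
            amp = config.burst_amplitude * mag * rng.uniform(0.85, 1.15)
            onset_t = com.t_touchdown - onset_ms / 1000.0
            env = _preactivation_envelope(t_emg, onset_t, com.t_touchdown, amp)
            env = env + _lift_envelope(t_emg, push_start, com.t_liftoff, LIFT_BURST_AMP)
        carrier = _carrier(rng, t_emg.size, config.fs_emg)
        sig = env * carrier
        if config.emg_noise_sd > 0:
            sig = sig + config.emg_noise_sd * _carrier(rng, t_emg.size, config.fs_emg)
        emg[muscle] = participant.emg_gain_v[muscle] * sig
        onsets[muscle] = onset_ms
        amps[muscle] = amp

    mtj = None
    torque = None
    true_l = None
    if config.include_mtj:
        mtj = _make_mtj(com, participant.l0_mg, config.mtj_frame_rate, duration)
        grf_clean = mass * (com.accel(t_mk) + g)
        torque = np.maximum(grf_clean, 0.0) * ANKLE_LEVER
        true_l = _mg_length(t_mk, com, participant.l0_mg, 0.02)

    trial = TrialRecording(
        grf_z=grf,
        fs_grf=config.fs_grf,
        emg=emg,
        fs_emg=config.fs_emg,
        marker_z=marker,
        fs_marker=config.fs_marker,
        body_weight=bw,
        condition="MAX" if max_jump else condition,
        participant_id=participant.participant_id,
        jump_index=jump_index,
        mtj=mtj,
        ankle_torque=torque,
        is_max_jump=max_jump,
    )
    truth = GroundTruth(
        true_onset_ms=onsets,
        true_burst_amplitude=amps,
        true_liftoff=com.t_liftoff,
        true_touchdown=com.t_touchdown,
        true_jump_height=height,
        true_effective_g=g,
        v_takeoff=com.v_to,
        movement_start=com.t_quiet,
        target_height=participant.target_for(config),
        true_muscle_length=true_l,
        l0_mg=participant.l0_mg,
    )
    return trial, truth


def draw_participants(config: CohortConfig) -> list[ParticipantParams]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0F0]))
    out = []
    for i in range(config.n_participants):
        gains = {m: float(rng.lognormal(math.log(4e-4), 0.2)) for m in MUSCLES}
        out.append(
            ParticipantParams(
                participant_id=f"P{i + 1:02d}",
                body_mass=float(np.clip(rng.normal(config.body_mass_mean, config.body_mass_sd), 45, 110)),
                standing_height=float(rng.normal(config.standing_height_mean, config.standing_height_sd)),
                max_jump_height=float(
                    np.clip(rng.normal(config.max_jump_height_mean, config.max_jump_height_sd), 0.15, 0.6)
                ),
                hypo_g=float(
                    np.clip(
                        rng.normal(config.effective_g["ADAPT"], config.hypo_g_sd * 9.81),
                        0.3 * 9.81,
                        0.95 * 9.81,
                    )
                ),
                emg_gain_v=gains,
                l0_mg=float(rng.normal(0.26, 0.015)),
            )
        )
    return out


def trial_seed(config_seed: int, p_idx: int, cond: str, jump: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    tag = {"MAX": 0, "PRE": 1, "ADAPT": 2, "POST": 3}.get(cond, 9)
    ss = np.random.SeedSequence([config_seed, p_idx, tag, jump])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_cohort(config: CohortConfig, out_dir: str | Path | None = None) -> CohortDataset:
    """Generate the full cohort; optionally write trials + manifest to disk.

    Layout per participant: 3 maximal jumps (normalization), then the
    PRE/ADAPT/POST blocks with the configured jump counts.
    """
    participants = draw_participants(config)
    trials: list[TrialRecording] = []
    truths: list[GroundTruth] = []
    max_jumps: dict[str, list[TrialRecording]] = {}
    for p_idx, part in enumerate(participants):
        max_jumps[part.participant_id] = []
        for j in range(3):
            tr, _ = generate_trial(
                part, "PRE", trial_seed(config.seed, p_idx, "MAX", j), config, j, max_jump=True
            )
            max_jumps[part.participant_id].append(tr)
        for cond in CONDITIONS:
            for j in range(config.jumps_per_condition.get(cond, 0)):
                tr, gt = generate_trial(
                    part, cond, trial_seed(config.seed, p_idx, cond, j), config, j
                )
                trials.append(tr)
                truths.append(gt)
    ds = CohortDataset(
        config=config, participants=participants, trials=trials, truths=truths, max_jumps=max_jumps
    )
    if out_dir is not None:
        write_cohort(ds, out_dir)
    return ds


def write_cohort(ds: CohortDataset, out_dir: str | Path) -> Path:
    """Write one TSV per trial plus a JSON manifest carrying ground truth."""
    from . import io as hio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for pid, maxima in ds.max_jumps.items():
        for tr in maxima:
            name = f"{pid}_MAX_{tr.jump_index:02d}.tsv"
            hio.write_trial(tr, out / name)
            entries.append({"file": name, "participant": pid, "condition": "MAX",
                            "jump": tr.jump_index, "ground_truth": None})
    for tr, gt in zip(ds.trials, ds.truths):
        name = f"{tr.participant_id}_{tr.condition}_{tr.jump_index:02d}.tsv"
        hio.write_trial(tr, out / name)
        entries.append(
            {
                "file": name,
                "participant": tr.participant_id,
                "condition": tr.condition,
                "jump": tr.jump_index,
                "ground_truth": {
                    "true_onset_ms": gt.true_onset_ms,
                    "true_burst_amplitude": gt.true_burst_amplitude,
                    "true_liftoff": gt.true_liftoff,
                    "true_touchdown": gt.true_touchdown,
                    "true_jump_height": gt.true_jump_height,
                    "true_effective_g": gt.true_effective_g,
                    "v_takeoff": gt.v_takeoff,
                    "movement_start": gt.movement_start,
                    "target_height": gt.target_height,
                },
            }
        )
    manifest = {
        "n_participants": ds.config.n_participants,
        "seed": ds.config.seed,
        "trials": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out / "manifest.json"
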