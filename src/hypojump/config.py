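"""Cohort and trial configuration.

The defaults encode the study protocol this package emulates: 20
participants, 10 baseline (PRE) jumps at 1 g, 50 adaptation (ADAPT) jumps
at a simulated ~0.51 g produced by constant-force body-weight support, 10
post-adaptation (POST) jumps back at 1 g, jump target at 75% of maximal
countermovement-jump height, and triceps-surae EMG on both legs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

G_STANDARD = 9.81

CONDITIONS = ("PRE", "ADAPT", "POST")

MUSCLES = (
    "MG_dom",
    "LG_dom",
    "SOL_dom",
    "MG_nd",
    "LG_nd",
    "SOL_nd",
)


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass
class ConditionEffect:
    """Condition-specific ground truth injected into generated trials.

    onset_ms: preactivation onset, ms before touchdown, at the start of the
        block; decays toward ``onset_ms_final`` with time constant
        ``tau_jumps`` (in jumps) to emulate adaptation/washout curves.
    magnitude: normalized preactivation burst amplitude scale (1.0 = PRE).
    height_bias_m: initial target error bias in meters (decays likewise).
    """

    onset_ms: float = 100.0
    onset_ms_final: float | None = None
    magnitude: float = 1.0
    magnitude_final: float | None = None
    height_bias_m: float = 0.0
    tau_jumps: float = 5.0

    def at_jump(self, j: int) -> tuple[float, float, float]:
        decay = math.exp(-j / self.tau_jumps)
        onset_f = self.onset_ms if self.onset_ms_final is None else self.onset_ms_final
        mag_f = self.magnitude if self.magnitude_final is None else self.magnitude_final
        onset = onset_f + (self.onset_ms - onset_f) * decay
        mag = mag_f + (self.magnitude - mag_f) * decay
        bias = self.height_bias_m * decay
        return onset, mag, bias


def _default_effects() -> dict[str, ConditionEffect]:
    return {
        # Baseline: triceps-surae preactivation ~100 ms before landing.
        "PRE": ConditionEffect(onset_ms=100.0, magnitude=1.0),
        # Hypogravity: longer flight, reduced landing speed -> smaller bursts;
        # early jumps overshoot the target until adaptation.
        "ADAPT": ConditionEffect(onset_ms=100.0, magnitude=0.7, height_bias_m=0.05, tau_jumps=8.0),
        # Aftereffect: delayed (shorter pre-landing interval) and reduced
        # preactivation that washes out over the POST block.
        "POST": ConditionEffect(
            onset_ms=74.0,
            onset_ms_final=100.0,
            magnitude=0.6,
            magnitude_final=1.0,
            height_bias_m=-0.035,
            tau_jumps=5.0,
        ),
    }


@dataclass
class CohortConfig:
    n_participants: int = 20
    jumps_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"PRE": 10, "ADAPT": 50, "POST": 10}
    )
    # Effective gravity per condition (m/s^2). ADAPT draws per participant
    # from N(hypo_g_mean, hypo_g_sd) in units of g.
    effective_g: Mapping[str, float] = field(
        default_factory=lambda: {"PRE": G_STANDARD, "ADAPT": 0.51 * G_STANDARD, "POST": G_STANDARD}
    )
    hypo_g_sd: float = 0.06  # SD of the simulated gravity level, in g
    body_mass_mean: float = 70.0  # kg
    body_mass_sd: float = 10.0
    standing_height_mean: float = 1.44  # sternal-notch marker height, m
    standing_height_sd: float = 0.05
    max_jump_height_mean: float = 0.364  # m; 75% target -> ~0.273 m
    max_jump_height_sd: float = 0.04
    target_height_frac: float = 0.75
    jump_height_sd: float = 0.015  # per-jump motor variability, m
    onset_jitter_ms: float = 3.0  # per-muscle onset jitter
    effects: Mapping[str, ConditionEffect] = field(default_factory=_default_effects)
    emg_noise_sd: float = 0.01  # normalized units (fraction of max-jump burst)
    grf_noise_sd: float = 1.0  # N
    marker_noise_sd: float = 0.0  # m
    fs_grf: float = 1000.0
    fs_emg: float = 2000.0
    fs_marker: float = 200.0
    mtj_frame_rate: float = 60.0
    include_mtj: bool = True
    burst_amplitude: float = 0.3  # PRE preactivation amplitude, normalized
    seed: int = 0

    def __post_init__(self) -> None:
        self.effects = {
            cond: eff if isinstance(eff, ConditionEffect) else ConditionEffect(**eff)
            for cond, eff in self.effects.items()
        }
        for cond, g in self.effective_g.items():
            if not (0.0 < g <= G_STANDARD):
                raise ConfigError(f"effective_g[{cond}]={g} outside (0, 9.81]")
        if not (0.0 < self.target_height_frac <= 1.0):
            raise ConfigError("target_height_frac must be in (0, 1]")
        if min(self.fs_grf, self.fs_emg, self.fs_marker) <= 0:
            raise ConfigError("sample rates must be positive")
        for cond, eff in self.effects.items():
            if eff.magnitude < 0:
                raise ConfigError(f"magnitude_scale[{cond}] must be >= 0")
        if self.max_jump_height_mean <= 0:
            raise ConfigError("max jump height must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        return cls(**dict(raw))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ParticipantParams:
    """Per-participant anthropometrics and gains drawn once per cohort."""

    participant_id: str
    body_mass: float  # kg
    standing_height: float  # m
    max_jump_height: float  # m, at 1 g
    hypo_g: float  # m/s^2, the participant's simulated gravity
    emg_gain_v: Mapping[str, float]  # volts per unit normalized envelope
    l0_mg: float = 0.26  # resting MG length, m

    @property
    def target_height(self) -> float:
        return 0.75 * self.max_jump_height

    def target_for(self, config: CohortConfig) -> float:
        return config.target_height_frac * self.max_jump_height
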