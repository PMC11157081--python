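"""End-to-end analysis: trials -> kinetics -> EMG -> fascicle -> statistics.

The canonical run generates (or loads) a cohort, analyzes every jump,
assembles tidy per-jump metrics, compares each probe timepoint against
baseline with the gated scalar battery, runs the wavelet functional test on
phase waveforms, and summarizes aftereffects as POST minus PRE averaged
across participants.

Probe jumps default to: baseline = last PRE jump, Early Adaptation = first
ADAPT jump, Late Adaptation = last ADAPT jump, POST = first POST jump,
Washout = last POST jump.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import fascicle as fas
from . import kinetics as kin
from . import scalar_stats as sstats
from . import wavestats
from .config import MUSCLES, CohortConfig
from .filters import lowpass, sliding_average
from .synth import CohortDataset, TrialRecording, generate_cohort

log = logging.getLogger("hypojump")

SCALAR_METRICS = (
    "jump_height",
    "abs_target_error",
    "lift_impulse",
    "land_impulse",
    "onset_MG_dom",
    "magnitude_MG_dom",
    "tsp_dom",
)

TIMEPOINTS = {
    "Early Adaptation": ("ADAPT", "first"),
    "Late Adaptation": ("ADAPT", "last"),
    "POST": ("POST", "first"),
    "Washout": ("POST", "last"),
}


@dataclass
class TrialAnalysis:
    participant: str
    condition: str
    jump: int
    phases: kin.JumpPhases
    kinetics: kin.JumpKinetics
    preactivation: dict[str, emg_mod.PreactivationResult]
    tsp: dict[str, float | None]  # per leg
    muscle_state: fas.MuscleState | None = None
    rectified_norm: dict[str, np.ndarray] = field(default_factory=dict)


def normalization_peaks(
    max_jump_trials: list[TrialRecording],
) -> dict[str, float]:
    """Per-muscle normalization peaks from a participant's maximal jumps."""
    peaks = {}
    for muscle in MUSCLES:
        rectified = [
            emg_mod.preprocess(tr.emg[muscle], tr.fs_emg) for tr in max_jump_trials
        ]
        peaks[muscle] = emg_mod.normalization_peak(rectified, max_jump_trials[0].fs_emg)
    return peaks


def analyze_trial(
    trial: TrialRecording,
    norm_peaks: dict[str, float],
    target_height: float,
    keep_waveforms: bool = False,
) -> TrialAnalysis:
    """Full single-trial analysis chain."""
    # Segmentation runs on the raw GRF: zero-phase smoothing of the
    # near-impulsive landing spike would drag the 25 N touchdown crossing
    # tens of ms early, corrupting every landing-referenced time.
    marker_f = lowpass(trial.marker_z, trial.fs_marker, 25.0)
    phases = kin.segment_phases(trial.grf_z, trial.body_weight, trial.fs_grf)
    lift_imp, land_imp = kin.compute_impulses(trial.grf_z, phases, trial.fs_grf)
    standing = float(np.mean(marker_f[: int(0.3 * trial.fs_marker)]))
    height, err = kin.jump_metrics(marker_f, trial.fs_marker, phases, standing, target_height)
    g_est = kin.aerial_acceleration(marker_f, trial.fs_marker, phases)
    kinetics = kin.JumpKinetics(lift_imp, land_imp, height, err, abs(err), g_est)

    lo_e = int(round(phases.liftoff_t * trial.fs_emg))
    td_e = int(round(phases.touchdown_t * trial.fs_emg))
    pre: dict[str, emg_mod.PreactivationResult] = {}
    rect_norm: dict[str, np.ndarray] = {}
    for muscle, raw in trial.emg.items():
        rn = emg_mod.preprocess(raw, trial.fs_emg) / norm_peaks[muscle]
        pre[muscle] = emg_mod.detect_onset(rn, trial.fs_emg, (lo_e, td_e))
        rect_norm[muscle] = rn

    tsp = {}
    for leg, suffix in (("dom", "_dom"), ("nd", "_nd")):
        iemgs = {
            m: (pre[m].iemg if pre[m].included else None)
            for m in MUSCLES
            if m.endswith(suffix)
        }
        tsp[leg], _ = emg_mod.triceps_surae_preactivity(iemgs)

    state = None
    if trial.mtj is not None:
        state = _fascicle_chain(trial, rect_norm, phases)

    out = TrialAnalysis(
        participant=trial.participant_id,
        condition=trial.condition,
        jump=trial.jump_index,
        phases=phases,
        kinetics=kinetics,
        preactivation=pre,
        tsp=tsp,
        muscle_state=state,
    )
    if keep_waveforms:
        out.rectified_norm = rect_norm
    return out


def _fascicle_chain(
    trial: TrialRecording,
    rect_norm: dict[str, np.ndarray],
    phases: kin.JumpPhases,
) -> fas.MuscleState:
    m = trial.mtj
    offsets = fas.rolling_shutter_offsets(m.u_px, m.image_width, m.frame_period)
    times = m.frame_times + offsets
    pts = fas.pixels_to_lab(m.u_px, m.v_px, m.px_scale, m.probe_r, m.probe_t)
    l_mg, l_tendon, l_mtu, out_flags = fas.project_mtj(pts, m.knee, m.insertion)

    t_kin = np.arange(trial.marker_z.size) / trial.fs_marker
    l_interp = fas.interpolate_track(times, l_mg, t_kin)
    l_filt, v_mg = fas.lengths_and_velocity(l_interp, trial.fs_marker)
    l_tendon_i = fas.interpolate_track(times, l_tendon, t_kin)

    # Resting MG length from quiet standing at the start of the trial.
    l0 = float(np.mean(l_filt[: int(0.3 * trial.fs_marker)]))

    activation = sliding_average(rect_norm["MG_dom"], trial.fs_emg, 0.1)
    t_emg = np.arange(activation.size) / trial.fs_emg
    u = np.clip(np.interp(t_kin, t_emg, activation), 0.0, 1.0)

    f_mg = None
    if trial.ankle_torque is not None:
        arm = fas.moment_arm(m.ankle, m.knee, m.insertion)
        f_mg, _ = fas.muscle_force(trial.ankle_torque[: t_kin.size], arm)
    r_ia = fas.ia_rate(v_mg, l_filt, l0, u)
    return fas.MuscleState(
        t=t_kin,
        l_mg=l_filt,
        l_tendon=l_tendon_i,
        l_mtu=np.full_like(l_filt, float(np.atleast_1d(l_mtu)[0])),
        v_mg=v_mg,
        l0=l0,
        f_mg=f_mg,
        activation=u,
        r_ia=r_ia,
        out_of_segment=out_flags,
    )


def tidy_metrics(analyses: list[TrialAnalysis]) -> pd.DataFrame:
    """Long-format per-jump metric table."""
    rows = []

    def add(a: TrialAnalysis, metric: str, value) -> None:
        rows.append(
            {
                "participant": a.participant,
                "condition": a.condition,
                "jump": a.jump,
                "metric": metric,
                "value": value,
            }
        )

    for a in analyses:
        k = a.kinetics
        add(a, "jump_height", k.jump_height)
        add(a, "target_error", k.target_error)
        add(a, "abs_target_error", k.abs_target_error)
        add(a, "lift_impulse", k.lift_impulse)
        add(a, "land_impulse", k.land_impulse)
        add(a, "aerial_g", k.aerial_g_estimate)
        for muscle, res in a.preactivation.items():
            if res.included:
                add(a, f"onset_{muscle}", res.onset_ms_before_landing)
                add(a, f"magnitude_{muscle}", res.magnitude)
                add(a, f"iemg_{muscle}", res.iemg)
            else:
                add(a, f"excluded_{muscle}", res.exclusion_rule.value)
        for leg, v in a.tsp.items():
            if v is not None:
                add(a, f"tsp_{leg}", v)
    return pd.DataFrame(rows)


def _probe_value(df: pd.DataFrame, metric: str, condition: str, which: str) -> pd.Series:
    sub = df[(df.metric == metric) & (df.condition == condition)].copy()
    sub = sub[pd.to_numeric(sub["value"], errors="coerce").notna()]
    sub["value"] = sub["value"].astype(float)
    idx = sub.groupby("participant")["jump"]
    pick = idx.transform("min" if which == "first" else "max")
    sel = sub[sub.jump == pick]
    return sel.set_index("participant")["value"]


def comparison_battery(
    df: pd.DataFrame, metrics: tuple[str, ...] = SCALAR_METRICS
) -> pd.DataFrame:
    """Tables-style battery: each timepoint's probe jump vs the baseline PRE
    jump, per metric, across participants."""
    out = []
    for metric in metrics:
        base = _probe_value(df, metric, "PRE", "last")
        for tp, (cond, which) in TIMEPOINTS.items():
            probe = _probe_value(df, metric, cond, which)
            joint = pd.concat([base, probe], axis=1, keys=["pre", "probe"]).dropna()
            if len(joint) < 3:
                continue
            cmp = sstats.paired_compare(
                joint["pre"].to_numpy(), joint["probe"].to_numpy(), metric=metric, timepoint=tp
            )
            out.append(
                {
                    "metric": metric,
                    "timepoint": tp,
                    "n": cmp.n,
                    "test": cmp.test_used,
                    "df": cmp.df,
                    "statistic": cmp.statistic,
                    "z": cmp.z,
                    "p": cmp.p,
                    "g_av": cmp.g_av,
                }
            )
    return pd.DataFrame(out)


def aftereffect_summary(df: pd.DataFrame, metrics: tuple[str, ...] = SCALAR_METRICS) -> pd.DataFrame:
    """POST minus PRE per participant (probe jumps), averaged across the
    cohort, with per-participant values retained in long form."""
    rows = []
    for metric in metrics:
        base = _probe_value(df, metric, "PRE", "last")
        post = _probe_value(df, metric, "POST", "first")
        joint = pd.concat([base, post], axis=1, keys=["pre", "post"]).dropna()
        delta = joint["post"] - joint["pre"]
        for pid, v in delta.items():
            rows.append({"metric": metric, "participant": pid, "delta": v})
        rows.append({"metric": metric, "participant": "MEAN", "delta": float(delta.mean())})
    return pd.DataFrame(rows)


def phase_waveform(
    trial: TrialRecording, analysis: TrialAnalysis, phase: str, n_points: int | None = None
) -> np.ndarray:
    """Time-normalized waveform of one jump phase.

    lift/land: GRFz in units of body weight (64 points); aerial: dominant-MG
    normalized EMG envelope (34 points).
    """
    ph = analysis.phases
    n_points = n_points or wavestats.PHASE_POINTS[phase]
    if phase == "lift":
        seg = trial.grf_z[ph.lift_start : ph.liftoff + 1] / trial.body_weight
    elif phase == "land":
        seg = trial.grf_z[ph.touchdown : ph.land_end + 1] / trial.body_weight
    elif phase == "aerial":
        rn = analysis.rectified_norm.get("MG_dom")
        if rn is None:
            raise ValueError("aerial waveform requires keep_waveforms=True")
        lo = int(round(ph.liftoff_t * trial.fs_emg))
        td = int(round(ph.touchdown_t * trial.fs_emg))
        seg = sliding_average(rn[lo : td + 1], trial.fs_emg, 0.02)
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return wavestats.time_normalize(seg, n_points)


def functional_battery(
    ds: CohortDataset, analyses: list[TrialAnalysis], phases: tuple[str, ...] = ("lift", "land")
) -> dict[str, wavestats.FunctionalTestResult]:
    """PRE vs POST wavelet functional test per phase, on per-participant
    mean waveforms."""
    trials_by_key: dict[tuple[str, str], list[tuple[TrialRecording, TrialAnalysis]]] = {}
    for tr, an in zip(ds.trials, analyses):
        trials_by_key.setdefault((an.participant, an.condition), []).append((tr, an))

    results = {}
    for phase in phases:
        pre_rows, post_rows = [], []
        for part in ds.participants:
            rows = {}
            for cond in ("PRE", "POST"):
                items = trials_by_key.get((part.participant_id, cond), [])
                wfs = [phase_waveform(tr, an, phase) for tr, an in items]
                if wfs:
                    rows[cond] = np.mean(wfs, axis=0)
            if "PRE" in rows and "POST" in rows:
                pre_rows.append(rows["PRE"])
                post_rows.append(rows["POST"])
        if len(pre_rows) >= 3:
            results[phase] = wavestats.wavelet_paired_test(
                np.array(pre_rows), np.array(post_rows)
            )
    return results


def exclusion_log(analyses: list[TrialAnalysis]) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for a in analyses:
        for res in a.preactivation.values():
            counts[res.exclusion_rule.value] += 1
    return dict(counts)


def run_all(
    config: CohortConfig,
    out_dir: str | Path,
    write_trials: bool = False,
    functional_phases: tuple[str, ...] = ("lift", "land"),
) -> dict:
    """Execute the full chain and write all outputs; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("generating cohort: %d participants", config.n_participants)
    ds = generate_cohort(config, out_dir=out / "trials" if write_trials else None)

    analyses = []
    targets = {p.participant_id: p.target_for(config) for p in ds.participants}
    peaks = {
        pid: normalization_peaks(trs) for pid, trs in ds.max_jumps.items()
    }
    for tr in ds.trials:
        try:
            analyses.append(
                analyze_trial(tr, peaks[tr.participant_id], targets[tr.participant_id])
            )
        except (kin.NoAerialPhaseError, kin.DegenerateTrialError) as exc:
            raise RuntimeError(
                f"kinetics stage failed on {tr.participant_id}/{tr.condition}/{tr.jump_index}: {exc}"
            ) from exc

    df = tidy_metrics(analyses)
    df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    comparisons = comparison_battery(df)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    aftereffects = aftereffect_summary(df)
    aftereffects.to_csv(out / "aftereffects.tsv", sep="\t", index=False)

    func = functional_battery(ds, analyses, phases=functional_phases)
    for phase, res in func.items():
        pd.DataFrame({"contrast": res.contrast, "significant": res.mask}).to_csv(
            out / f"functional_{phase}.tsv", sep="\t", index=False
        )
        res.coeff_table.to_json(out / f"functional_{phase}_coeffs.json", orient="records")

    manifest = {
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "n_trials": len(ds.trials),
        "exclusions": exclusion_log(analyses),
        "outputs": sorted(p.name for p in out.glob("*.tsv")),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    log.info("exclusions by rule: %s", manifest["exclusions"])
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
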