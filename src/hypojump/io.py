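"""Trial file I/O.

One delimited-text (TSV) file per trial: a column per channel, channels of
different sample rates padded to the longest with empty cells. Channel
metadata (unit, sample rate) and trial-level metadata (body weight,
condition, probe geometry) live in ``#``-prefixed header lines, so the file
is self-describing and loads with plain pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import MUSCLES
from .synth import MtjChannels, TrialRecording


def write_trial(trial: TrialRecording, path: str | Path) -> None:
    cols: dict[str, np.ndarray] = {"grf_z": trial.grf_z, "marker_z": trial.marker_z}
    channel_meta = {
        "grf_z": {"unit": "N", "fs": trial.fs_grf},
        "marker_z": {"unit": "m", "fs": trial.fs_marker},
    }
    for muscle, sig in trial.emg.items():
        name = f"emg_{muscle}"
        cols[name] = sig
        channel_meta[name] = {"unit": "V", "fs": trial.fs_emg}
    if trial.mtj is not None:
        cols["mtj_u"] = trial.mtj.u_px
        cols["mtj_v"] = trial.mtj.v_px
        fs_mtj = 1.0 / trial.mtj.frame_period
        channel_meta["mtj_u"] = {"unit": "px", "fs": fs_mtj}
        channel_meta["mtj_v"] = {"unit": "px", "fs": fs_mtj}
    if trial.ankle_torque is not None:
        cols["ankle_torque"] = trial.ankle_torque
        channel_meta["ankle_torque"] = {"unit": "N.m", "fs": trial.fs_marker}

    meta = {
        "body_weight": trial.body_weight,
        "condition": trial.condition,
        "participant_id": trial.participant_id,
        "jump_index": trial.jump_index,
        "is_max_jump": trial.is_max_jump,
    }
    if trial.mtj is not None:
        m = trial.mtj
        meta["mtj"] = {
            "image_width": m.image_width,
            "image_height": m.image_height,
            "frame_period": m.frame_period,
            "px_scale": m.px_scale,
            "probe_r": np.asarray(m.probe_r).tolist(),
            "probe_t": np.asarray(m.probe_t).tolist(),
            "knee": np.asarray(m.knee).tolist(),
            "insertion": np.asarray(m.insertion).tolist(),
            "ankle": np.asarray(m.ankle).tolist(),
        }

    n = max(v.size for v in cols.values())
    frame = pd.DataFrame(
        {k: np.concatenate([v, np.full(n - v.size, np.nan)]) for k, v in cols.items()}
    )
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# meta={json.dumps(meta)}\n")
        for name, cm in channel_meta.items():
            fh.write(f"# channel={name} unit={cm['unit']} fs={cm['fs']:g}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="", float_format="%.9g")


def read_trial(path: str | Path) -> TrialRecording:
    path = Path(path)
    meta: dict = {}
    channel_meta: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if body.startswith("meta="):
                meta = json.loads(body[len("meta=") :])
            elif body.startswith("channel="):
                parts = dict(p.split("=", 1) for p in body.split())
                channel_meta[parts["channel"]] = {
                    "unit": parts["unit"],
                    "fs": float(parts["fs"]),
                }
    frame = pd.read_csv(path, sep="\t", comment="#")

    def col(name: str) -> np.ndarray:
        return frame[name].dropna().to_numpy(dtype=float)

    emg = {m: col(f"emg_{m}") for m in MUSCLES if f"emg_{m}" in frame.columns}
    mtj = None
    if "mtj" in meta:
        mm = meta["mtj"]
        mtj = MtjChannels(
            u_px=col("mtj_u"),
            v_px=col("mtj_v"),
            image_width=int(mm["image_width"]),
            image_height=int(mm["image_height"]),
            frame_period=float(mm["frame_period"]),
            px_scale=float(mm["px_scale"]),
            probe_r=np.array(mm["probe_r"]),
            probe_t=np.array(mm["probe_t"]),
            knee=np.array(mm["knee"]),
            insertion=np.array(mm["insertion"]),
            ankle=np.array(mm["ankle"]),
        )
    emg_fs = next(
        (cm["fs"] for name, cm in channel_meta.items() if name.startswith("emg_")), 0.0
    )
    return TrialRecording(
        grf_z=col("grf_z"),
        fs_grf=channel_meta["grf_z"]["fs"],
        emg=emg,
        fs_emg=emg_fs,
        marker_z=col("marker_z"),
        fs_marker=channel_meta["marker_z"]["fs"],
        body_weight=float(meta["body_weight"]),
        condition=meta["condition"],
        participant_id=meta["participant_id"],
        jump_index=int(meta["jump_index"]),
        mtj=mtj,
        ankle_torque=col("ankle_torque") if "ankle_torque" in frame.columns else None,
        is_max_jump=bool(meta.get("is_max_jump", False)),
    )
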