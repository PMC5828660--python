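"""Session serialization.

A session directory holds ``session.json`` (metadata, trial table, optional
ground-truth block) and ``traces.h5`` (the voltage array and time grid in an
HDF5 container).  Round trips are lossless: arrays are stored float64.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import (AcquisitionSpec, GroundTruthElectrode, RFMappingSession,
                    SpeechSession, StimulusSchedule)


def _truth_meta(truth: list[GroundTruthElectrode]) -> list[dict]:
    out = []
    for el in truth:
        d = asdict(el)
        d.pop("condition_envelopes")
        d["has_envelopes"] = el.condition_envelopes is not None
        out.append(d)
    return out


def _truth_from_meta(meta: list[dict], env_store: dict) -> list[GroundTruthElectrode]:
    truth = []
    for d in meta:
        has_env = d.pop("has_envelopes")
        if d.get("rf_center") is not None:
            d["rf_center"] = tuple(d["rf_center"])
        if d.get("rf_sigma") is not None:
            d["rf_sigma"] = tuple(d["rf_sigma"])
        envs = env_store.get(d["name"]) if has_env else None
        truth.append(GroundTruthElectrode(condition_envelopes=envs, **d))
    return truth


def save_session(session: RFMappingSession | SpeechSession,
                 directory: str | Path) -> Path:
    """Write a session to ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    meta: dict = {
        "kind": session.kind,
        "seed": int(session.seed),
        "electrodes": list(session.electrodes),
        "acq": asdict(session.acq),
        "trials": session.trials.to_dict(orient="list"),
    }
    if session.kind == "rf":
        meta["grid"] = np.asarray(session.grid).tolist()
    else:
        meta["schedule"] = asdict(session.schedule)
        meta["regions"] = list(session.regions)
    if session.truth is not None:
        meta["truth"] = _truth_meta(session.truth)

    with h5py.File(directory / "traces.h5", "w") as h5:
        h5.create_dataset("traces", data=session.traces)
        h5.create_dataset("time_ms", data=session.time_ms)
        if session.truth is not None:
            grp = h5.create_group("truth_envelopes")
            for el in session.truth:
                if el.condition_envelopes is None:
                    continue
                sub = grp.create_group(el.name)
                for cond, env in el.condition_envelopes.items():
                    sub.create_dataset(cond, data=np.asarray(env, float))

    (directory / "session.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_session(directory: str | Path) -> RFMappingSession | SpeechSession:
    """Read a session previously written by :func:`save_session`."""
    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())

    with h5py.File(directory / "traces.h5", "r") as h5:
        traces = h5["traces"][()]
        time_ms = h5["time_ms"][()]
        env_store: dict[str, dict[str, np.ndarray]] = {}
        if "truth_envelopes" in h5:
            for name, sub in h5["truth_envelopes"].items():
                env_store[name] = {cond: sub[cond][()] for cond in sub}

    acq_d = meta["acq"]
    for key in ("line_freqs", "line_amplitudes"):
        acq_d[key] = tuple(acq_d[key])
    acq = AcquisitionSpec(**acq_d)
    trials = pd.DataFrame(meta["trials"])
    truth = (_truth_from_meta(meta["truth"], env_store)
             if "truth" in meta else None)

    if meta["kind"] == "rf":
        return RFMappingSession(acq=acq, grid=np.asarray(meta["grid"], float),
                                trials=trials, traces=traces, time_ms=time_ms,
                                electrodes=meta["electrodes"],
                                seed=meta["seed"], truth=truth)
    sched_d = meta["schedule"]
    for key in ("words", "mouth_move_onset_ms", "auditory_onset_ms",
                "vocal_duration_ms", "trial_duration_ms"):
        sched_d[key] = tuple(sched_d[key])
    schedule = StimulusSchedule(**sched_d)
    return SpeechSession(acq=acq, schedule=schedule, trials=trials,
                         traces=traces, time_ms=time_ms,
                         electrodes=meta["electrodes"],
                         regions=meta["regions"], seed=meta["seed"],
                         truth=truth)
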