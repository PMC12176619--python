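"""CSV/JSON serialization of sessions and results.

Formats: spikes as long-format CSV (unit_id, time_s); events as CSV
(stream, time_s, port) with stream in {cue, reward, entry, bout_on,
bout_off, injection} plus a JSON epochs sidecar; unit metadata as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Epoch, EventLog, UnitMeta


def write_spikes_csv(path, spike_times: list[np.ndarray]) -> None:
    rows = [
        pd.DataFrame({"unit_id": u, "time_s": np.round(t, 6)})
        for u, t in enumerate(spike_times)
    ]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_spikes_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    n = int(df["unit_id"].max()) + 1 if len(df) else 0
    return [df.loc[df["unit_id"] == u, "time_s"].to_numpy() for u in range(n)]


def write_events(path_csv, path_epochs_json, events: EventLog) -> None:
    rows = []
    for t, p in zip(events.cue_times, events.cue_ports):
        rows.append(("cue", t, p))
    for t, p in zip(events.reward_times, events.reward_ports):
        rows.append(("reward", t, p))
    for t, p in zip(events.entry_times, events.entry_ports):
        rows.append(("entry", t, p))
    for on, off in events.stim_bouts:
        rows.append(("bout_on", on, ""))
        rows.append(("bout_off", off, ""))
    if events.injection_time is not None:
        rows.append(("injection", events.injection_time, ""))
    pd.DataFrame(rows, columns=["stream", "time_s", "port"]).to_csv(
        path_csv, index=False, float_format="%.6f"
    )
    epochs = {
        lbl: {"start": ep.start, "end": ep.end} for lbl, ep in events.epochs.items()
    }
    Path(path_epochs_json).write_text(json.dumps(epochs, indent=1, sort_keys=True))


def read_events(path_csv, path_epochs_json) -> EventLog:
    df = pd.read_csv(path_csv, keep_default_na=False)
    epochs_raw = json.loads(Path(path_epochs_json).read_text())
    epochs = {lbl: Epoch(lbl, d["start"], d["end"]) for lbl, d in epochs_raw.items()}

    def stream(name):
        sub = df[df["stream"] == name]
        return sub["time_s"].to_numpy(), sub["port"].to_numpy(dtype=object)

    cue_t, cue_p = stream("cue")
    rew_t, rew_p = stream("reward")
    ent_t, ent_p = stream("entry")
    on_t, _ = stream("bout_on")
    off_t, _ = stream("bout_off")
    inj_t, _ = stream("injection")
    log = EventLog(
        cue_times=cue_t,
        cue_ports=cue_p,
        reward_times=rew_t,
        reward_ports=rew_p,
        entry_times=ent_t,
        entry_ports=ent_p,
        stim_bouts=np.column_stack([on_t, off_t]) if on_t.size else np.empty((0, 2)),
        epochs=epochs,
        injection_time=float(inj_t[0]) if inj_t.size else None,
    )
    log.validate()
    return log


def write_unit_meta_csv(path, meta: list[UnitMeta]) -> None:
    pd.DataFrame(
        {
            "unit_id": [m.unit_id for m in meta],
            "median_amplitude_uv": [m.median_amplitude for m in meta],
            "fp_rate": [m.fp_rate for m in meta],
            "firing_rate": [m.firing_rate for m in meta],
            "label": [m.curation_label for m in meta],
            "region": [m.region_label for m in meta],
        }
    ).to_csv(path, index=False)


def read_unit_meta_csv(path) -> list[UnitMeta]:
    df = pd.read_csv(path)
    return [
        UnitMeta(
            unit_id=int(r.unit_id),
            median_amplitude=float(r.median_amplitude_uv),
            fp_rate=float(r.fp_rate),
            firing_rate=float(r.firing_rate),
            curation_label=str(r.label),
            region_label=str(r.region),
        )
        for r in df.itertuples()
    ]


def write_labels_csv(path, labels) -> None:
    pd.DataFrame(
        {
            "unit_id": np.arange(labels.labels.size),
            "label": labels.labels,
            "p": labels.pvalue,
            "stat": labels.statistic,
            "mean_flavour": labels.mean_flavour,
            "mean_water": labels.mean_water,
            "rejected": labels.rejected.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.8g")


def write_photometry_csv(path, trace) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "iso405": trace.iso405, "act488": trace.act488}
    ).to_csv(path, index=False, float_format="%.6f")


def read_photometry_csv(path, fs: float):
    from .simulate import PhotometryTrace

    df = pd.read_csv(path)
    return PhotometryTrace(
        time=df["time_s"].to_numpy(),
        iso405=df["iso405"].to_numpy(),
        act488=df["act488"].to_numpy(),
        fs=fs,
    )
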