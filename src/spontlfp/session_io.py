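"""HDF5 session container and CSV side tables.

Layout of a session file:

    /lfp                  channels x samples, float32; attrs: fs
    /meta/nucleus         per-channel nucleus labels (UTF-8)
    /events/*             stimulus table columns (onset_s, duration_s,
                          modality, block_index, within_block_index)
    /spikes/unit###       optional per-unit spike times (s)
    /ibi/beat_times       optional heartbeat times (s)
    root attrs            ground-truth parameters as a JSON string

Events and heartbeat tables can additionally be exported as plain CSV.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .autonomic import IBISeries
from .protocol import BlockProtocol
from .simulate import SessionRecording


def save_session(session: SessionRecording, path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("lfp", data=session.lfp.astype(np.float32))
        d.attrs["fs"] = session.fs
        f.create_dataset("meta/nucleus",
                         data=np.array(session.nucleus_of_channel, dtype="S32"))
        ev = session.protocol.to_frame()
        g = f.create_group("events")
        for col in ev.columns:
            data = ev[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S32")
            g.create_dataset(col, data=data)
        if session.spikes is not None:
            sg = f.create_group("spikes")
            for i, train in enumerate(session.spikes):
                sg.create_dataset(f"unit{i:03d}", data=np.asarray(train, dtype=float))
        if session.heartbeats is not None:
            f.create_dataset("ibi/beat_times", data=session.heartbeats.beat_times)
        f.attrs["ground_truth"] = json.dumps(session.ground_truth)


def load_session(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        lfp = f["lfp"][...]
        fs = float(f["lfp"].attrs["fs"])
        nucleus = [s.decode() for s in f["meta/nucleus"][...]]
        ev = {}
        for col in f["events"]:
            data = f["events"][col][...]
            if data.dtype.kind == "S":
                data = np.array([s.decode() for s in data])
            ev[col] = data
        protocol = BlockProtocol.from_frame(pd.DataFrame(ev))
        spikes = None
        if "spikes" in f:
            spikes = [f["spikes"][k][...] for k in sorted(f["spikes"])]
        heartbeats = None
        if "ibi" in f:
            heartbeats = IBISeries.from_beats(f["ibi/beat_times"][...])
        gt = json.loads(f.attrs.get("ground_truth", "{}"))
    return SessionRecording(lfp=lfp, fs=fs, nucleus_of_channel=nucleus,
                            protocol=protocol, spikes=spikes,
                            heartbeats=heartbeats, ground_truth=gt)


def export_events_csv(session: SessionRecording, path) -> None:
    session.protocol.to_frame().to_csv(path, index=False)


def export_ibi_csv(ibi: IBISeries, path) -> None:
    ibi.to_frame().to_csv(path, index=False)


def load_ibi_csv(path) -> IBISeries:
    df = pd.read_csv(path)
    return IBISeries.from_beats(df["beat_time_s"].to_numpy())
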