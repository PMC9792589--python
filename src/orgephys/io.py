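"""On-disk formats: HDF5 recording bundles and event-train CSV files.

HDF5 bundle layout::

    /data                float32, (n_channels, n_samples), µV
    /fs_hz               float64 scalar
    /channels            compound table: channel_id, row, col, x_um, y_um,
                         region (int: 0=organoid, 1=cortex, 2=ambiguous),
                         impedance_ohm, included
    /stimulus/onsets_s   float64[]  (group absent when no stimulus)
        attrs: pulse_width_s, pulse_rate_hz, train_duration_s
    root attrs: state, provenance

Event CSV: header ``channel_id,time_s``, times printed with 6 decimals
(microsecond precision).
"""

from __future__ import annotations

import os
from typing import List, Sequence

import h5py
import numpy as np
import pandas as pd

from .data import ChannelInfo, EventTrain, Recording, Region, StimulusProtocol

__all__ = ["read_recording", "write_recording", "read_events", "write_events"]

_REGION_TO_INT = {Region.ORGANOID: 0, Region.CORTEX: 1, Region.AMBIGUOUS: 2}
_INT_TO_REGION = {v: k for k, v in _REGION_TO_INT.items()}

_CHANNEL_DTYPE = np.dtype(
    [
        ("channel_id", "<i8"),
        ("row", "<i8"),
        ("col", "<i8"),
        ("x_um", "<f8"),
        ("y_um", "<f8"),
        ("region", "<i8"),
        ("impedance_ohm", "<f8"),
        ("included", "<i8"),
    ]
)


class FormatError(ValueError):
    """Raised when a bundle on disk does not conform to the expected layout."""


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a :class:`Recording` as an HDF5 bundle (µV / seconds on disk)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=np.asarray(rec.data, dtype=np.float32))
        f.create_dataset("fs_hz", data=float(rec.fs_hz))
        table = np.zeros(len(rec.channels), dtype=_CHANNEL_DTYPE)
        for i, c in enumerate(rec.channels):
            table[i] = (
                c.channel_id,
                c.row,
                c.col,
                c.x_um,
                c.y_um,
                _REGION_TO_INT[c.region],
                c.impedance_ohm,
                int(c.included),
            )
        f.create_dataset("channels", data=table)
        if rec.stimulus is not None:
            g = f.create_group("stimulus")
            g.create_dataset("onsets_s", data=np.asarray(rec.stimulus.onsets_s, dtype=np.float64))
            g.attrs["pulse_width_s"] = float(rec.stimulus.pulse_width_s)
            g.attrs["pulse_rate_hz"] = float(rec.stimulus.pulse_rate_hz)
            g.attrs["train_duration_s"] = float(rec.stimulus.train_duration_s)
        f.attrs["state"] = rec.state
        f.attrs["provenance"] = rec.provenance


def read_recording(path: str | os.PathLike) -> Recording:
    """Read an HDF5 bundle written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        for name in ("data", "fs_hz", "channels"):
            if name not in f:
                raise FormatError(f"bundle is missing dataset /{name}")
        data = f["data"][()]
        if data.ndim != 2:
            raise FormatError("/data must be 2-D (channel x sample)")
        fs = float(f["fs_hz"][()])
        if fs <= 0:
            raise ValueError(f"invalid sampling rate {fs}")
        table = f["channels"][()]
        if table.shape[0] != data.shape[0]:
            raise FormatError(
                f"/data has {data.shape[0]} rows but /channels has {table.shape[0]} records"
            )
        channels = [
            ChannelInfo(
                channel_id=int(r["channel_id"]),
                row=int(r["row"]),
                col=int(r["col"]),
                x_um=float(r["x_um"]),
                y_um=float(r["y_um"]),
                region=_INT_TO_REGION[int(r["region"])],
                impedance_ohm=float(r["impedance_ohm"]),
                included=bool(r["included"]),
            )
            for r in table
        ]
        stimulus = None
        if "stimulus" in f:
            g = f["stimulus"]
            if "onsets_s" not in g:
                raise FormatError("bundle /stimulus group is missing onsets_s")
            stimulus = StimulusProtocol(
                onsets_s=g["onsets_s"][()],
                pulse_width_s=float(g.attrs["pulse_width_s"]),
                pulse_rate_hz=float(g.attrs["pulse_rate_hz"]),
                train_duration_s=float(g.attrs["train_duration_s"]),
            )
        state = str(f.attrs.get("state", "awake"))
        provenance = str(f.attrs.get("provenance", ""))
    return Recording(
        data=data, fs_hz=fs, channels=channels, stimulus=stimulus, state=state, provenance=provenance
    )


def write_events(trains: Sequence[EventTrain], path: str | os.PathLike) -> None:
    """Write event trains as CSV with 6-decimal (µs) time precision."""
    rows = []
    for tr in trains:
        for t in tr.event_times_s:
            rows.append((tr.channel_id, f"{t:.6f}"))
    df = pd.DataFrame(rows, columns=["channel_id", "time_s"])
    df.to_csv(path, index=False)


def read_events(path: str | os.PathLike) -> List[EventTrain]:
    """Read event trains from CSV; one train per channel id, in file order."""
    df = pd.read_csv(path, dtype={"channel_id": int, "time_s": float})
    trains: List[EventTrain] = []
    if df.empty:
        return trains
    for cid, grp in df.groupby("channel_id", sort=True):
        times = grp["time_s"].to_numpy()
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(f"event times for channel {cid} are not strictly increasing")
        trains.append(EventTrain(channel_id=int(cid), event_times_s=times))
    return trains
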