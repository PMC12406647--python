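"""On-disk formats: IKI series as CSV, epoch sets as HDF5 with a JSON
sidecar duplicating the metadata for auditability."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, IKISeries

IKI_COLUMNS = ["participant", "production", "soa", "index", "iki_s"]


def write_iki_csv(series_list: list[IKISeries], path) -> None:
    """Long-format CSV: participant, production, soa, index, iki_s."""
    rows = []
    for s in series_list:
        for i, v in enumerate(s.intervals):
            rows.append((s.participant_id, s.production, s.soa, i, v))
    pd.DataFrame(rows, columns=IKI_COLUMNS).to_csv(path, index=False)


def read_iki_csv(path) -> list[IKISeries]:
    df = pd.read_csv(path)
    missing = set(IKI_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"IKI CSV missing columns: {sorted(missing)}")
    out = []
    for (pid, prod, soa), g in df.groupby(["participant", "production", "soa"],
                                          sort=True):
        g = g.sort_values("index")
        out.append(IKISeries(participant_id=str(pid), production=str(prod),
                             soa=float(soa), intervals=g["iki_s"].to_numpy()))
    return out


def write_epochs_h5(epochs: EpochSet, path) -> None:
    """HDF5 container (dataset ``epochs``, μV) plus a ``.json`` sidecar."""
    path = Path(path)
    attrs = {
        "fs_hz": epochs.fs,
        "t0_ms": epochs.t0_offset_ms,
        "channel_labels": list(epochs.channel_labels),
        "production": epochs.production,
        "soa": epochs.soa,
        "participant_id": epochs.participant_id,
    }
    with h5py.File(path, "w") as f:
        d = f.create_dataset("epochs", data=epochs.data)
        d.attrs["units"] = "uV"
        f.attrs["fs_hz"] = epochs.fs
        f.attrs["t0_ms"] = epochs.t0_offset_ms
        f.attrs["channel_labels"] = [c.encode() for c in epochs.channel_labels]
        f.attrs["production"] = epochs.production
        f.attrs["soa"] = epochs.soa
        f.attrs["participant_id"] = epochs.participant_id
    sidecar = dict(attrs)
    sidecar["shape"] = list(epochs.data.shape)
    sidecar["meta"] = _jsonable(epochs.meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_epochs_h5(path) -> EpochSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data = f["epochs"][...]
        labels = [c.decode() if isinstance(c, bytes) else str(c)
                  for c in f.attrs["channel_labels"]]
        eps = EpochSet(
            data=data,
            fs=float(f.attrs["fs_hz"]),
            t0_offset_ms=float(f.attrs["t0_ms"]),
            channel_labels=labels,
            production=str(f.attrs["production"]),
            soa=float(f.attrs["soa"]),
            participant_id=str(f.attrs["participant_id"]),
        )
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        eps.meta.update(json.loads(sidecar.read_text()).get("meta", {}))
    return eps


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
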