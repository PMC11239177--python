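"""Table and trace serialization.

Tables are tab-delimited text; traces go to HDF5 (`roi/<recording>/<roi_id>`
datasets with frame-time attributes, `current/<recording>` for the somatic
trace).  Every table written by the pipeline carries a `# config_hash:` header
line so each statistic is traceable to the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .detection import Barrage, CurrentTrace, RoiTrace, TransmissionEvent

EVENT_COLUMNS = [
    "synapse_id", "recording_id", "onset", "duration_frames",
    "amplitude", "z_amplitude", "barrage_id",
]
BARRAGE_COLUMNS = [
    "barrage_id", "recording_id", "onset", "offset",
    "charge_pC", "peak_pA", "n_events",
]


def config_hash(config) -> str:
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, chash: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if chash:
            fh.write(f"# config_hash: {chash}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def events_to_frame(events: list[TransmissionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(e, c) for c in EVENT_COLUMNS} for e in events],
        columns=EVENT_COLUMNS,
    )


def events_from_frame(df: pd.DataFrame) -> list[TransmissionEvent]:
    out = []
    for row in df.itertuples(index=False):
        bid = row.barrage_id
        if bid is not None and (isinstance(bid, float) and np.isnan(bid)):
            bid = None
        z = row.z_amplitude
        if isinstance(z, float) and np.isnan(z):
            z = None
        out.append(
            TransmissionEvent(
                synapse_id=str(row.synapse_id),
                recording_id=str(row.recording_id),
                onset=float(row.onset),
                duration_frames=int(row.duration_frames),
                amplitude=float(row.amplitude),
                z_amplitude=z,
                barrage_id=None if bid is None else str(bid),
            )
        )
    return out


def barrages_to_frame(barrages: list[Barrage]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(b, c) for c in BARRAGE_COLUMNS} for b in barrages],
        columns=BARRAGE_COLUMNS,
    )


def barrages_from_frame(df: pd.DataFrame) -> list[Barrage]:
    return [
        Barrage(
            barrage_id=str(r.barrage_id),
            recording_id=str(r.recording_id),
            onset=float(r.onset),
            offset=float(r.offset),
            charge_pC=float(r.charge_pC),
            peak_pA=float(r.peak_pA),
            n_events=int(r.n_events),
        )
        for r in df.itertuples(index=False)
    ]


def write_traces_h5(
    path, roi_traces: list[RoiTrace], current: dict[str, CurrentTrace] | None = None
) -> None:
    with h5py.File(path, "w") as f:
        for tr in roi_traces:
            d = f.create_dataset(f"roi/{tr.recording_id}/{tr.roi_id}", data=tr.values)
            d.attrs["times"] = tr.times
        if current:
            for rec, tr in current.items():
                d = f.create_dataset(f"current/{rec}", data=tr.values)
                d.attrs["t0"] = tr.times[0]
                d.attrs["dt"] = float(np.median(np.diff(tr.times)))


def read_traces_h5(path) -> tuple[list[RoiTrace], dict[str, CurrentTrace]]:
    rois: list[RoiTrace] = []
    current: dict[str, CurrentTrace] = {}
    with h5py.File(path, "r") as f:
        if "roi" in f:
            for rec in f["roi"]:
                for roi in f[f"roi/{rec}"]:
                    d = f[f"roi/{rec}/{roi}"]
                    rois.append(
                        RoiTrace(
                            roi_id=roi,
                            times=np.asarray(d.attrs["times"]),
                            values=d[...],
                            recording_id=rec,
                        )
                    )
        if "current" in f:
            for rec in f["current"]:
                d = f[f"current/{rec}"]
                n = d.shape[0]
                times = d.attrs["t0"] + d.attrs["dt"] * np.arange(n)
                current[rec] = CurrentTrace(times=times, values=d[...],
                                            recording_id=rec)
    return rois, current


def write_yaml(obj, path) -> None:
    if dataclasses.is_dataclass(obj):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
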