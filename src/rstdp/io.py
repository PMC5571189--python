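"""Reading and writing annotated membrane-potential recordings.

Two on-disk formats:

* **HDF5** (``.h5``/``.hdf5``): datasets ``vm`` (mV) and ``time`` (s), event
  annotations as parallel ``event_times`` / ``event_kinds`` datasets, and
  recording metadata as root attributes.
* **CSV** (``.csv``): long format with columns ``time_s, vm_mv``; events and
  metadata travel in a JSON sidecar ``<stem>.events.json``.

Both round-trip the full object losslessly (vm, time, events, meta).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synth import MembraneRecording

__all__ = ["read_recording", "write_recording", "events_sidecar_path"]


def events_sidecar_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_name(p.stem + ".events.json")


def write_recording(rec: MembraneRecording, path) -> Path:
    """Write a recording to HDF5 or CSV (+JSON sidecar), by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            # track_times=False keeps the file byte-identical across runs
            f.create_dataset("vm", data=rec.vm_mv, track_times=False)
            f.create_dataset("time", data=rec.time_s, track_times=False)
            f.create_dataset("event_times", data=np.array(
                [t for t, _ in rec.events], dtype=float), track_times=False)
            f.create_dataset("event_kinds", data=np.array(
                [k for _, k in rec.events], dtype="S24"), track_times=False)
            f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            f.attrs["duration_s"] = rec.duration_s
            if rec.seed is not None:
                f.attrs["seed"] = int(rec.seed)
    elif suffix == ".csv":
        pd.DataFrame({"time_s": rec.time_s, "vm_mv": rec.vm_mv}).to_csv(
            path, index=False, float_format="%.17g")
        sidecar = {
            "events": [[float(t), k] for t, k in rec.events],
            "meta": {"sampling_rate_hz": rec.sampling_rate_hz,
                     "duration_s": rec.duration_s,
                     "seed": rec.seed},
        }
        events_sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported recording format {suffix!r} (use .h5 or .csv)")
    return path


def read_recording(path) -> MembraneRecording:
    """Read a recording written by :func:`write_recording`.

    Malformed files raise ``ValueError`` naming the offending field.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            for name in ("vm", "time", "event_times", "event_kinds"):
                if name not in f:
                    raise ValueError(f"malformed recording {path}: missing dataset {name!r}")
            for attr in ("sampling_rate_hz", "duration_s"):
                if attr not in f.attrs:
                    raise ValueError(f"malformed recording {path}: missing attribute {attr!r}")
            events = [(float(t), k.decode())
                      for t, k in zip(f["event_times"][:], f["event_kinds"][:])]
            return MembraneRecording(
                time_s=f["time"][:], vm_mv=f["vm"][:], events=events,
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                duration_s=float(f.attrs["duration_s"]),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None)
    if suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        for col in ("time_s", "vm_mv"):
            if col not in df.columns:
                raise ValueError(f"malformed recording {path}: missing column {col!r}")
        sidecar_path = events_sidecar_path(path)
        events, meta = [], {}
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            if "meta" not in sidecar:
                raise ValueError(f"malformed sidecar {sidecar_path}: missing 'meta'")
            events = [(float(t), str(k)) for t, k in sidecar.get("events", [])]
            meta = sidecar["meta"]
        time = df["time_s"].to_numpy()
        fs = meta.get("sampling_rate_hz") or 1.0 / np.median(np.diff(time))
        return MembraneRecording(
            time_s=time, vm_mv=df["vm_mv"].to_numpy(), events=events,
            sampling_rate_hz=float(fs),
            duration_s=float(meta.get("duration_s", time[-1])),
            seed=meta.get("seed"))
    raise ValueError(f"unsupported recording format {suffix!r} (use .h5 or .csv)")
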