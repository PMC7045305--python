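"""Reading and writing the pipeline's containers.

Movies and trace matrices go to HDF5; event trains, behavior logs, centroid
and label tables go to single-file CSV (comma-separated, header row, UTF-8,
'.' decimal) with scalar metadata in leading ``# key=value`` comment lines;
statistical results go to JSON.  Every writer is paired with a reader such
that write-then-read returns an equal container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import BehaviorSession, EventTrain, FluorescenceMovie, TraceSet

__all__ = [
    "SchemaError",
    "write_movie",
    "read_movie",
    "write_traces",
    "read_traces",
    "write_events",
    "read_events",
    "write_behavior",
    "read_behavior",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "save",
    "load",
]


class SchemaError(ValueError):
    """A file is missing a required column/dataset or holds an invalid value."""


# ---------------------------------------------------------------------------
# HDF5 containers


def write_movie(movie: FluorescenceMovie, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.data)
        f.attrs["frame_rate_hz"] = movie.frame_rate_hz
        f.attrs["is_dff"] = movie.is_dff


def read_movie(path) -> FluorescenceMovie:
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise SchemaError(f"{path}: missing dataset 'frames'")
        return FluorescenceMovie(
            data=f["frames"][...],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            is_dff=bool(f.attrs.get("is_dff", False)),
        )


def write_traces(traces: TraceSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=traces.data)
        f.create_dataset(
            "cell_types", data=np.array([str(c) for c in traces.cell_types], dtype="S")
        )
        f.attrs["frame_rate_hz"] = traces.frame_rate_hz
        f.attrs["session"] = traces.session
        f.attrs["is_dff"] = traces.is_dff


def read_traces(path) -> TraceSet:
    with h5py.File(path, "r") as f:
        if "dff" not in f:
            raise SchemaError(f"{path}: missing dataset 'dff'")
        cell_types = None
        if "cell_types" in f:
            cell_types = np.array([c.decode() for c in f["cell_types"][...]], dtype=object)
        return TraceSet(
            data=f["dff"][...],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            cell_types=cell_types,
            session=str(f.attrs.get("session", "")),
            is_dff=bool(f.attrs.get("is_dff", True)),
        )


# ---------------------------------------------------------------------------
# CSV containers with comment-line metadata


def _write_csv_with_meta(df: pd.DataFrame, meta: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def _read_csv_with_meta(path) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        try:
            df = pd.read_csv(fh)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
    return df, meta


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def write_events(events: EventTrain, path) -> None:
    rows = []
    for cell, (t, a) in enumerate(zip(events.times, events.amplitudes)):
        for ti, ai in zip(t, a):
            rows.append((cell, ti, ai, events.cell_types[cell]))
    df = pd.DataFrame(rows, columns=["cell", "time_s", "amplitude", "cell_type"])
    per_cell_types = ";".join(str(c) for c in events.cell_types)
    _write_csv_with_meta(
        df,
        {
            "container": "EventTrain",
            "n_cells": events.n_cells,
            "duration_s": repr(float(events.duration_s)),
            "session": events.session,
            "cell_types": per_cell_types,
        },
        path,
    )


def read_events(path) -> EventTrain:
    df, meta = _read_csv_with_meta(path)
    if "n_cells" not in meta or "duration_s" not in meta:
        raise SchemaError(f"{path}: missing EventTrain metadata (n_cells/duration_s)")
    n_cells = int(meta["n_cells"])
    if len(df):
        _require_columns(df, ("cell", "time_s", "amplitude"), path)
    times = [np.array([], dtype=float) for _ in range(n_cells)]
    amps = [np.array([], dtype=float) for _ in range(n_cells)]
    if len(df):
        for cell, grp in df.groupby("cell"):
            times[int(cell)] = grp["time_s"].to_numpy(dtype=float)
            amps[int(cell)] = grp["amplitude"].to_numpy(dtype=float)
    cell_types = None
    if meta.get("cell_types", ""):
        cell_types = np.array(meta["cell_types"].split(";"), dtype=object)
        if len(cell_types) != n_cells:
            raise SchemaError(f"{path}: cell_types metadata length != n_cells")
    return EventTrain(
        times=times,
        amplitudes=amps,
        duration_s=float(meta["duration_s"]),
        cell_types=cell_types,
        session=meta.get("session", ""),
    )


def write_behavior(session: BehaviorSession, path) -> None:
    _write_csv_with_meta(
        session.events[["time_s", "event", "cued"]],
        {
            "container": "BehaviorSession",
            "session_type": session.session_type,
            "duration_s": repr(float(session.duration_s)),
        },
        path,
    )


def read_behavior(path) -> BehaviorSession:
    df, meta = _read_csv_with_meta(path)
    if "session_type" not in meta or "duration_s" not in meta:
        raise SchemaError(f"{path}: missing BehaviorSession metadata")
    if not len(df):
        df = pd.DataFrame(columns=["time_s", "event", "cued"])
    _require_columns(df, BehaviorSession.REQUIRED_COLUMNS, path)
    df = df.copy()
    df["cued"] = df["cued"].astype(bool)
    return BehaviorSession(
        events=df, session_type=meta["session_type"], duration_s=float(meta["duration_s"])
    )


def write_table(df: pd.DataFrame, path) -> None:
    """Plain CSV for centroid and label tables."""
    df.to_csv(path, index=False)


def read_table(path, required_columns=()) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, required_columns, path)
    return df


# ---------------------------------------------------------------------------
# JSON results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Generic dispatch

_WRITERS = {
    FluorescenceMovie: write_movie,
    TraceSet: write_traces,
    EventTrain: write_events,
    BehaviorSession: write_behavior,
}
_READERS = {
    FluorescenceMovie: read_movie,
    TraceSet: read_traces,
    EventTrain: read_events,
    BehaviorSession: read_behavior,
}


def save(obj, path) -> None:
    """Write any core container to ``path`` in its documented format."""
    for cls, writer in _WRITERS.items():
        if isinstance(obj, cls):
            writer(obj, path)
            return
    if isinstance(obj, pd.DataFrame):
        write_table(obj, path)
        return
    raise TypeError(f"no writer for {type(obj).__name__}")


def load(cls, path):
    """Read a container of type ``cls`` from ``path``."""
    if cls is pd.DataFrame:
        return read_table(path)
    try:
        return _READERS[cls](path)
    except KeyError:
        raise TypeError(f"no reader for {cls.__name__}") from None
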