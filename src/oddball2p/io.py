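"""Session on-disk formats.

Tabular objects (trial table, event list, behavior trace, report tables)
are tab-separated text with a header row; times are seconds with 8
significant digits. Traces and ground truth live in one HDF5 container per
session:

    /traces/raw              (n_cells, n_frames) measured fluorescence, a.u.
    /traces/neuropil         (n_cells, n_frames) matched neuropil traces
    /traces/cell             (n_cells, n_frames) uncontaminated cell trace
                             (ground-truth auxiliary; synthetic sessions only)
    /traces/timestamps       (n_frames,) s
    /cells/animal_id         (n_cells,)
    /ground_truth/...        one dataset per GroundTruth field
    attrs: session_id

Frame stacks are multi-page 16-bit TIFF.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .synthetic import BehaviorTrace, FrameStack, GroundTruth, RawTraceSet

FLOAT_FMT = "%.8g"


# ---------------------------------------------------------------------------
# Tabular text


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_behavior(behavior: BehaviorTrace, path) -> None:
    df = pd.DataFrame(
        {
            "timestamp": behavior.timestamps,
            "running_speed": behavior.running_speed,
            "pupil_area": behavior.pupil_area,
        }
    )
    write_table(df, path)


def read_behavior(path) -> BehaviorTrace:
    df = read_table(path)
    return BehaviorTrace(
        timestamps=df.timestamp.to_numpy(),
        running_speed=df.running_speed.to_numpy(),
        pupil_area=df.pupil_area.to_numpy(),
    )


# ---------------------------------------------------------------------------
# HDF5 session container


def write_session_h5(path, traces: RawTraceSet, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("traces")
        g.create_dataset("raw", data=traces.raw, compression="gzip", shuffle=True)
        g.create_dataset("neuropil", data=traces.neuropil, compression="gzip", shuffle=True)
        if traces.cell_fluorescence is not None:
            g.create_dataset(
                "cell", data=traces.cell_fluorescence, compression="gzip", shuffle=True
            )
        g.create_dataset("timestamps", data=traces.timestamps)
        f.create_group("cells").create_dataset("animal_id", data=traces.animal_id)
        f.attrs["session_id"] = traces.session_id
        if truth is not None:
            gt = f.create_group("ground_truth")
            for fld in dataclasses.fields(truth):
                val = getattr(truth, fld.name)
                if val is None:
                    continue
                arr = np.asarray(val)
                if arr.dtype == object or arr.dtype.kind == "U":
                    arr = arr.astype("S")
                gt.create_dataset(fld.name, data=arr)


def read_session_h5(path):
    """Returns (RawTraceSet, GroundTruth | None)."""
    with h5py.File(path, "r") as f:
        g = f["traces"]
        traces = RawTraceSet(
            raw=g["raw"][()],
            neuropil=g["neuropil"][()],
            timestamps=g["timestamps"][()],
            animal_id=f["cells/animal_id"][()],
            session_id=str(f.attrs.get("session_id", "unknown")),
            cell_fluorescence=g["cell"][()] if "cell" in g else None,
        )
        truth = None
        if "ground_truth" in f:
            gt = f["ground_truth"]
            kwargs = {}
            for name in gt:
                arr = gt[name][()]
                if getattr(arr, "dtype", None) is not None and arr.dtype.kind == "S":
                    arr = arr.astype(str)
                kwargs[name] = arr
            if "tuning_labels" in kwargs:
                kwargs["tuning_labels"] = tuple(np.atleast_1d(kwargs["tuning_labels"]))
            truth = GroundTruth(**kwargs)
    return traces, truth


# ---------------------------------------------------------------------------
# TIFF frame stacks


def write_stack_tiff(stack: FrameStack, path) -> None:
    frames = stack.frames
    lo, hi = frames.min(), frames.max()
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    data = ((frames - lo) * scale).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_stack_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_shifts(stack: FrameStack, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(len(stack.shifts)),
            "dy": stack.shifts[:, 0],
            "dx": stack.shifts[:, 1],
        }
    )
    write_table(df, path)


def read_shifts(path) -> np.ndarray:
    df = read_table(path)
    return df[["dy", "dx"]].to_numpy()


def session_paths(directory) -> dict[str, Path]:
    d = Path(directory)
    return {
        "trials": d / "trials.tsv",
        "events": d / "events.tsv",
        "behavior": d / "behavior.tsv",
        "container": d / "session.h5",
        "stack": d / "stack.tif",
        "shifts": d / "stack_shifts.tsv",
        "config": d / "config.yaml",
    }
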