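"""Recording-bundle reading and writing.

A "recording bundle" is a single HDF5 file holding one paired
recording: the grid electrophysiology (volts, float32), its geometry,
the calcium traces, the imaging geometry and frame rate, the clock
offset between the two acquisition systems, and (for synthetic data)
the ground truth as a JSON string.  CSV exports of traces and geometry
are provided for inspection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .core import CalciumTraces, GridRecording
from .synth import GroundTruth


class BundleSchemaError(ValueError):
    """A bundle is missing a dataset or violates a type invariant."""


def write_bundle(path, recording: GridRecording, traces: CalciumTraces,
                 truth: GroundTruth | None = None,
                 sync_offset_s: float = 0.0) -> None:
    """Write one paired recording to an HDF5 bundle.

    Electrophysiology is stored in volts (float32); the in-memory
    convention is microvolts, so the writer rescales.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("ephys", data=(recording.signals * 1e-6).astype(np.float32))
        f["ephys"].attrs["units"] = "V"
        f.create_dataset("ephys_rate", data=float(recording.rate))
        geo = f.create_group("geometry")
        geo.create_dataset("channel", data=recording.geometry["channel"].to_numpy(int))
        geo.create_dataset("x_mm", data=recording.geometry["x_mm"].to_numpy(float))
        geo.create_dataset("y_mm", data=recording.geometry["y_mm"].to_numpy(float))
        geo.create_dataset("functional",
                           data=recording.geometry["functional"].to_numpy(bool))
        f.create_dataset("calcium", data=traces.dff.astype(np.float64))
        f["calcium"].attrs["units"] = "dF/F"
        f.create_dataset("frame_rate", data=float(traces.frame_rate))
        f.create_dataset("centroids", data=traces.centroids.astype(float))
        f.create_dataset("baseline_epoch", data=np.asarray(traces.baseline_epoch, int))
        f.create_dataset("sync_offset_s", data=float(sync_offset_s))
        if truth is not None:
            f.create_dataset("ground_truth", data=truth.to_json())


def read_bundle(path) -> tuple[GridRecording, CalciumTraces, GroundTruth | None, float]:
    """Load a bundle, validating the schema and type invariants.

    Returns ``(recording, traces, ground_truth_or_None, sync_offset_s)``.
    Validation failures raise :class:`BundleSchemaError` naming the
    offending field.
    """
    with h5py.File(path, "r") as f:
        for name in ("ephys", "ephys_rate", "geometry", "calcium",
                     "frame_rate", "centroids", "baseline_epoch", "sync_offset_s"):
            if name not in f:
                raise BundleSchemaError(f"bundle missing /{name}")
        for name in ("channel", "x_mm", "y_mm", "functional"):
            if name not in f["geometry"]:
                raise BundleSchemaError(f"bundle missing /geometry/{name}")
        rate = float(f["ephys_rate"][()])
        if rate <= 0:
            raise BundleSchemaError("ephys_rate must be positive")
        signals = np.asarray(f["ephys"], dtype=float) * 1e6  # V -> µV
        geometry = pd.DataFrame({
            "channel": np.asarray(f["geometry/channel"], int),
            "x_mm": np.asarray(f["geometry/x_mm"], float),
            "y_mm": np.asarray(f["geometry/y_mm"], float),
            "functional": np.asarray(f["geometry/functional"], bool),
        })
        try:
            recording = GridRecording(signals=signals, rate=rate, geometry=geometry)
        except ValueError as e:
            raise BundleSchemaError(str(e)) from e
        try:
            traces = CalciumTraces(
                dff=np.asarray(f["calcium"], float),
                frame_rate=float(f["frame_rate"][()]),
                centroids=np.asarray(f["centroids"], float),
                baseline_epoch=tuple(np.asarray(f["baseline_epoch"], int)),
            )
        except ValueError as e:
            raise BundleSchemaError(str(e)) from e
        truth = None
        if "ground_truth" in f:
            raw = f["ground_truth"][()]
            if isinstance(raw, bytes):
                raw = raw.decode()
            truth = GroundTruth.from_json(raw)
        sync = float(f["sync_offset_s"][()])
    return recording, traces, truth, sync


def traces_to_csv(traces: CalciumTraces, path) -> None:
    """Cells x frames CSV with a header row of frame times (s)."""
    df = pd.DataFrame(traces.dff,
                      columns=[f"{t:.4f}" for t in traces.frame_times])
    df.insert(0, "cell_id", np.arange(traces.n_cells))
    df.to_csv(path, index=False)


def centroids_to_csv(traces: CalciumTraces, path) -> None:
    pd.DataFrame({
        "cell_id": np.arange(traces.n_cells),
        "x_um": traces.centroids[:, 0],
        "y_um": traces.centroids[:, 1],
    }).to_csv(path, index=False)


def geometry_to_csv(recording: GridRecording, path) -> None:
    recording.geometry.to_csv(path, index=False)
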