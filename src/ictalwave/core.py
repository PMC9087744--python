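"""Core in-memory containers shared across the analysis stages.

Two substrates flow through the pipeline: a multichannel extracellular
recording from a planar microelectrode grid, and somatic calcium traces
(ΔF/F) extracted from a co-registered imaging field.  Both carry the
geometry needed by the spatial analyses (channel positions in mm on the
array, ROI centroids in µm in the imaging frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GEOMETRY_COLUMNS = ("channel", "x_mm", "y_mm", "functional")


@dataclass
class GridRecording:
    """Wide-band voltage series from a planar electrode grid.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    rate
        Sampling rate in Hz.
    geometry
        One row per channel with columns ``channel`` (id), ``x_mm``,
        ``y_mm`` (planar position) and ``functional`` (bool flag;
        non-functional channels are excluded from spatial fits).
    """

    signals: np.ndarray
    rate: float
    geometry: pd.DataFrame

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        missing = [c for c in GEOMETRY_COLUMNS if c not in self.geometry.columns]
        if missing:
            raise ValueError(f"geometry missing columns: {missing}")
        if len(self.geometry) != self.signals.shape[0]:
            raise ValueError(
                "geometry/channel count mismatch: "
                f"{len(self.geometry)} rows vs {self.signals.shape[0]} channels"
            )
        xy = self.geometry[["x_mm", "y_mm"]].to_numpy(float)
        if not np.all(np.isfinite(xy)):
            raise ValueError("channel positions must be finite")
        if len(np.unique(xy, axis=0)) != len(xy):
            raise ValueError("channel positions must be unique")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    def functional_mask(self) -> np.ndarray:
        return self.geometry["functional"].to_numpy(bool)


@dataclass
class CalciumTraces:
    """Per-cell fluorescence traces with imaging-frame geometry.

    ``dff`` holds cells x frames; values are ΔF/F relative to a
    preseizure baseline (use :func:`ictalwave.calcium.compute_dff` to
    normalize raw fluorescence).  ``baseline_epoch`` is the half-open
    frame interval used as the preseizure reference.
    """

    dff: np.ndarray
    frame_rate: float
    centroids: np.ndarray  # (n_cells, 2) in µm
    baseline_epoch: tuple[int, int]

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.dff.ndim != 2:
            raise ValueError("dff must be 2-D (cells x frames)")
        if not 1.0 <= self.frame_rate <= 100.0:
            raise ValueError("frame_rate must lie in [1, 100] Hz")
        if self.centroids.shape != (self.dff.shape[0], 2):
            raise ValueError("centroids must be (n_cells, 2)")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        lo, hi = self.baseline_epoch
        if not (0 <= lo < hi <= self.dff.shape[1]):
            raise ValueError("baseline_epoch must be a non-empty frame interval")

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_frames(self) -> int:
        return self.dff.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate
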