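"""Sliding-window multimodal features and wave-speed targets.

From one electrode channel and the co-registered calcium traces,
extracts per-window features used to predict the traveling-wave speed:

ephys (5): mean and SD of the high-γ (80–150 Hz) Hilbert amplitude,
fractional 4–30 Hz power, fractional 80–150 Hz power, and the
phase-locking value (PLV) between the 4–30 Hz phase and the phase of
the high-γ amplitude envelope;

calcium (5): mean ΔF/F amplitude, mean per-cell line length
(Σ|diff(ΔF/F)|), mean per-cell SD of the first ΔF/F difference, and
the mean and SD of pairwise cell-cell Pearson correlations.

The per-window target is the median speed of the discharge events
whose peak falls inside the window; windows without events carry a
missing (NaN) target and are excluded from model training.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import CalciumTraces, GridRecording
from .ephys import HG_BAND, LOW_BAND, analytic, bandpass, downsample
from .waves import DischargeEvent

logger = logging.getLogger(__name__)

EPHYS_FEATURES = ["mean_hg_amp", "sd_hg_amp", "frac_power_4_30",
                  "frac_power_80_150", "plv"]
CALCIUM_FEATURES = ["mean_dff_amp", "mean_dff_line_length",
                    "mean_sd_dff_derivative", "mean_pair_corr", "sd_pair_corr"]
FEATURE_COLUMNS = EPHYS_FEATURES + CALCIUM_FEATURES
TARGET_COLUMN = "target_speed_mm_s"


def make_windows(total_duration_s: float, win: float = 4.0, step: float = 3.0
                 ) -> list[tuple[float, float]]:
    """Sliding windows [k·step, k·step + win] with end <= total.

    The default step of 3 s realizes a 1 s overlap between consecutive
    4 s windows.
    """
    if total_duration_s < win:
        warnings.warn("record shorter than one window; no windows", stacklevel=2)
        return []
    out = []
    k = 0
    eps = 1e-9
    while k * step + win <= total_duration_s + eps:
        out.append((k * step, k * step + win))
        k += 1
    return out


def plv(phase_a: np.ndarray, phase_b: np.ndarray) -> float:
    """Phase-locking value |mean exp(i(φ_a − φ_b))| in [0, 1]."""
    d = np.asarray(phase_a, dtype=float) - np.asarray(phase_b, dtype=float)
    return float(np.abs(np.mean(np.exp(1j * d))))


class EphysFeatureExtractor:
    """Precomputed band signals for one channel.

    Filtering and Hilbert transforms run once on the whole record
    (zero-phase), so per-window features are free of filter edge
    transients.  The phase of the high-γ amplitude envelope is the
    analytic phase of the mean-removed envelope.
    """

    def __init__(self, samples: np.ndarray, rate: float, analysis_rate: float = 2000.0):
        x, fs = downsample(np.asarray(samples, dtype=float), rate, min(analysis_rate, rate))
        self.rate = fs
        self.raw = x
        self.low = bandpass(x, fs, LOW_BAND)
        self.hg = bandpass(x, fs, HG_BAND)
        self.low_phase = analytic(self.low).phase
        self.hg_amp = analytic(self.hg).amplitude
        env = self.hg_amp - self.hg_amp.mean()
        self.hg_amp_phase = np.angle(sps.hilbert(env))

    def window_features(self, start_s: float, end_s: float) -> dict[str, float]:
        i0 = int(round(start_s * self.rate))
        i1 = int(round(end_s * self.rate))
        if i0 < 0 or i1 > self.raw.size:
            raise ValueError("window outside the recording")
        if (end_s - start_s) < 2.0 / LOW_BAND[0]:
            raise ValueError("window shorter than two low-frequency cycles")
        amp = self.hg_amp[i0:i1]
        f, pxx = sps.periodogram(self.raw[i0:i1], fs=self.rate, window="hann")
        total = np.trapezoid(pxx, f)
        def frac(band):
            m = (f >= band[0]) & (f <= band[1])
            return float(np.trapezoid(pxx[m], f[m]) / total) if total > 0 else 0.0
        return {
            "mean_hg_amp": float(amp.mean()),
            "sd_hg_amp": float(np.std(amp, ddof=1)),
            "frac_power_4_30": frac(LOW_BAND),
            "frac_power_80_150": frac(HG_BAND),
            "plv": plv(self.low_phase[i0:i1], self.hg_amp_phase[i0:i1]),
        }


def calcium_window_features(traces: CalciumTraces, start_s: float, end_s: float
                            ) -> dict[str, float]:
    """Five calcium features over frames with timestamps in [start, end)."""
    t = traces.frame_times
    m = (t >= start_s) & (t < end_s)
    if traces.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if m.sum() < 3:
        raise ValueError("need at least 3 frames in the window")
    seg = traces.dff[:, m]
    d = np.diff(seg, axis=1)
    sd_cells = np.std(seg, axis=1, ddof=1)
    varying = sd_cells > 0
    if not varying.any():
        raise ValueError("no variance: all cells constant in window")
    corr = np.corrcoef(seg[varying])
    iu = np.triu_indices(int(varying.sum()), k=1)
    pair = corr[iu]
    n_dropped = traces.n_cells - int(varying.sum())
    if n_dropped:
        logger.info("dropped %d constant cells from pair correlations", n_dropped)
    return {
        "mean_dff_amp": float(seg.mean()),
        "mean_dff_line_length": float(np.abs(d).sum(axis=1).mean()),
        "mean_sd_dff_derivative": float(np.std(d, axis=1, ddof=1).mean()),
        "mean_pair_corr": float(pair.mean()) if pair.size else np.nan,
        "sd_pair_corr": float(np.std(pair, ddof=1)) if pair.size > 1 else np.nan,
    }


def window_speed_targets(events: list[DischargeEvent],
                         windows: list[tuple[float, float]]) -> np.ndarray:
    """Median wave speed per window; NaN where no event falls inside."""
    times = np.array([ev.t_center for ev in events
                      if not ev.degenerate and np.isfinite(ev.speed_mm_s)])
    speeds = np.array([ev.speed_mm_s for ev in events
                       if not ev.degenerate and np.isfinite(ev.speed_mm_s)])
    out = np.full(len(windows), np.nan)
    for i, (s, e) in enumerate(windows):
        m = (times >= s) & (times < e)
        if m.any():
            out[i] = np.median(speeds[m])
    return out


def build_feature_table(recording: GridRecording, traces: CalciumTraces,
                        events: list[DischargeEvent], channel: int,
                        win: float = 4.0, step: float = 3.0,
                        sync_offset_s: float = 0.0,
                        span: tuple[float, float] | None = None,
                        seizure_id: str = "seizure") -> pd.DataFrame:
    """Aligned per-window feature rows for one seizure.

    ``channel`` selects the electrode above the imaging plane.  The
    calcium clock is shifted by ``sync_offset_s`` (calcium time =
    ephys time − offset) before windowing, so both modalities share
    window boundaries.  ``span`` restricts windowing to an epoch
    (e.g. the annotated seizure, from first to last discharge); by
    default the whole record is windowed.
    """
    t0 = 0.0
    total = min(recording.duration_s,
                traces.n_frames / traces.frame_rate + sync_offset_s)
    if span is not None:
        t0 = max(0.0, span[0])
        total = min(total, span[1]) - t0
    windows = [(t0 + s, t0 + e) for s, e in make_windows(total, win=win, step=step)]
    ex = EphysFeatureExtractor(recording.signals[channel], recording.rate)
    targets = window_speed_targets(events, windows)
    rows = []
    for (s, e), tgt in zip(windows, targets):
        row = {"start_s": s, "end_s": e}
        row.update(ex.window_features(s, e))
        row.update(calcium_window_features(traces, s - sync_offset_s, e - sync_offset_s))
        row[TARGET_COLUMN] = tgt
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["seizure_id"] = seizure_id
    df.attrs["channel"] = channel
    return df
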