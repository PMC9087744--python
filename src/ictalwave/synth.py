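"""Seeded synthetic multimodal seizure datasets with known ground truth.

The generator emulates the phenomenology the downstream stages measure,
so every stage is testable by parameter recovery:

* ictal discharges propagating as plane waves across a planar electrode
  grid at a controllable speed and direction (Gabor wavelets, 8 Hz
  carrier under a Gaussian envelope, inside the 4–30 Hz analysis band);
* high-γ bursts (120 Hz carrier) and brief biphasic multiunit spikes
  placed at times whose low-frequency phase is drawn from a von Mises
  distribution — i.e. phase-locked to the discharge rhythm;
* calcium traces with a planted cell-recruitment order (onsets spread
  over a configurable span), indicator-like rise/decay kinetics, and
  per-discharge transients whose amplitude can be coupled to the
  planted wave speed so that imaging features carry speed information.

All randomness flows from a single seed, split into fixed per-component
substreams so that, e.g., adding cells does not perturb the LFP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig
from scipy import stats as sstats

from .core import CalciumTraces, GridRecording

__all__ = ["SynthConfig", "GroundTruth", "generate_lfp", "generate_calcium", "generate_study"]

# fixed substream indices (adding a component must not renumber others)
_STREAM_LFP_NOISE = 0
_STREAM_EVENTS = 1
_STREAM_CALCIUM_NOISE = 2
_STREAM_CALCIUM_RANKS = 3
_STREAM_CENTROIDS = 4

_WAVELET_F0 = 8.0        # Hz, discharge carrier
_WAVELET_SIGMA = 0.040   # s, discharge Gaussian envelope
_HG_F0 = 120.0           # Hz, high-γ carrier
_HG_SIGMA = 0.030 / 2.355  # s, ~30 ms FWHM envelope
_MUA_WIDTH = 0.001       # s, biphasic spike duration


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic seizure recording.

    Defaults describe a one-minute focal seizure on a 4x4 grid with
    0.5 mm pitch, recruitment of the imaged population over 1.2 s, and
    a plane wave near 500 mm/s — magnitudes typical of hippocampal
    seizure traveling waves.
    """

    seed: int = 0
    duration_s: float = 60.0
    ephys_rate: float = 8000.0
    frame_rate: float = 10.0
    grid_shape: tuple[int, int] = (4, 4)
    pitch_mm: float = 0.5
    n_cells: int = 20
    baseline_s: float = 10.0
    discharge_rate_hz: float = 2.0
    wave_speed_mm_s: float = 500.0
    wave_direction_rad: float = np.pi / 4
    timing_jitter_ms: float = 2.0
    hg_lock_phase_rad: float = 0.0
    hg_lock_kappa: float = 8.0
    mua_lock_phase_rad: float = 0.0
    mua_lock_kappa: float = 8.0
    onset_span_s: float = 1.2
    onset_span_sd_s: float = 0.0   # across-seizure SD of the realized span
    onset_rank_noise: float = 0.0
    calcium_rise_s: float = 0.2
    calcium_decay_s: float = 1.5
    noise_sd_ephys: float = 10.0   # µV
    noise_sd_dff: float = 0.05
    speed_trend: float = 1.0       # multiplicative per discharge; <1 = slowing
    # signal amplitudes
    discharge_amp_uv: float = 300.0
    hg_amp_uv: float = 30.0
    onset_amp_dff: float = 1.5
    transient_amp_dff: float = 0.6
    # coupling of per-discharge calcium transient amplitude to planted speed
    # (exponent on speed relative to the first discharge; 0 = uncoupled)
    calcium_speed_coupling: float = 1.0
    n_hg_per_discharge: int = 2
    n_mua_per_discharge: int = 3
    sync_offset_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.duration_s > self.baseline_s > 0:
            raise ValueError("require duration_s > baseline_s > 0")
        if self.wave_speed_mm_s <= 0:
            raise ValueError("wave_speed_mm_s must be positive")
        if not 0 < self.onset_span_s < self.duration_s - self.baseline_s:
            raise ValueError("require 0 < onset_span_s < duration_s - baseline_s")
        if self.grid_shape[0] * self.grid_shape[1] < 4:
            raise ValueError("grid must have at least 4 channels")
        for name in ("ephys_rate", "frame_rate", "discharge_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.onset_rank_noise < 0:
            raise ValueError("onset_rank_noise must be >= 0")
        # merged discharges would break per-event analyses
        half_width = 2.355 * _WAVELET_SIGMA  # envelope FWHM
        if half_width >= 1.0 / self.discharge_rate_hz:
            raise ValueError("discharge wavelet half-width >= inter-discharge interval")

    def rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(stream,))
        return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted parameters of one synthetic seizure."""

    discharge_times: np.ndarray            # (n_events,) s, event reference time
    speeds_mm_s: np.ndarray                # (n_events,)
    directions_rad: np.ndarray             # (n_events,)
    peak_times: np.ndarray                 # (n_events, n_channels), jittered
    plane_peak_times: np.ndarray           # (n_events, n_channels), pre-jitter
    hg_times: np.ndarray                   # reference-channel burst centers, s
    hg_phases: np.ndarray                  # planted low-frequency phases, rad
    mua_times: np.ndarray
    mua_phases: np.ndarray
    cell_onset_times: np.ndarray | None = None   # (n_cells,) s
    cell_onset_frames: np.ndarray | None = None  # (n_cells,) first frame after onset
    cell_ranks: np.ndarray | None = None         # (n_cells,) frame-resolution ranks
                                                 # (average ties), 1-based

    def to_json(self) -> str:
        def conv(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        return json.dumps({k: conv(v) for k, v in self.__dict__.items()})

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        out = {}
        for k, v in raw.items():
            out[k] = np.asarray(v, dtype=float) if v is not None else None
        return cls(**out)


def grid_geometry(config: SynthConfig) -> pd.DataFrame:
    rows, cols = config.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return pd.DataFrame(
        {
            "channel": np.arange(rows * cols),
            "x_mm": cc.ravel() * config.pitch_mm,
            "y_mm": rr.ravel() * config.pitch_mm,
            "functional": True,
        }
    )


def _von_mises(rng: np.random.Generator, mu: float, kappa: float, n: int) -> np.ndarray:
    if not np.isfinite(kappa) or kappa > 1e8:
        return np.full(n, mu)
    return rng.vonmises(mu, kappa, n)


def _add_gabor(sig: np.ndarray, rate: float, center: float, amp: float,
               f0: float, sigma: float, phase: float = 0.0) -> None:
    """Add amp * exp(-(t-c)^2/2σ²) * cos(2π f0 (t-c) + phase) in place."""
    half = 4.0 * sigma
    i0 = max(0, int((center - half) * rate))
    i1 = min(sig.size, int((center + half) * rate) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / rate - center
    sig[i0:i1] += amp * np.exp(-0.5 * (t / sigma) ** 2) * np.cos(2 * np.pi * f0 * t + phase)


def _add_biphasic(sig: np.ndarray, rate: float, center: float, trough_amp: float) -> None:
    """1 ms negative-leading biphasic pulse with trough amplitude trough_amp (<0)."""
    i0 = max(0, int((center - _MUA_WIDTH / 2) * rate))
    i1 = min(sig.size, int((center + _MUA_WIDTH / 2) * rate) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / rate - (center - _MUA_WIDTH / 2)
    sig[i0:i1] += trough_amp * np.sin(2 * np.pi * t / _MUA_WIDTH)


def _phase_to_offset(rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Map low-frequency phase to time offset from the wavelet peak.

    The 4–30 Hz band truncates the lower half of the discharge
    wavelet's spectrum, so the measured instantaneous phase of the
    filtered signal advances faster than the nominal 8 Hz carrier
    phase.  Planted event phases are defined on the measured phase, so
    the offsets are read off the analytic phase profile of the
    band-passed wavelet template rather than from the carrier.
    Returns ``(phases, offsets)`` suitable for ``np.interp``.
    """
    half = 0.5  # s of template on each side; generous for filter edges
    t = np.arange(-half, half, 1.0 / rate)
    w = np.exp(-0.5 * (t / _WAVELET_SIGMA) ** 2) * np.cos(2 * np.pi * _WAVELET_F0 * t)
    sos = spsig.butter(2, (4.0, 30.0), btype="bandpass", fs=rate, output="sos")
    phase = np.unwrap(np.angle(spsig.hilbert(spsig.sosfiltfilt(sos, w))))
    center = np.argmin(np.abs(t))
    phase = phase - phase[center]
    # restrict to the central carrier cycle, where phase is monotonic
    m = np.abs(t) <= 0.5 / _WAVELET_F0
    return phase[m], t[m]


def discharge_times(config: SynthConfig) -> np.ndarray:
    """Regularly spaced event reference times inside the ictal epoch."""
    period = 1.0 / config.discharge_rate_hz
    start = config.baseline_s + 0.5
    stop = config.duration_s - 0.5
    n = int(np.floor((stop - start) / period)) + 1
    return start + np.arange(max(n, 0)) * period


def generate_lfp(config: SynthConfig) -> tuple[GridRecording, GroundTruth]:
    """Synthesize the grid recording and its ground truth.

    Each discharge is a Gabor wavelet whose envelope peak on channel i
    is ``t_event + (x_i cosθ + y_i sinθ)/v + jitter``.  High-γ bursts
    and multiunit spikes ride on every channel at fixed phase offsets
    of the 8 Hz carrier, drawn per event from von Mises distributions.
    """
    geom = grid_geometry(config)
    n_ch = len(geom)
    n_samp = int(round(config.duration_s * config.ephys_rate))
    rate = config.ephys_rate

    ev_rng = config.rng(_STREAM_EVENTS)
    t_events = discharge_times(config)
    n_ev = t_events.size
    speeds = config.wave_speed_mm_s * config.speed_trend ** np.arange(n_ev)
    dirs = np.full(n_ev, config.wave_direction_rad)

    x = geom["x_mm"].to_numpy()
    y = geom["y_mm"].to_numpy()
    delay = (np.outer(np.cos(dirs), x) + np.outer(np.sin(dirs), y)) / speeds[:, None]
    plane_peaks = t_events[:, None] + delay
    jitter = ev_rng.normal(0.0, config.timing_jitter_ms / 1000.0, plane_peaks.shape)
    peaks = plane_peaks + jitter

    # phase-locked event offsets, shared across channels within an event
    hg_ph = _von_mises(ev_rng, config.hg_lock_phase_rad, config.hg_lock_kappa,
                       n_ev * config.n_hg_per_discharge)
    mua_ph = _von_mises(ev_rng, config.mua_lock_phase_rad, config.mua_lock_kappa,
                        n_ev * config.n_mua_per_discharge)
    # burst k of event e sits where the measured low-frequency phase of
    # the filtered wavelet equals its drawn phase; all bursts stay
    # within the central carrier cycle, where the envelope (and hence
    # the phase estimate) is strong
    ph_grid, off_grid = _phase_to_offset(rate)
    hg_off = np.interp(hg_ph, ph_grid, off_grid)
    mua_off = np.interp(mua_ph, ph_grid, off_grid)

    noise_rng = config.rng(_STREAM_LFP_NOISE)
    sig = noise_rng.normal(0.0, config.noise_sd_ephys, (n_ch, n_samp)) \
        if config.noise_sd_ephys > 0 else np.zeros((n_ch, n_samp))

    # spike-band noise floor sets the planted MUA amplitude (−6x band SD)
    band_frac = max((min(3000.0, rate / 2 * 0.95) - 300.0), 0.0) / (rate / 2)
    sd_spike_band = config.noise_sd_ephys * np.sqrt(max(band_frac, 0.0))
    mua_amp = -6.0 * (sd_spike_band if sd_spike_band > 0 else 1.0)

    for ch in range(n_ch):
        s = sig[ch]
        for e in range(n_ev):
            tp = peaks[e, ch]
            _add_gabor(s, rate, tp, config.discharge_amp_uv, _WAVELET_F0, _WAVELET_SIGMA)
            for k in range(config.n_hg_per_discharge):
                off = hg_off[e * config.n_hg_per_discharge + k]
                _add_gabor(s, rate, tp + off, config.hg_amp_uv, _HG_F0, _HG_SIGMA)
            for k in range(config.n_mua_per_discharge):
                off = mua_off[e * config.n_mua_per_discharge + k]
                _add_biphasic(s, rate, tp + off, mua_amp)

    ref = 0  # ground-truth event times reported on channel 0
    hg_times = (peaks[:, ref][:, None]
                + hg_off.reshape(n_ev, -1)).ravel()
    mua_times = (peaks[:, ref][:, None]
                 + mua_off.reshape(n_ev, -1)).ravel()

    rec = GridRecording(signals=sig, rate=rate, geometry=geom)
    truth = GroundTruth(
        discharge_times=t_events,
        speeds_mm_s=speeds,
        directions_rad=dirs,
        peak_times=peaks,
        plane_peak_times=plane_peaks,
        hg_times=hg_times,
        hg_phases=hg_ph,
        mua_times=mua_times,
        mua_phases=mua_ph,
    )
    return rec, truth


def _indicator_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Step-plus-exponential response: (1 - e^{-t/rise}) e^{-t/decay}, t >= 0."""
    out = np.zeros_like(t)
    m = t >= 0
    out[m] = (1.0 - np.exp(-t[m] / rise)) * np.exp(-t[m] / decay)
    return out


def planted_ranks(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Realized recruitment order for this seizure.

    The rank template is the cell index itself (cell 0 recruits first
    in the noiseless case); ``onset_rank_noise`` is the SD, in rank
    units, of a Gaussian perturbation applied to the template before
    re-ranking, so the template is shared across seizures while the
    realized order varies.
    Returns (order, ranks) with ``order[j]`` = cell recruited j-th and
    ``ranks`` 1-based per cell.
    """
    rng = config.rng(_STREAM_CALCIUM_RANKS)
    scores = np.arange(config.n_cells, dtype=float)
    if config.onset_rank_noise > 0:
        scores = scores + rng.normal(0.0, config.onset_rank_noise, config.n_cells)
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(config.n_cells, dtype=float)
    ranks[order] = np.arange(1, config.n_cells + 1)
    return order, ranks


def generate_calcium(config: SynthConfig, truth: GroundTruth) -> CalciumTraces:
    """Synthesize ΔF/F traces consistent with the planted seizure.

    Each cell is silent (noise only) until its planted onset; onsets are
    spread uniformly over ``onset_span_s`` in planted rank order,
    starting at the first discharge.  After onset the cell shows a large
    recruitment transient plus one transient per subsequent discharge
    whose amplitude follows the planted wave speed via
    ``calcium_speed_coupling``.  Centroids are laid out so the planted
    rank increases along the +x axis of the imaging frame.
    """
    if config.n_cells < 2:
        raise ValueError("n_cells must be >= 2")
    n_frames = int(round(config.duration_s * config.frame_rate))
    ft = np.arange(n_frames) / config.frame_rate

    order, ranks = planted_ranks(config)
    t0 = float(truth.discharge_times[0]) if truth.discharge_times.size else config.baseline_s
    span = config.onset_span_s
    if config.onset_span_sd_s > 0:
        span_rng = config.rng(_STREAM_CALCIUM_RANKS).spawn(1)[0]
        span = max(0.2, float(np.random.default_rng(span_rng).normal(
            config.onset_span_s, config.onset_span_sd_s)))
    if config.n_cells > 1:
        onset_of_position = t0 + span * np.arange(config.n_cells) / (config.n_cells - 1)
    else:
        onset_of_position = np.array([t0])
    onsets = np.empty(config.n_cells)
    onsets[order] = onset_of_position

    noise_rng = config.rng(_STREAM_CALCIUM_NOISE)
    dff = noise_rng.normal(0.0, config.noise_sd_dff, (config.n_cells, n_frames)) \
        if config.noise_sd_dff > 0 else np.zeros((config.n_cells, n_frames))

    v0 = truth.speeds_mm_s[0] if truth.speeds_mm_s.size else 1.0
    rel_amp = (truth.speeds_mm_s / v0) ** config.calcium_speed_coupling \
        if truth.speeds_mm_s.size else np.array([])
    for c in range(config.n_cells):
        resp = config.onset_amp_dff * _indicator_kernel(
            ft - onsets[c], config.calcium_rise_s, config.calcium_decay_s)
        for e, te in enumerate(truth.discharge_times):
            if te < onsets[c]:
                continue
            resp += config.transient_amp_dff * rel_amp[e] * _indicator_kernel(
                ft - te, config.calcium_rise_s, config.calcium_decay_s)
        # keep the pre-onset segment exactly at baseline (noise only)
        resp[ft < onsets[c]] = 0.0
        dff[c] += resp

    # rank-1 cells near x=0, last-recruited near x=300 µm
    cen_rng = config.rng(_STREAM_CENTROIDS)
    span_um = 300.0
    cx = span_um * (ranks - 1) / max(config.n_cells - 1, 1)
    cx = cx + cen_rng.normal(0.0, 5.0, config.n_cells)
    cy = cen_rng.uniform(0.0, span_um, config.n_cells)
    centroids = np.column_stack([cx, cy])

    truth.cell_onset_times = onsets
    # ground-truth ranks at frame resolution: the indicator response is
    # zero at the onset instant itself, so the first observable frame is
    # the first with ft > onset; cells sharing it tie (average ranks)
    onset_frames = np.searchsorted(ft, onsets, side="right")
    truth.cell_onset_frames = onset_frames
    truth.cell_ranks = sstats.rankdata(onset_frames, method="average")

    baseline = (0, int(config.baseline_s * config.frame_rate))
    return CalciumTraces(dff=dff, frame_rate=config.frame_rate,
                         centroids=centroids, baseline_epoch=baseline)


def generate_study(
    config: SynthConfig, n_seizures: int, seed: int | None = None
) -> list[tuple[GridRecording, CalciumTraces, GroundTruth]]:
    """Generate a set of paired seizures sharing the rank template.

    Per-seizure seeds are derived from ``seed`` (default: the config
    seed), so seizures differ in noise and rank perturbation but share
    the planted recruitment template and wave-direction distribution.
    """
    if n_seizures < 1:
        raise ValueError("n_seizures must be >= 1")
    base = config.seed if seed is None else seed
    out = []
    for k in range(n_seizures):
        child = int(np.random.SeedSequence(base, spawn_key=(100 + k,)).generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=child)
        rec, truth = generate_lfp(cfg)
        traces = generate_calcium(cfg, truth)
        out.append((rec, traces, truth))
    return out


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["grid_shape"] = list(d["grid_shape"])
    return d
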