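"""Calcium transient onsets, recruitment order, and reliability.

Given ΔF/F traces (cells x frames) this module detects each cell's
seizure-onset frame against a per-cell baseline threshold, ranks the
recruited cells by onset time, measures the recruitment duration
(last onset minus first onset), quantifies the reproducibility of
recruitment order across seizures (pairwise Spearman r and Kendall's W
with a permutation null), and summarizes the spatial progression of
onsets as a 2-D onset-direction vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import CalciumTraces

logger = logging.getLogger(__name__)

NOT_RECRUITED = -1
SG_WINDOW = 7
SG_ORDER = 2


def compute_dff(raw_f: np.ndarray, baseline_epoch: tuple[int, int],
                frame_rate: float, centroids: np.ndarray) -> CalciumTraces:
    """Normalize raw fluorescence to the preseizure baseline.

    ΔF/F[c, t] = (F[c, t] − F0[c]) / F0[c] with F0 the per-cell mean
    over ``baseline_epoch``.
    """
    raw_f = np.asarray(raw_f, dtype=float)
    lo, hi = baseline_epoch
    f0 = raw_f[:, lo:hi].mean(axis=1)
    if np.any(f0 <= 0):
        bad = np.where(f0 <= 0)[0]
        raise ValueError(f"non-positive baseline for cells {bad.tolist()}")
    dff = (raw_f - f0[:, None]) / f0[:, None]
    return CalciumTraces(dff=dff, frame_rate=frame_rate,
                         centroids=centroids, baseline_epoch=baseline_epoch)


def smooth_traces(traces: CalciumTraces) -> CalciumTraces:
    """Second-order Savitzky–Golay smoothing, window length 7.

    Leaves any quadratic series unchanged on interior frames; edges are
    handled by the polynomial fit on the truncated window.
    """
    if traces.n_frames < SG_WINDOW:
        raise ValueError(f"need at least {SG_WINDOW} frames")
    sm = sps.savgol_filter(traces.dff, SG_WINDOW, SG_ORDER, axis=1, mode="interp")
    return CalciumTraces(dff=sm, frame_rate=traces.frame_rate,
                         centroids=traces.centroids,
                         baseline_epoch=traces.baseline_epoch)


@dataclass
class OnsetResult:
    """Per-cell onset detection for one seizure.

    ``onset_frame`` is ``NOT_RECRUITED`` (-1) for cells that never
    cross their threshold inside the analysis window; ``ranks`` is NaN
    for those cells and fractional (average-tie) over recruited cells
    otherwise.
    """

    onset_frame: np.ndarray          # int per cell, NOT_RECRUITED if absent
    onset_threshold: np.ndarray      # ΔF/F per cell
    ranks: np.ndarray                # float per cell, NaN if not recruited
    recruitment_duration_s: float
    analysis_window: tuple[int, int]
    frame_rate: float
    excluded_cells: list[int] = field(default_factory=list)

    @property
    def recruited(self) -> np.ndarray:
        return self.onset_frame != NOT_RECRUITED

    def onset_times(self) -> np.ndarray:
        t = np.full(self.onset_frame.shape, np.nan)
        m = self.recruited
        t[m] = self.onset_frame[m] / self.frame_rate
        return t


def select_onset_window(traces: CalciumTraces, length: int = 80,
                        n_baseline: int = 25, k: float = 5.0,
                        n_pre: int = 5) -> tuple[int, int]:
    """Automatic analysis window containing the optical seizure onset.

    Finds where the population-mean ΔF/F first exceeds its own baseline
    mean + k·SD and opens a ``length``-frame window starting ``n_pre``
    frames earlier, so the window contains the onset near its start.
    Keeping the pre-onset stretch short matters: every pre-onset frame
    inside the window is a chance for a spurious threshold crossing,
    whatever the threshold multiple, since thresholds scale with the
    baseline noise.  The window is clipped so at least ``n_baseline``
    frames precede it.
    """
    pop = traces.dff.mean(axis=0)
    lo, hi = traces.baseline_epoch
    base = pop[lo:hi]
    thr = base.mean() + k * np.std(base, ddof=1)
    after = np.where(pop[hi:] > thr)[0]
    if after.size == 0:
        raise ValueError("population mean never exceeds baseline threshold")
    onset_idx = hi + int(after[0])
    start = max(n_baseline, onset_idx - n_pre)
    stop = min(traces.n_frames, start + length)
    return (start, stop)


def detect_onsets(traces: CalciumTraces, window: tuple[int, int] | None = None,
                  n_baseline: int = 25, k: float = 5.0) -> OnsetResult:
    """Per-cell onset frames against mean + k·SD baseline thresholds.

    The threshold for each cell uses the ``n_baseline`` frames
    immediately preceding the window; the onset is the first frame in
    the window whose ΔF/F exceeds it.  Cells whose baseline SD is zero
    are excluded with a warning; cells never crossing threshold are
    marked not recruited.
    """
    if window is None:
        window = select_onset_window(traces, n_baseline=n_baseline, k=k)
    start, stop = window
    if start < n_baseline:
        raise ValueError(f"window start {start} leaves < {n_baseline} baseline frames")
    if stop <= start or stop > traces.n_frames:
        raise ValueError("invalid analysis window")

    n_cells = traces.n_cells
    onset = np.full(n_cells, NOT_RECRUITED, dtype=int)
    thr = np.full(n_cells, np.nan)
    excluded: list[int] = []
    for c in range(n_cells):
        base = traces.dff[c, start - n_baseline:start]
        sd = np.std(base, ddof=1)
        if sd == 0:
            excluded.append(c)
            logger.warning("cell %d: degenerate baseline (SD = 0); excluded", c)
            continue
        thr[c] = base.mean() + k * sd
        above = np.where(traces.dff[c, start:stop] > thr[c])[0]
        if above.size:
            onset[c] = start + int(above[0])

    recruited = onset != NOT_RECRUITED
    ranks = np.full(n_cells, np.nan)
    if recruited.any():
        ranks[recruited] = stats.rankdata(onset[recruited], method="average")
        dur = (onset[recruited].max() - onset[recruited].min()) / traces.frame_rate
    else:
        dur = 0.0
    return OnsetResult(onset_frame=onset, onset_threshold=thr, ranks=ranks,
                       recruitment_duration_s=float(dur), analysis_window=window,
                       frame_rate=traces.frame_rate, excluded_cells=excluded)


@dataclass
class ReliabilityResult:
    """Recruitment-order reproducibility across seizures."""

    spearman_r: np.ndarray   # (n_seiz, n_seiz), unit diagonal
    spearman_p: np.ndarray
    kendall_w: float
    kendall_p: float
    n_permutations: int
    n_common_cells: int


def kendalls_w(rank_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance, tie-corrected.

    ``rank_matrix`` is cells x seizures; each column holds (possibly
    fractional) ranks of the n cells in one seizure.
    """
    R = np.asarray(rank_matrix, dtype=float)
    n, m = R.shape
    totals = R.sum(axis=1)
    S = np.sum((totals - totals.mean()) ** 2)
    T = 0.0
    for j in range(m):
        _, counts = np.unique(R[:, j], return_counts=True)
        T += np.sum(counts**3 - counts)
    denom = m**2 * (n**3 - n) - m * T
    if denom <= 0:
        raise ValueError("degenerate rank matrix (all ties)")
    return float(12.0 * S / denom)


def _null_rank_matrix(shape: tuple[int, int], max_ranks: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """One shuffled matrix: each seizure's ranks re-drawn independently."""
    n, m = shape
    out = np.empty((n, m))
    for j in range(m):
        top = int(round(max_ranks[j]))
        if top >= n:
            out[:, j] = rng.permutation(n) + 1
        else:  # ties compressed the observed range: draw from 1..max
            out[:, j] = rng.integers(1, top + 1, n)
    return out


def rank_reliability(rank_matrix: np.ndarray, n_perm: int = 1000,
                     seed: int | None = 0) -> ReliabilityResult:
    """Spearman pairs, Kendall's W, and a permutation p for W.

    ``rank_matrix`` is cells x seizures with NaN for cells not
    recruited in a seizure.  Spearman r/p are computed per seizure pair
    over cells recruited in both (large-sample p); Kendall's W uses
    cells recruited in every seizure, re-ranked within that common
    subset.  The permutation null re-draws each seizure's ranks as a
    random permutation of 1..max observed rank; the p-value is the
    fraction of null matrices with W >= observed, with the +1
    adjustment keeping it in (0, 1].
    """
    R = np.asarray(rank_matrix, dtype=float)
    n_cells, n_seiz = R.shape
    if n_seiz < 2:
        raise ValueError("need at least 2 seizures")
    common = ~np.isnan(R).any(axis=1)
    if common.sum() < 3:
        raise ValueError("insufficient overlap: fewer than 3 commonly recruited cells")

    r_mat = np.eye(n_seiz)
    p_mat = np.zeros((n_seiz, n_seiz))
    for i in range(n_seiz):
        for j in range(i + 1, n_seiz):
            both = ~np.isnan(R[:, i]) & ~np.isnan(R[:, j])
            if both.sum() < 3:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(R[both, i], R[both, j])
            r_mat[i, j] = r_mat[j, i] = r
            p_mat[i, j] = p_mat[j, i] = p

    # re-rank within the commonly recruited subset
    sub = np.column_stack([
        stats.rankdata(R[common, j], method="average") for j in range(n_seiz)
    ])
    w = kendalls_w(sub)

    rng = np.random.default_rng(seed)
    max_ranks = sub.max(axis=0)
    exceed = 0
    for _ in range(n_perm):
        w_null = kendalls_w(_null_rank_matrix(sub.shape, max_ranks, rng))
        if w_null >= w:
            exceed += 1
    p_perm = (exceed + 1) / (n_perm + 1)
    return ReliabilityResult(spearman_r=r_mat, spearman_p=p_mat,
                             kendall_w=w, kendall_p=float(p_perm),
                             n_permutations=n_perm,
                             n_common_cells=int(common.sum()))


@dataclass
class OnsetVector:
    """Spatial onset-progression vector for one seizure.

    ``raw_vector`` runs from the mean centroid of the first-recruited
    cells (x1) to the mean centroid of the last-recruited cells (x2) in
    imaging-frame coordinates; ``anatomical_vector`` applies the
    reflection about the x-axis and a signed rotation that map the
    imaging frame onto anatomical axes.
    """

    x1: np.ndarray
    x2: np.ndarray
    raw_vector: np.ndarray
    anatomical_vector: np.ndarray
    direction_rad: float


def onset_direction(onsets: OnsetResult, centroids: np.ndarray,
                    rotation_deg: float = 30.0) -> OnsetVector:
    """Onset-direction vector from first- to last-recruited centroids.

    The imaging-to-anatomy transform reflects the raw vector about the
    x-axis and rotates it by ``rotation_deg`` (positive =
    counterclockwise, toward +y); the magnitude is preserved.
    """
    ranks = onsets.ranks
    rec = onsets.recruited
    if not rec.any():
        raise ValueError("no recruited cells")
    rmin, rmax = np.nanmin(ranks), np.nanmax(ranks)
    if rmin == rmax:
        raise ValueError("no rank spread: all recruited cells share one rank")
    centroids = np.asarray(centroids, dtype=float)
    x1 = centroids[np.where(ranks == rmin)[0]].mean(axis=0)
    x2 = centroids[np.where(ranks == rmax)[0]].mean(axis=0)
    raw = x2 - x1
    reflected = np.array([raw[0], -raw[1]])
    ang = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    anat = rot @ reflected
    return OnsetVector(x1=x1, x2=x2, raw_vector=raw, anatomical_vector=anat,
                       direction_rad=float(np.arctan2(anat[1], anat[0])))
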