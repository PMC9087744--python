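"""Discharge detection, plane fitting, and wave statistics."""

import numpy as np
import pandas as pd
import pytest

from ictalwave import ephys as ep
from ictalwave import synth
from ictalwave import waves as wv
from conftest import extract_events


def grid_geometry(n=4, pitch=0.5):
    rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return pd.DataFrame({
        "channel": np.arange(n * n),
        "x_mm": cc.ravel() * pitch,
        "y_mm": rr.ravel() * pitch,
        "functional": True,
    })


def event_from_plane(a, b, c, geom, jitter=None):
    x = geom["x_mm"].to_numpy()
    y = geom["y_mm"].to_numpy()
    t = a * x + b * y + c
    if jitter is not None:
        t = t + jitter
    pts = np.column_stack([x, y, t])
    return wv.DischargeEvent(channels=geom["channel"].to_numpy(), points=pts,
                             amplitudes=np.ones(len(pts)))


class TestFitPlane:
    def test_exact_plane_along_x(self):
        ev = wv.fit_plane(event_from_plane(0.002, 0.0, 1.0, grid_geometry()))
        assert ev.direction_rad == pytest.approx(0.0, abs=1e-12)
        assert ev.speed_mm_s == pytest.approx(500.0)
        assert ev.residual_rms == pytest.approx(0.0, abs=1e-12)
        assert ev.speed_m_s == pytest.approx(0.5)

    def test_simultaneous_discharge_degenerate(self):
        ev = wv.fit_plane(event_from_plane(0.0, 0.0, 2.0, grid_geometry()))
        assert ev.degenerate
        assert np.isnan(ev.speed_mm_s)

    def test_diagonal_plane_recovered_exactly(self):
        v, th = 250.0, np.deg2rad(45.0)
        a, b = np.cos(th) / v, np.sin(th) / v
        ev = wv.fit_plane(event_from_plane(a, b, 0.0, grid_geometry()))
        assert ev.direction_rad == pytest.approx(th, abs=1e-6)
        assert ev.speed_mm_s == pytest.approx(v, rel=1e-6)

    def test_collinear_positions_rejected(self):
        geom = pd.DataFrame({"channel": [0, 1, 2],
                             "x_mm": [0.0, 1.0, 2.0],
                             "y_mm": [0.0, 1.0, 2.0],
                             "functional": True})
        with pytest.raises(ValueError, match="rank-deficient"):
            wv.fit_plane(event_from_plane(0.001, 0.0, 0.0, geom))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 17)
            pts = np.column_stack([rng.uniform(0, 2, n), rng.uniform(0, 2, n),
                                   rng.normal(0, 0.01, n)])
            ev = wv.DischargeEvent(channels=np.arange(n), points=pts,
                                   amplitudes=np.ones(n))
            A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(n)])
            if np.linalg.matrix_rank(A) < 3:
                continue
            oracle = np.linalg.inv(A.T @ A) @ A.T @ pts[:, 2]
            fitted = wv.fit_plane(ev).plane
            assert np.allclose(fitted, oracle, rtol=1e-10, atol=1e-12)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        geom = grid_geometry()
        v, th = 300.0, 0.4
        a, b = np.cos(th) / v, np.sin(th) / v
        ev = wv.fit_plane(event_from_plane(a, b, 0.0, geom,
                                           jitter=rng.normal(0, 1e-4, 16)))
        rho = 0.9
        R = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
        xy = geom[["x_mm", "y_mm"]].to_numpy() @ R.T
        geom2 = geom.copy()
        geom2["x_mm"], geom2["y_mm"] = xy[:, 0], xy[:, 1]
        pts2 = np.column_stack([xy, ev.points[:, 2]])
        ev2 = wv.fit_plane(wv.DischargeEvent(channels=ev.channels, points=pts2,
                                             amplitudes=ev.amplitudes))
        assert ev2.direction_rad == pytest.approx(ev.direction_rad + rho, abs=1e-9)
        assert ev2.speed_mm_s == pytest.approx(ev.speed_mm_s, rel=1e-9)


class TestDetectPeaks:
    def test_subthreshold_sinusoid_ignored(self):
        # |sin| has mean 2/π and SD ~0.31: a pure sinusoid never exceeds
        # mean + 2 SD of its own rectification
        t = np.arange(20000) / 2000.0
        band = ep.BandSignal(samples=np.sin(2 * np.pi * 10 * t), rate=2000.0,
                             band=(4.0, 30.0))
        times, _ = wv.detect_discharge_peaks(band)
        assert times.size == 0

    def test_rescaling_leaves_peak_times(self):
        cfg = synth.SynthConfig(seed=2, duration_s=20.0)
        rec, _ = synth.generate_lfp(cfg)
        y, fs = ep.downsample(rec.signals[0], rec.rate)
        t1, _ = wv.detect_discharge_peaks(ep.BandSignal(y, fs, (4.0, 30.0)))
        t3, _ = wv.detect_discharge_peaks(ep.BandSignal(3 * y, fs, (4.0, 30.0)))
        assert np.array_equal(t1, t3)

    def test_every_planted_discharge_detected(self):
        # each planted wavelet yields a suprathreshold peak at its
        # center (side cycles may add peaks; grouping collapses them —
        # one grouped event per planted discharge)
        cfg = synth.SynthConfig(seed=3, duration_s=30.0, noise_sd_ephys=0.0,
                                hg_amp_uv=0.0, n_mua_per_discharge=0)
        rec, truth = synth.generate_lfp(cfg)
        y, fs = ep.downsample(rec.signals[0], rec.rate)
        times, _ = wv.detect_discharge_peaks(ep.bandpass(y, fs, ep.LOW_BAND))
        for tp in truth.peak_times[:, 0]:
            assert np.min(np.abs(times - tp)) < 0.002
        events = extract_events(rec)
        assert len(events) == truth.discharge_times.size


class TestGrouping:
    def _peaks(self, per_channel):
        times = [np.asarray(t, dtype=float) for t in per_channel]
        amps = [np.ones_like(t) for t in times]
        return times, amps

    def test_tight_cluster_one_event(self):
        geom = grid_geometry()
        times, amps = self._peaks([[10.0 + 0.001 * i] for i in range(16)])
        events = wv.group_discharges(times, amps, geom)
        assert len(events) == 1
        assert events[0].n_channels == 16

    def test_half_coverage_discarded(self):
        geom = grid_geometry()
        times, amps = self._peaks([[10.0]] * 8 + [[]] * 8)
        assert wv.group_discharges(times, amps, geom) == []

    def test_two_separated_events(self):
        geom = grid_geometry()
        times, amps = self._peaks([[10.0, 11.0]] * 16)
        events = wv.group_discharges(times, amps, geom)
        assert len(events) == 2

    def test_largest_amplitude_wins_within_event(self):
        geom = grid_geometry()
        times = [np.array([10.0, 10.05])] + [np.array([10.0])] * 15
        amps = [np.array([1.0, 5.0])] + [np.array([1.0])] * 15
        events = wv.group_discharges(times, amps, geom)
        ch0 = events[0].points[events[0].channels == 0]
        assert ch0[0, 2] == 10.05


class TestDirectionStats:
    def _events(self, dirs):
        out = []
        for i, d in enumerate(dirs):
            ev = wv.DischargeEvent(channels=np.arange(3),
                                   points=np.zeros((3, 3)),
                                   amplitudes=np.ones(3))
            ev.direction_rad = d
            ev.speed_mm_s = 100.0
            ev.points[:, 2] = i
            out.append(ev)
        return out

    def test_identical_directions_nonuniform(self):
        report = wv.direction_stats({"a": self._events(np.full(20, 0.5))})
        assert report["datasets"]["a"]["omnibus_p"] < 0.001

    def test_dataset_vs_itself_ks(self):
        rng = np.random.default_rng(5)
        evs = self._events(rng.vonmises(0, 2, 30))
        report = wv.direction_stats({"a": evs, "b": evs})
        pair = report["pairs"]["a|b"]
        assert pair["ks_stat"] == 0.0
        assert pair["ks_p"] == pytest.approx(1.0)

    def test_same_distribution_rarely_rejected(self):
        rng = np.random.default_rng(6)
        rejections = 0
        for _ in range(100):
            a = self._events(rng.vonmises(0.3, 2, 40))
            b = self._events(rng.vonmises(0.3, 2, 40))
            p = wv.direction_stats({"a": a, "b": b})["pairs"]["a|b"]["ks_p"]
            rejections += p < 0.05
        assert rejections <= 10

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            wv.direction_stats({"a": self._events(np.zeros(5))})


class TestSpeedEpochs:
    def _events(self, times, speeds):
        out = []
        for t, v in zip(times, speeds):
            ev = wv.DischargeEvent(channels=np.arange(3),
                                   points=np.column_stack([np.zeros(3), np.zeros(3),
                                                           np.full(3, t)]),
                                   amplitudes=np.ones(3))
            ev.speed_mm_s = v
            ev.direction_rad = 0.0
            out.append(ev)
        return out

    def test_decreasing_speeds_rejected(self):
        t = np.linspace(0, 100, 100)
        v = np.linspace(500, 200, 100)
        cmp_ = wv.speed_epoch_comparison(self._events(t, v))
        assert cmp_.p_value < 0.01
        assert cmp_.median_last < cmp_.median_first

    def test_identical_epochs_p_one(self):
        t = np.linspace(0, 100, 20)
        v = np.tile([300.0, 300.0, 300.0, 300.0], 5)
        cmp_ = wv.speed_epoch_comparison(self._events(t, v))
        assert cmp_.p_value == 1.0

    def test_constant_speed_calibrated(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 100, 100)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            v = 300.0 + rng.normal(0, 30.0, 100)
            if wv.speed_epoch_comparison(self._events(t, v)).p_value < 0.05:
                rej += 1
        assert 0.03 <= rej / n_rep <= 0.07

    def test_sparse_epoch_rejected(self):
        with pytest.raises(ValueError):
            wv.speed_epoch_comparison(self._events([0, 1, 50, 99], [1, 2, 3, 4]))


def test_recovery_under_noise(evolving_study):
    """Planted plane waves recovered from the raw synthetic LFP."""
    rec, _, truth = evolving_study[0]
    events = extract_events(rec)
    assert len(events) == truth.discharge_times.size
    det = np.array([ev.t_center for ev in events])
    planted = np.sort(truth.peak_times.mean(axis=1))
    assert np.allclose(np.sort(det), planted, atol=0.05)
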