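"""Shared fixtures: synthetic studies generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ictalwave import synth
from ictalwave import ephys as ep
from ictalwave import features as ft
from ictalwave import waves as wv


def extract_events(rec):
    """Downsample, band-pass, and fit discharge planes for one recording."""
    bands = []
    for c in range(rec.n_channels):
        y, fs = ep.downsample(rec.signals[c], rec.rate)
        bands.append(ep.bandpass(y, fs, ep.LOW_BAND, channel_id=c))
    return wv.extract_discharges(rec, bands)


def study_tables(study, channel: int = 5):
    """Discharge events and feature tables for every seizure of a study."""
    events_list, tables = [], []
    for i, (rec, tr, truth) in enumerate(study):
        events = extract_events(rec)
        events_list.append(events)
        t_ev = [e.t_center for e in events]
        tables.append(ft.build_feature_table(
            rec, tr, events, channel=channel, span=(min(t_ev), max(t_ev)),
            seizure_id=f"seizure_{i}"))
    return events_list, tables


@pytest.fixture(scope="session")
def evolving_study():
    """Four 2-minute seizures with slowing waves and speed-coupled calcium.

    speed_trend < 1 makes later discharges slower; the calcium
    transient amplitude follows the planted speed, so imaging features
    carry speed information while high-γ burst amplitude stays flat.
    """
    cfg = synth.SynthConfig(seed=21, duration_s=120.0, speed_trend=0.997,
                            calcium_speed_coupling=1.5)
    return synth.generate_study(cfg, 4, seed=21)


@pytest.fixture(scope="session")
def evolving_events_tables(evolving_study):
    return study_tables(evolving_study)


@pytest.fixture(scope="session")
def default_seizure():
    """One seizure at generator defaults (constant speed, 60 s)."""
    cfg = synth.SynthConfig(seed=5)
    rec, truth = synth.generate_lfp(cfg)
    traces = synth.generate_calcium(cfg, truth)
    return cfg, rec, traces, truth
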