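"""One-command end-to-end pipeline over a synthetic study or bundles.

Stage order mirrors the analysis workflow: simulate (optional) →
calcium onsets/reliability → phase coupling → traveling waves →
windowed features → speed model → feature-evolution comparison.  Each
stage writes its outputs before the next starts, so a failure leaves
prior outputs intact and is reported with the stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calcium as ca
from . import circstats as cs
from . import ephys as ep
from . import features as ft
from . import model as md
from . import synth
from . import waves as wv
from .io import write_bundle

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Every analysis default in one place, plus the master seed."""

    out_dir: str = "ictalwave_out"
    seed: int = 0
    # input: either existing bundles or a synthetic study
    bundles: list[str] = field(default_factory=list)
    n_seizures: int = 4
    synth: dict = field(default_factory=dict)   # SynthConfig overrides
    # analysis parameters (defaults match the module-level conventions)
    onset_k: float = 5.0
    onset_n_baseline: int = 25
    hg_k: float = 2.5
    n_perm: int = 1000
    max_gap_s: float = 0.150
    min_frac: float = 0.6
    window_s: float = 4.0
    step_s: float = 3.0
    feature_channel: int = 5   # channel above the imaging plane
    n_ensembles: int = 200
    n_trees: int = 50
    cv_folds: int = 5
    epoch_frac: float = 0.25

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)


def _write(report: RunReport, out: Path, name: str, obj) -> Path:
    path = out / name
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    else:
        with open(path, "w") as f:
            json.dump(obj, f, indent=2, default=_jsonable)
    report.outputs.append(str(path))
    return path


def _jsonable(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer, np.floating, np.bool_)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; returns the run report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed,
                       version=__version__)
    stage = "simulate"
    try:
        if config.bundles:
            from .io import read_bundle
            study = []
            for p in config.bundles:
                rec, tr, truth, sync = read_bundle(p)
                study.append((rec, tr, truth))
        else:
            scfg = synth.SynthConfig(seed=config.seed, **config.synth)
            study = synth.generate_study(scfg, config.n_seizures, seed=config.seed)
            for i, (rec, tr, truth) in enumerate(study):
                p = out / f"seizure_{i}.h5"
                write_bundle(p, rec, tr, truth)
                report.outputs.append(str(p))
        report.counts["n_seizures"] = len(study)

        stage = "onsets"
        rank_cols, onset_rows = [], []
        for i, (rec, tr, truth) in enumerate(study):
            sm = ca.smooth_traces(tr)
            res = ca.detect_onsets(sm, n_baseline=config.onset_n_baseline,
                                   k=config.onset_k)
            rank_cols.append(res.ranks)
            for c in range(tr.n_cells):
                onset_rows.append({
                    "seizure": i, "cell": c, "onset_frame": res.onset_frame[c],
                    "rank": res.ranks[c], "threshold": res.onset_threshold[c],
                    "recruitment_duration_s": res.recruitment_duration_s,
                })
        _write(report, out, "onsets.csv", pd.DataFrame(onset_rows))
        if len(study) >= 2:
            rel = ca.rank_reliability(np.column_stack(rank_cols),
                                      n_perm=config.n_perm, seed=config.seed)
            _write(report, out, "reliability.json", {
                "spearman_r": rel.spearman_r, "spearman_p": rel.spearman_p,
                "kendall_w": rel.kendall_w, "kendall_p": rel.kendall_p,
                "n_permutations": rel.n_permutations,
                "n_common_cells": rel.n_common_cells,
            })

        stage = "phase"
        rng = np.random.default_rng(config.seed)
        rec = study[0][0]
        ch = config.feature_channel
        x2k, fs = ep.downsample(rec.signals[ch], rec.rate)
        low = ep.analytic(ep.bandpass(x2k, fs, ep.LOW_BAND))
        hg = ep.analytic(ep.bandpass(x2k, fs, ep.HG_BAND))
        hg_times = ep.detect_hg_events(hg, k=config.hg_k)
        hg_sample = ep.phases_at_events(low, hg_times)
        spike = ep.bandpass(rec.signals[ch], rec.rate, ep.SPIKE_BAND)
        mua_times = ep.detect_mua(spike)
        low_native = ep.analytic(ep.bandpass(rec.signals[ch], rec.rate, ep.LOW_BAND))
        mua_sample = ep.phases_at_events(low_native, mua_times)
        ev_rows = [{"channel": ch, "time_s": t, "phase_rad": p, "kind": "hg"}
                   for t, p in zip(hg_sample.event_times, hg_sample.phases)]
        ev_rows += [{"channel": ch, "time_s": t, "phase_rad": p, "kind": "mua"}
                    for t, p in zip(mua_sample.event_times, mua_sample.phases)]
        _write(report, out, "phase_events.csv", pd.DataFrame(ev_rows))
        _write(report, out, "circular_tests.json", {
            "hg": cs.circular_tests(hg_sample.phases, rng=rng),
            "mua": cs.circular_tests(mua_sample.phases, rng=rng),
        })
        report.counts["n_hg_events"] = int(hg_sample.n_events)
        report.counts["n_mua_events"] = int(mua_sample.n_events)

        stage = "wave"
        study_events = []
        for i, (rec, tr, truth) in enumerate(study):
            bands = []
            for c in range(rec.n_channels):
                y, fs = ep.downsample(rec.signals[c], rec.rate)
                bands.append(ep.bandpass(y, fs, ep.LOW_BAND, channel_id=c))
            events = wv.extract_discharges(rec, bands, max_gap=config.max_gap_s,
                                           min_frac=config.min_frac)
            study_events.append(events)
        _write(report, out, "discharges.csv",
               pd.concat([wv.events_table(ev).assign(seizure=i)
                          for i, ev in enumerate(study_events)], ignore_index=True))
        _write(report, out, "wave_stats.json", wv.direction_stats(
            {f"seizure_{i}": ev for i, ev in enumerate(study_events)}))
        epochs = {}
        for i, ev in enumerate(study_events):
            try:
                cmp_ = wv.speed_epoch_comparison(ev, frac=config.epoch_frac)
                epochs[f"seizure_{i}"] = dataclasses.asdict(cmp_)
            except ValueError as e:
                report.warnings.append(f"seizure {i} epoch comparison: {e}")
        _write(report, out, "speed_epochs.json", epochs)
        report.counts["n_discharges"] = sum(len(e) for e in study_events)

        stage = "features"
        tables = []
        for i, ((rec, tr, truth), events) in enumerate(zip(study, study_events)):
            t_ev = [ev.t_center for ev in events]
            span = (min(t_ev), max(t_ev)) if t_ev else None
            t = ft.build_feature_table(rec, tr, events, channel=config.feature_channel,
                                       win=config.window_s, step=config.step_s,
                                       span=span, seizure_id=f"seizure_{i}")
            tables.append(t)
            _write(report, out, f"features_seizure_{i}.csv", t)
        report.counts["n_windows"] = sum(len(t) for t in tables)

        stage = "model"
        if len(tables) >= 4:
            train_tables, withheld = tables[:3], tables[3]
            training = md.assemble_training(train_tables, seed=config.seed)
            models = md.train_ensembles(training, n_ensembles=config.n_ensembles,
                                        n_trees=config.n_trees,
                                        cv_folds=config.cv_folds, seed=config.seed)
            ev_report = md.evaluate(models, withheld, training=training)
            _write(report, out, "model_summary.json", {
                "cv_scores": [m.cv_score for m in models],
                "train_r": ev_report.train_r,
                "withheld_r": ev_report.withheld_r,
                "withheld_r_median": float(np.nanmedian(ev_report.withheld_r)),
                "withheld_r_top_median":
                    float(np.nanmedian(ev_report.withheld_r[ev_report.top_indices])),
                "top_indices": ev_report.top_indices,
            })
            _write(report, out, "importance.csv", md.importance_table(ev_report))
        else:
            report.warnings.append("fewer than 4 seizures; model stage skipped")

        stage = "epochs"
        comp = md.feature_epoch_comparison(
            tables, ft.FEATURE_COLUMNS, frac=config.epoch_frac)
        _write(report, out, "feature_epochs.csv", comp)
    except Exception as e:
        report.failed_stage = stage
        report.to_json(out / "run_report.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    report.to_json(out / "run_report.json")
    report.outputs.append(str(out / "run_report.json"))
    return report
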