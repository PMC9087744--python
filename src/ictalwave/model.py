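"""Bagged regression trees predicting traveling-wave speed.

The learning task: predict the per-window median wave speed from the
ten windowed multimodal features.  Training data come from three
seizures, subsampled so each contributes equally; each "ensemble" is a
bagged forest (bootstrap-resampled CART trees, variance-reduction
splits, minimum leaf size 5) trained under 5-fold cross validation,
keeping the fold-model that best generalizes to its held-out fold.
Feature importance is the out-of-bag permutation delta error, averaged
over trees and divided by its SD over trees.  Generalization is the
Pearson r between observed and predicted speeds in a withheld seizure;
the top 10% of ensembles by that r are the "best generalizing" set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingRegressor
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor

from .features import CALCIUM_FEATURES, EPHYS_FEATURES, FEATURE_COLUMNS, TARGET_COLUMN
from ._stats import mann_whitney

logger = logging.getLogger(__name__)


@dataclass
class TrainingSet:
    """Balanced training matrix: k usable rows from each seizure."""

    X: np.ndarray
    y: np.ndarray
    seizure_labels: np.ndarray
    feature_names: list[str]
    k: int
    subsample_record: dict[str, np.ndarray] = field(default_factory=dict)


def usable_rows(table: pd.DataFrame, feature_names: list[str]) -> pd.DataFrame:
    """Rows with a target and finite features."""
    ok = table[TARGET_COLUMN].notna()
    for c in feature_names:
        ok &= np.isfinite(table[c])
    return table.loc[ok]


def assemble_training(tables: list[pd.DataFrame], seed: int = 0,
                      feature_names: list[str] | None = None) -> TrainingSet:
    """Equal-enrichment training set from the per-seizure tables.

    k is the usable row count of the smallest table; larger tables are
    subsampled uniformly without replacement to k rows.
    """
    feature_names = feature_names or FEATURE_COLUMNS
    rng = np.random.default_rng(seed)
    usable = [usable_rows(t, feature_names) for t in tables]
    for i, u in enumerate(usable):
        if len(u) < 5:
            raise ValueError(f"table {i} has {len(u)} usable rows (< 5)")
    k = min(len(u) for u in usable)
    X, y, labels, record = [], [], [], {}
    for i, u in enumerate(usable):
        idx = np.sort(rng.choice(len(u), size=k, replace=False))
        sel = u.iloc[idx]
        sid = u.attrs.get("seizure_id", str(i)) if hasattr(u, "attrs") else str(i)
        X.append(sel[feature_names].to_numpy(float))
        y.append(sel[TARGET_COLUMN].to_numpy(float))
        labels.extend([sid] * k)
        record[sid] = idx
    return TrainingSet(X=np.vstack(X), y=np.concatenate(y),
                       seizure_labels=np.array(labels),
                       feature_names=list(feature_names), k=k,
                       subsample_record=record)


@dataclass
class EnsembleModel:
    """One bagged forest (the best CV fold-model) and its metadata."""

    forest: BaggingRegressor
    X_fit: np.ndarray
    y_fit: np.ndarray
    cv_score: float
    seed: int
    importances: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict(X)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(stats.pearsonr(a, b)[0])


def _fit_forest(X, y, n_trees, min_leaf, seed, bootstrap=True) -> BaggingRegressor:
    forest = BaggingRegressor(
        estimator=DecisionTreeRegressor(min_samples_leaf=min_leaf),
        n_estimators=n_trees, bootstrap=bootstrap, random_state=seed)
    return forest.fit(X, y)


def train_ensembles(training: TrainingSet, n_ensembles: int = 200,
                    n_trees: int = 50, cv_folds: int = 5,
                    min_samples_leaf: int = 5, seed: int = 0) -> list[EnsembleModel]:
    """Train ``n_ensembles`` bagged forests with k-fold cross validation.

    For each ensemble the rows are split into ``cv_folds`` folds; one
    forest is fitted per fold on the complement and scored by Pearson r
    on the held-out fold; the best fold-model is kept.  Defaults are
    desk-scale (200 x 50); the full-scale configuration is 1000
    ensembles of 100 trees.
    """
    X, y = training.X, training.y
    if np.std(y) == 0:
        raise ValueError("degenerate target: constant speed")
    if len(y) < 2 * cv_folds:
        raise ValueError("too few rows for cross validation")
    ss = np.random.SeedSequence(seed)
    models = []
    for e, child in enumerate(ss.spawn(n_ensembles)):
        es = int(child.generate_state(1)[0] % (2**31))
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=es)
        best = None
        for f, (tr, va) in enumerate(kf.split(X)):
            forest = _fit_forest(X[tr], y[tr], n_trees, min_samples_leaf, es + f)
            r = _pearson(y[va], forest.predict(X[va]))
            score = -np.inf if np.isnan(r) else r
            if best is None or score > best[0]:
                best = (score, forest, tr)
        score, forest, tr = best
        models.append(EnsembleModel(forest=forest, X_fit=X[tr], y_fit=y[tr],
                                    cv_score=score, seed=es))
    return models


def oob_importance(model: EnsembleModel, permutation: str = "random") -> np.ndarray:
    """Out-of-bag permuted-predictor delta error, per feature.

    For every tree: squared-error on its out-of-bag rows, minus the
    same with one feature's OOB values permuted; the per-feature
    importance is the mean delta over trees divided by its SD over
    trees.  ``permutation="identity"`` is a test hook that leaves the
    values in place (all deltas are then exactly 0).
    """
    X, y = model.X_fit, model.y_fit
    n, p = X.shape
    rng = np.random.default_rng(model.seed)
    deltas = []
    for tree, samp in zip(model.forest.estimators_,
                          model.forest.estimators_samples_):
        oob = np.setdiff1d(np.arange(n), samp)
        if oob.size == 0:
            logger.warning("tree with empty OOB set skipped")
            continue
        Xo, yo = X[oob], y[oob]
        base = np.mean((tree.predict(Xo) - yo) ** 2)
        row = np.empty(p)
        for j in range(p):
            Xp = Xo.copy()
            if permutation == "random":
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
            err = np.mean((tree.predict(Xp) - yo) ** 2)
            row[j] = err - base
        deltas.append(row)
    if not deltas:
        raise ValueError("no trees with OOB rows")
    D = np.array(deltas)
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1) if len(D) > 1 else np.ones(p)
    imp = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    model.importances = imp
    return imp


@dataclass
class EvaluationReport:
    """Per-ensemble performance and importance summaries."""

    train_r: np.ndarray
    withheld_r: np.ndarray
    top_indices: np.ndarray
    importances: np.ndarray          # (n_models, n_features)
    importance_all: np.ndarray       # mean over all models
    importance_top: np.ndarray       # mean over top 10%
    feature_names: list[str]


def evaluate(models: list[EnsembleModel], withheld: pd.DataFrame,
             feature_names: list[str] | None = None,
             training: TrainingSet | None = None,
             top_frac: float = 0.1) -> EvaluationReport:
    """Withheld-seizure generalization and top-10% importance summary.

    Ensembles whose predictions are constant get an undefined r and
    rank last.  ``training`` (when given) supplies the rows for the
    training-set r; otherwise each model's own fit rows are used.
    """
    feature_names = feature_names or FEATURE_COLUMNS
    wh = usable_rows(withheld, feature_names)
    if len(wh) < 5:
        raise ValueError("withheld table has < 5 usable rows")
    Xw = wh[feature_names].to_numpy(float)
    yw = wh[TARGET_COLUMN].to_numpy(float)

    train_r, withheld_r, imps = [], [], []
    for m in models:
        if training is not None:
            train_r.append(_pearson(training.y, m.predict(training.X)))
        else:
            train_r.append(_pearson(m.y_fit, m.predict(m.X_fit)))
        withheld_r.append(_pearson(yw, m.predict(Xw)))
        imps.append(m.importances if m.importances is not None else oob_importance(m))
    withheld_r = np.array(withheld_r)
    order = np.argsort(np.where(np.isnan(withheld_r), -np.inf, withheld_r))[::-1]
    n_top = int(np.ceil(top_frac * len(models)))
    top = order[:n_top]
    imps = np.array(imps)
    return EvaluationReport(
        train_r=np.array(train_r), withheld_r=withheld_r, top_indices=top,
        importances=imps, importance_all=imps.mean(axis=0),
        importance_top=imps[top].mean(axis=0), feature_names=list(feature_names))


def importance_table(report: EvaluationReport) -> pd.DataFrame:
    return pd.DataFrame({
        "feature": report.feature_names,
        "importance_all_models": report.importance_all,
        "importance_top_10pct": report.importance_top,
    })


def feature_epoch_comparison(tables: list[pd.DataFrame],
                             feature_names: list[str],
                             frac: float = 0.25) -> pd.DataFrame:
    """Early vs. late evolution of features across seizures.

    Per seizure, each feature is min-max rescaled to [0, 1]; the first
    ``frac`` and last ``frac`` of the sliding windows are pooled across
    seizures and compared per feature with a two-sided Mann–Whitney U.
    A feature constant within a seizure cannot be rescaled and that
    seizure is excluded for it (logged).
    """
    rows = []
    for name in feature_names:
        first_pool, last_pool = [], []
        for i, t in enumerate(tables):
            v = t[name].to_numpy(float)
            v = v[np.isfinite(v)]
            n_epoch = int(np.ceil(frac * len(v)))
            if n_epoch < 3:
                raise ValueError(f"table {i}: fewer than 3 windows per epoch")
            lo, hi = v.min(), v.max()
            if hi == lo:
                logger.warning("feature %s constant in seizure %d; excluded", name, i)
                continue
            r = (v - lo) / (hi - lo)
            first_pool.append(r[:n_epoch])
            last_pool.append(r[-n_epoch:])
        if not first_pool:
            rows.append({"feature": name, "u_stat": np.nan, "p_value": np.nan,
                         "median_first": np.nan, "median_last": np.nan,
                         "n_first": 0, "n_last": 0})
            continue
        first = np.concatenate(first_pool)
        last = np.concatenate(last_pool)
        u, p = mann_whitney(first, last)
        rows.append({"feature": name, "u_stat": u, "p_value": p,
                     "median_first": float(np.median(first)),
                     "median_last": float(np.median(last)),
                     "n_first": int(first.size), "n_last": int(last.size)})
    return pd.DataFrame(rows)
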