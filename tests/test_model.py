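"""Bagged-tree speed model: training, importance, evaluation, epochs."""

import numpy as np
import pandas as pd
import pytest

from ictalwave import model as md
from ictalwave.features import FEATURE_COLUMNS, TARGET_COLUMN


def table_from(X, y):
    df = pd.DataFrame(X, columns=FEATURE_COLUMNS[: X.shape[1]])
    for c in FEATURE_COLUMNS[X.shape[1]:]:
        df[c] = 0.0
    df[TARGET_COLUMN] = y
    return df


def random_table(rng, n, informative=0):
    X = rng.normal(0, 1, (n, 10))
    y = X[:, informative] * 2.0 + rng.normal(0, 0.1, n)
    return table_from(X, y)


class TestAssemble:
    def test_balanced_subsampling(self):
        rng = np.random.default_rng(0)
        tables = [random_table(rng, n) for n in (40, 60, 80)]
        tr = md.assemble_training(tables, seed=1)
        assert tr.k == 40
        assert tr.X.shape == (120, 10)
        counts = pd.Series(tr.seizure_labels).value_counts()
        assert (counts == 40).all()

    def test_same_seed_identical(self):
        rng = np.random.default_rng(1)
        tables = [random_table(rng, n) for n in (30, 50, 50)]
        a = md.assemble_training(tables, seed=7)
        b = md.assemble_training(tables, seed=7)
        assert np.array_equal(a.X, b.X)

    def test_all_missing_targets_rejected(self):
        rng = np.random.default_rng(2)
        t = random_table(rng, 30)
        t[TARGET_COLUMN] = np.nan
        good = random_table(rng, 30)
        with pytest.raises(ValueError):
            md.assemble_training([t, good, good], seed=0)


class TestTraining:
    def test_monotone_relation_fit_closely(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (120, 10))
        y = 3.0 * X[:, 0]
        tr = md.TrainingSet(X=X, y=y, seizure_labels=np.zeros(120),
                            feature_names=list(FEATURE_COLUMNS), k=40)
        models = md.train_ensembles(tr, n_ensembles=3, n_trees=30, seed=0)
        from scipy.stats import pearsonr
        r = pearsonr(y, models[0].predict(X))[0]
        assert r >= 0.99

    def test_constant_target_rejected(self):
        tr = md.TrainingSet(X=np.random.default_rng(0).normal(size=(40, 10)),
                            y=np.ones(40), seizure_labels=np.zeros(40),
                            feature_names=list(FEATURE_COLUMNS), k=40)
        with pytest.raises(ValueError, match="degenerate target"):
            md.train_ensembles(tr, n_ensembles=1)

    def test_single_tree_matches_exhaustive_cart_oracle(self):
        # no bootstrap, one tree: predictions equal an exhaustive
        # variance-reduction CART grown by brute force
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 3))
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.05, 50)
        forest = md._fit_forest(X, y, n_trees=1, min_leaf=5, seed=0,
                                bootstrap=False)

        def grow(idx):
            node_y = y[idx]
            best = None
            for j in range(X.shape[1]):
                xs = np.sort(np.unique(X[idx, j]))
                for lo, hi in zip(xs[:-1], xs[1:]):
                    thr = (lo + hi) / 2
                    left = idx[X[idx, j] <= thr]
                    right = idx[X[idx, j] > thr]
                    if len(left) < 5 or len(right) < 5:
                        continue
                    sse = (np.sum((y[left] - y[left].mean()) ** 2)
                           + np.sum((y[right] - y[right].mean()) ** 2))
                    if best is None or sse < best[0]:
                        best = (sse, j, thr, left, right)
            if best is None:
                return ("leaf", node_y.mean())
            _, j, thr, left, right = best
            return ("split", j, thr, grow(left), grow(right))

        def predict(tree, x):
            while tree[0] == "split":
                _, j, thr, l, r = tree
                tree = l if x[j] <= thr else r
            return tree[1]

        oracle_tree = grow(np.arange(50))
        oracle = np.array([predict(oracle_tree, x) for x in X])
        assert np.allclose(forest.predict(X), oracle, atol=1e-9)

    def test_determinism(self):
        rng = np.random.default_rng(5)
        tables = [random_table(rng, 30) for _ in range(3)]
        wh = random_table(rng, 30)
        out = []
        for _ in range(2):
            tr = md.assemble_training(tables, seed=3)
            models = md.train_ensembles(tr, n_ensembles=4, n_trees=10, seed=3)
            rep = md.evaluate(models, wh, training=tr)
            out.append((rep.withheld_r.copy(), rep.importances.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])


class TestImportance:
    def _model(self, rng, n=80, n_trees=10):
        X = rng.normal(0, 1, (n, 2))
        y = 2.0 * X[:, 0] + rng.normal(0, 0.1, n)
        forest = md._fit_forest(X, y, n_trees=n_trees, min_leaf=5, seed=int(rng.integers(2**31)))
        return md.EnsembleModel(forest=forest, X_fit=X, y_fit=y, cv_score=0.0,
                                seed=int(rng.integers(2**31)))

    def test_identity_permutation_zero_deltas(self):
        rng = np.random.default_rng(6)
        m = self._model(rng)
        imp = md.oob_importance(m, permutation="identity")
        assert np.allclose(imp, 0.0)
        assert imp.shape == (2,)

    def test_informative_beats_noise_feature(self):
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            m = self._model(rng)
            imp = md.oob_importance(m)
            wins += imp[0] > imp[1]
        assert wins >= 95

    def test_bagging_reduces_test_error(self):
        rng = np.random.default_rng(8)
        better = 0
        for _ in range(20):
            X = rng.normal(0, 1, (100, 10))
            y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.3, 100)
            # large held-out set so the error estimate itself is stable
            Xt = rng.normal(0, 1, (1000, 10))
            yt = Xt[:, 0] + 0.5 * Xt[:, 1] + rng.normal(0, 0.3, 1000)
            s = int(rng.integers(2**31))
            forest = md._fit_forest(X, y, n_trees=25, min_leaf=5, seed=s)
            single = md._fit_forest(X, y, n_trees=1, min_leaf=5, seed=s,
                                    bootstrap=False)
            e_f = np.mean((forest.predict(Xt) - yt) ** 2)
            e_s = np.mean((single.predict(Xt) - yt) ** 2)
            better += e_f <= e_s
        assert better >= 18

    def test_uninformative_importance_near_zero(self):
        rng = np.random.default_rng(9)
        imps = []
        for _ in range(100):
            X = rng.normal(0, 1, (60, 2))
            y = 2.0 * X[:, 0] + rng.normal(0, 0.1, 60)
            forest = md._fit_forest(X, y, n_trees=10, min_leaf=5,
                                    seed=int(rng.integers(2**31)))
            m = md.EnsembleModel(forest=forest, X_fit=X, y_fit=y, cv_score=0.0,
                                 seed=int(rng.integers(2**31)))
            imps.append(md.oob_importance(m)[1])  # noise feature
        imps = np.array(imps)
        assert abs(imps.mean()) <= 2 * imps.std(ddof=1)


class TestEvaluate:
    def test_perfect_predictor_r_one_and_top_size(self):
        rng = np.random.default_rng(10)
        tables = [random_table(rng, 30) for _ in range(3)]
        wh = random_table(rng, 40)
        tr = md.assemble_training(tables, seed=0)
        models = md.train_ensembles(tr, n_ensembles=25, n_trees=10, seed=0)
        rep = md.evaluate(models, wh, training=tr)
        assert rep.top_indices.size == 3  # ceil(0.1 * 25)
        assert rep.importances.shape == (25, 10)
        assert np.all(rep.withheld_r[rep.top_indices] >=
                      np.nanmedian(rep.withheld_r) - 1e-12)


class TestEpochComparison:
    def _trend_table(self, rng, n=40, decreasing=True):
        X = rng.normal(0, 0.01, (n, 10))
        trend = np.linspace(1, 0, n) if decreasing else rng.normal(0.5, 0.05, n)
        X[:, 0] += trend
        return table_from(X, np.ones(n) + rng.normal(0, 0.1, n))

    def test_rescale_and_trend_detection(self):
        rng = np.random.default_rng(11)
        tables = [self._trend_table(rng) for _ in range(3)]
        rep = md.feature_epoch_comparison(tables, ["mean_hg_amp"])
        row = rep.iloc[0]
        assert row.p_value < 0.01
        assert row.median_last < row.median_first

    def test_minmax_rescale_values(self):
        t = table_from(np.column_stack([np.array([2.0, 4.0, 6.0] * 4)]
                                       + [np.zeros(12)] * 9),
                       np.ones(12))
        rep = md.feature_epoch_comparison([t], ["mean_hg_amp"], frac=0.25)
        # rescale of {2,4,6} tiles maps to {0,0.5,1}
        assert set(np.round([rep.iloc[0].median_first, rep.iloc[0].median_last], 3)) \
            <= {0.0, 0.5, 1.0}

    def test_identical_epochs_p_one(self):
        vals = np.tile([1.0, 2.0, 3.0, 4.0], 4)
        t = table_from(np.column_stack([vals] + [np.zeros(16)] * 9), np.ones(16))
        rep = md.feature_epoch_comparison([t], ["mean_hg_amp"], frac=0.25)
        assert rep.iloc[0].p_value == 1.0

    def test_constant_feature_excluded(self):
        t = table_from(np.zeros((20, 10)), np.ones(20))
        rep = md.feature_epoch_comparison([t], ["mean_hg_amp"])
        assert np.isnan(rep.iloc[0].p_value)
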