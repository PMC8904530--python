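import numpy as np
import pandas as pd
import pytest

import pvpstack as pv
from pvpstack.stacking import (
    MetaFeatureMatrix,
    binarize_cf,
    build_meta_features,
    concat_pcf,
    generate_pf,
    pf_for_new_data,
    rank_features,
    sweep_subsets,
)

from conftest import REDUCED_GRIDS


def _pf(values, columns=None):
    values = np.asarray(values, dtype=float)
    cols = columns or [f"m{j}" for j in range(values.shape[1])]
    return MetaFeatureMatrix("PF", pd.DataFrame(values, columns=cols))


class TestBinarizeAndConcat:
    def test_threshold_strictly_greater(self):
        cf = binarize_cf(_pf([[0.7, 0.5, 0.3]]))
        np.testing.assert_array_equal(cf.values, [[1.0, 0.0, 0.0]])

    def test_pcf_concatenation(self):
        pf = _pf([[0.9, 0.2], [0.4, 0.6]])
        cf = binarize_cf(pf)
        pcf = concat_pcf(pf, cf)
        assert pcf.kind == "PCF"
        assert pcf.frame.shape == (2, 4)
        np.testing.assert_array_equal(pcf.values[:, :2], pf.values)
        # block names disambiguated
        assert pcf.columns == ["m0", "m1", "m0.CF", "m1.CF"]

    def test_shape_mismatch_errors(self):
        pf = _pf([[0.9, 0.2]])
        cf = binarize_cf(_pf([[0.9, 0.2], [0.1, 0.3]]))
        with pytest.raises(ValueError):
            concat_pcf(pf, cf)

    def test_pf_range_validated(self):
        with pytest.raises(ValueError, match="PF"):
            _pf([[1.5, 0.2]])


class TestGeneratePf:
    def test_shapes_and_range(self, small_pool):
        pool, feats, labels = small_pool
        pf = generate_pf(pool, feats, labels, folds=5, seed=11)
        assert pf.frame.shape == (len(labels), len(pool))
        assert pf.columns == pool.member_names
        assert np.all((pf.values >= 0) & (pf.values <= 1))
        pcf = build_meta_features(pf, "PCF")
        assert pcf.frame.shape == (len(labels), 2 * len(pool))

    def test_separable_members_separate_classes(self, small_pool):
        pool, feats, labels = small_pool
        pf = generate_pf(pool, feats, labels, folds=5, seed=11)
        y = np.asarray(labels)
        col = pf.frame["RF-AAC"].to_numpy()
        assert col[y == 1].mean() - col[y == 0].mean() > 0.5

    def test_out_of_fold_blocks_memorization(self):
        """A 1-NN memorizer on random labels scores ~chance out-of-fold but
        perfectly in-sample — the leakage-control contrast."""
        rng = np.random.default_rng(5)
        n = 60
        y = np.array([0, 1] * (n // 2))
        X = pd.DataFrame(rng.random((n, 4)), index=[f"s{i}" for i in range(n)])
        X.attrs["descriptor"] = "AAC"
        feats = {"AAC": X}
        pool = pv.train_pool(
            feats, y, seed=5, folds=5,
            grids={"KNN": {"n_neighbors": [1]}}, algorithms=["KNN"],
        )
        oof = generate_pf(pool, feats, y, folds=5, seed=5)
        insample = generate_pf(pool, feats, y, folds=5, seed=5, mode="in-sample")
        np.testing.assert_array_equal(insample.values.ravel(), y)  # memorized
        oof_acc = np.mean((oof.values.ravel() > 0.5) == y)
        assert oof_acc < 0.75  # random labels cannot be predicted out-of-fold

    def test_new_data_featurization(self, small_pool, small_dataset):
        pool, feats, labels = small_pool
        records, profiles = small_dataset
        new = pv.encode_all(records[:7], profiles, ["AAC", "CTDC", "PSSM_AAC"])
        pf = pf_for_new_data(pool, new)
        assert pf.frame.shape == (7, len(pool))
        assert np.all((pf.values >= 0) & (pf.values <= 1))
        pf2 = pf_for_new_data(pool, new)
        np.testing.assert_array_equal(pf.values, pf2.values)  # deterministic

    def test_missing_descriptor_errors(self, small_pool):
        pool, feats, labels = small_pool
        partial = {k: v for k, v in feats.items() if k != "CTDC"}
        with pytest.raises(ValueError, match="CTDC"):
            pf_for_new_data(pool, partial)


class TestRankFeatures:
    def test_label_identical_column_ranks_first(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 40)
        X = rng.random((80, 12))
        X[:, 7] = np.clip(y * 0.9 + 0.05, 0, 1)  # label-identical up to scale
        ranking = rank_features(_pf(X), y, seed=0)
        assert ranking[0] == 7
        assert sorted(ranking) == list(range(12))  # a permutation

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        y = np.array([0, 1] * 30)
        X = rng.random((60, 8))
        a = rank_features(_pf(X), y, seed=3)
        b = rank_features(_pf(X), y, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            rank_features(_pf(np.random.default_rng(0).random((10, 3))), [1] * 10)


class TestSweepSubsets:
    def _signal_data(self, n=80, d=20, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        X = rng.random((n, d))
        X[:, 0] = np.clip(y * 0.8 + 0.1 + rng.normal(0, 0.05, n), 0, 1)
        return _pf(X), y

    def test_default_grid_has_20_sizes(self):
        assert len(pv.DEFAULT_K_GRID) == 20
        assert pv.DEFAULT_K_GRID[0] == 5 and pv.DEFAULT_K_GRID[-1] == 100

    def test_chosen_k_in_grid_and_columns_ranked(self):
        pf, y = self._signal_data()
        ranking = rank_features(pf, y, seed=1)
        sel = sweep_subsets(
            pf, y, ranking, k_grid=[5, 10], folds=5, seed=1,
            meta_grid={"n_estimators": [50]},
        )
        assert sel.chosen_k in (5, 10)
        assert sel.chosen_columns == [pf.columns[i] for i in ranking[: sel.chosen_k]]

    def test_oversized_k_dropped_with_warning(self):
        pf, y = self._signal_data(d=8)
        ranking = rank_features(pf, y, seed=1)
        with pytest.warns(UserWarning, match="dropping"):
            sel = sweep_subsets(
                pf, y, ranking, k_grid=[5, 50], folds=5, seed=1,
                meta_grid={"n_estimators": [50]},
            )
        assert sel.k_grid == (5,)

    def test_empty_grid_errors(self):
        pf, y = self._signal_data(d=8)
        ranking = rank_features(pf, y, seed=1)
        with pytest.raises(ValueError):
            sweep_subsets(pf, y, ranking, k_grid=[], folds=5, seed=1)


@pytest.fixture(scope="module")
def stacked(small_pool):
    pool, feats, labels = small_pool
    pf = generate_pf(pool, feats, labels, folds=5, seed=11)
    ranking = rank_features(pf, labels, seed=11)
    sel = sweep_subsets(
        pf, labels, ranking, k_grid=[5, 10], folds=5, seed=11,
        meta_grid={"n_estimators": [50]},
    )
    model = pv.fit_stacked(pool, pf, labels, sel, seed=11)
    return model, pf, labels


class TestStackedModel:
    def test_meta_input_width_is_chosen_k(self, stacked):
        model, pf, labels = stacked
        assert model.meta.n_features_in_ == model.selection.chosen_k

    def test_end_to_end_prediction(self, stacked, small_dataset):
        model, _, _ = stacked
        records, profiles = small_dataset
        preds = pv.predict_stacked(model, records, profiles)
        assert len(preds) == len(records)
        assert preds["probability"].between(0, 1).all()
        np.testing.assert_array_equal(
            preds["label"].to_numpy(), (preds["probability"] > 0.5).astype(int)
        )
        # strongly separable training positives score above 0.5
        pos = preds.loc[[r.id for r in records if r.label == 1], "probability"]
        assert (pos > 0.5).mean() > 0.9

    def test_save_load_reproduces_predictions(self, stacked, small_dataset, tmp_path):
        model, _, _ = stacked
        records, profiles = small_dataset
        path = tmp_path / "stacked.joblib"
        model.save(path)
        back = pv.StackedModel.load(path)
        a = pv.predict_stacked(model, records[:5], profiles)
        b = pv.predict_stacked(back, records[:5], profiles)
        np.testing.assert_array_equal(
            a["probability"].to_numpy(), b["probability"].to_numpy()
        )

    def test_selection_column_mismatch_errors(self, stacked, small_pool):
        model, pf, labels = stacked
        pool, _, _ = small_pool
        other = MetaFeatureMatrix(
            "PF", pf.frame.rename(columns=lambda c: c + "_x")
        )
        with pytest.raises(ValueError, match="columns"):
            pv.fit_stacked(pool, other, labels, model.selection, seed=11)
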