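"""L2OGO cross-validation, cell-set classification, metrics, importance."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucmorph import (balance_classes, classify_sets, evaluate_metrics,
                      feature_importance, fit_and_score_cells, l2ogo_splits,
                      make_model, run_l2ogo)
from nucmorph.features import FEATURE_COLUMNS


def toy_table(n_images=(2, 3), cells_per_image=10, n_features=4, seed=0,
              shift=2.0):
    """Synthetic feature table: Gaussian features, class B shifted in f0."""
    rng = np.random.default_rng(seed)
    rows = []
    for cond, n_img in zip("AB", n_images):
        for i in range(n_img):
            feats = rng.normal(0, 1, (cells_per_image, n_features))
            if cond == "B":
                feats[:, 0] += shift
            for row in feats:
                rows.append({**{f"f{j}": row[j] for j in range(n_features)},
                             "image_id": f"{cond}{i}", "condition": cond})
    return pd.DataFrame(rows)


FEATS = [f"f{j}" for j in range(4)]


class TestL2OGOSplits:
    def test_pairwise_product_count(self):
        folds = l2ogo_splits(toy_table((2, 3)))
        assert len(folds) == 6

    @pytest.mark.parametrize("layout", [(2, 2), (3, 4), (5, 2)])
    def test_matches_exhaustive_enumeration(self, layout):
        table = toy_table(layout, cells_per_image=3)
        folds = l2ogo_splits(table)
        imgs_a = sorted(table[table.condition == "A"].image_id.unique())
        imgs_b = sorted(table[table.condition == "B"].image_id.unique())
        expected = set(itertools.product(imgs_a, imgs_b))
        assert {f.test_pair for f in folds} == expected

    def test_partition_property(self):
        table = toy_table((3, 3))
        all_images = set(table.image_id.unique())
        cond = dict(zip(table.image_id, table.condition))
        for fold in l2ogo_splits(table):
            a, b = fold.test_pair
            assert cond[a] != cond[b]
            assert set(fold.train_image_ids) | {a, b} == all_images
            assert not set(fold.train_image_ids) & {a, b}

    def test_degenerate_one_image_per_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            l2ogo_splits(toy_table((1, 1)))

    def test_single_condition_rejected(self):
        table = toy_table((3, 3))
        with pytest.raises(ValueError, match="2 conditions"):
            l2ogo_splits(table[table.condition == "A"])


class TestBalanceClasses:
    def test_downsamples_to_minority(self):
        table = toy_table((31, 15), cells_per_image=10, seed=1)  # 310 vs 150
        table = table.iloc[:-2]  # 310 A vs 148 B
        balanced = balance_classes(table, seed=0)
        assert balanced.condition.value_counts().tolist() == [148, 148]

    def test_already_balanced_unchanged(self):
        table = toy_table((2, 2), cells_per_image=5)
        balanced = balance_classes(table, seed=0)
        assert sorted(balanced.index) == sorted(table.index)

    def test_deterministic_given_seed(self):
        table = toy_table((3, 2), cells_per_image=8)
        a = balance_classes(table, seed=7)
        b = balance_classes(table, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestFitAndScore:
    def test_separable_classes_perfect_auc(self):
        table = toy_table((2, 2), cells_per_image=20, shift=8.0)
        train = table[table.image_id.isin(["A0", "B0"])]
        test = table[table.image_id.isin(["A1", "B1"])]
        probs, _ = fit_and_score_cells(train, test, "fast-rf", seed=0,
                                       feature_columns=FEATS)
        labels = (test.condition == "B").to_numpy()
        assert evaluate_metrics(probs, labels)["auc"] == pytest.approx(1.0)

    def test_permuted_labels_chance_auc(self):
        rng = np.random.default_rng(3)
        table = toy_table((2, 2), cells_per_image=60, shift=8.0, seed=2)
        table["condition"] = rng.permutation(table["condition"].to_numpy())
        table = table.groupby("condition", group_keys=False).head(55)
        train = table.iloc[::2]
        test = table.iloc[1::2]
        probs, _ = fit_and_score_cells(train, test, "fast-rf", seed=0,
                                       feature_columns=FEATS)
        labels = (test.condition == "B").to_numpy()
        assert abs(evaluate_metrics(probs, labels)["auc"] - 0.5) < 0.2

    def test_single_class_train_rejected(self):
        table = toy_table((2, 2))
        train = table[table.condition == "A"]
        with pytest.raises(ValueError, match="single class"):
            fit_and_score_cells(train, table, "fast-rf", feature_columns=FEATS)

    def test_benchmark_presets_expose_exact_hyperparameters(self):
        gb = make_model("fibroblast-gb")
        p = gb.get_params()
        assert (p["n_estimators"], p["max_depth"], p["subsample"]) == (1500, 8, 0.5)
        rf = make_model("pc3-rf")
        p = rf.get_params()
        assert (p["n_estimators"], p["max_depth"], p["max_features"]) == (1000, 12, 0.4)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            make_model("nonexistent")


class TestEvaluateMetrics:
    def test_perfect_predictions(self):
        labels = np.array([True, False, True, False])
        scores = labels.astype(float)
        m = evaluate_metrics(scores, labels)
        assert all(v == 1.0 for v in m.values())

    def test_constant_scores_chance_auc(self):
        m = evaluate_metrics(np.full(10, 0.7), np.arange(10) % 2 == 0)
        assert m["auc"] == 0.5

    def test_hand_worked_confusion_case(self):
        # TP=2, FP=1, FN=1, TN=2
        labels = np.array([True, True, True, False, False, False])
        scores = np.array([0.9, 0.8, 0.1, 0.7, 0.2, 0.3])
        m = evaluate_metrics(scores, labels)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == pytest.approx(2 / 3)


def iid_cell_results(p=0.7, n=4000, seed=42):
    """Two test images with i.i.d. per-cell accuracy p."""
    rng = np.random.default_rng(seed)
    frames = []
    for img, label in [("P", True), ("N", False)]:
        correct = rng.random(n) < p
        score = np.where(correct == label, 0.8, 0.2)
        frames.append(pd.DataFrame({"fold": 0, "image_id": img, "label": label,
                                    "score": score}))
    return pd.concat(frames, ignore_index=True)


class TestClassifySets:
    def test_perfect_cells_give_perfect_sets(self):
        cells = pd.DataFrame({
            "fold": 0,
            "image_id": ["P"] * 40 + ["N"] * 40,
            "label": [True] * 40 + [False] * 40,
            "score": [1.0] * 40 + [0.0] * 40,
        })
        for size in (3, 9, 19):
            res = classify_sets(cells, size, n_bootstrap=50, seed=0)
            assert res.mean["accuracy"] == 1.0
            assert res.mean["auc"] == 1.0

    def test_majority_vote_matches_binomial_tail(self):
        # i.i.d. per-cell accuracy 0.7, sets of 19: the exact majority-vote
        # accuracy is the binomial tail P(X >= 10), X ~ Bin(19, 0.7)
        res = classify_sets(iid_cell_results(0.7), set_size=19,
                            n_bootstrap=1000, seed=3)
        oracle = float(1 - stats.binom.cdf(9, 19, 0.7))
        mc_err = 3 * np.sqrt(oracle * (1 - oracle) / (2 * 1000)) + 0.01
        assert abs(res.mean["accuracy"] - oracle) < mc_err

    def test_even_set_size_logs_warning_and_uses_tiebreak(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nucmorph.classification"):
            res = classify_sets(iid_cell_results(0.9, n=200), set_size=4,
                                n_bootstrap=50, seed=0)
        assert any("tie" in r.message for r in caplog.records)
        assert 0.0 <= res.mean["accuracy"] <= 1.0

    def test_small_image_sampled_with_replacement(self):
        cells = iid_cell_results(0.8, n=5)
        res = classify_sets(cells, set_size=9, n_bootstrap=100, seed=1)
        assert 0.0 <= res.mean["accuracy"] <= 1.0

    def test_invalid_set_size_rejected(self):
        with pytest.raises(ValueError):
            classify_sets(iid_cell_results(), set_size=0)


class TestFeatureImportanceAndDriver:
    def test_informative_feature_ranked_first(self):
        table = toy_table((3, 3), cells_per_image=15, shift=4.0, seed=5)
        res = run_l2ogo(table, model_config="fast-rf", set_sizes=(3,),
                        n_bootstrap=20, seed=0, feature_columns=FEATS)
        assert res.importance.iloc[0]["feature"] == "f0"
        assert res.importance["importance"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_importance_covers_nuclear_and_nucleolar_names(self):
        class Fake:
            feature_importances_ = np.ones(len(FEATURE_COLUMNS))

        df = feature_importance([Fake()])
        names = set(df.feature)
        assert "Volume" in names and "AvgVolume" in names and "VarCurvedness" in names

    def test_run_l2ogo_deterministic(self):
        table = toy_table((2, 2), cells_per_image=12, shift=2.0, seed=8)
        a = run_l2ogo(table, "fast-rf", set_sizes=(3, 5), n_bootstrap=30,
                      seed=4, feature_columns=FEATS)
        b = run_l2ogo(table, "fast-rf", set_sizes=(3, 5), n_bootstrap=30,
                      seed=4, feature_columns=FEATS)
        pd.testing.assert_frame_equal(a.set_summary(), b.set_summary())
        pd.testing.assert_frame_equal(a.cell_results, b.cell_results)
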