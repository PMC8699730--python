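"""Shuffle protocol, training loop, metric suite and aggregation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phasefluct.models import FusionModelSpec
from phasefluct.train_eval import (CellRecord, TrainConfig, aggregate,
                                   evaluate, make_shuffles,
                                   metrics_from_scores, prepare_dataset,
                                   train_one_shuffle)

SMALL_SINGLE = FusionModelSpec("single", ("morphology",), backbone="small-cnn")


def separable_records(n_per_class=8, seed=0, noise=0.05):
    """Two distinct spatial patterns + noise: linearly separable by class."""
    rng = np.random.default_rng(seed)
    records = []
    for label, base in (("primary", 0), ("metastatic", 1)):
        for i in range(n_per_class):
            img = np.zeros((16, 16))
            if base:
                img[4:12, 4:12] = 1.0
            else:
                img[:4, :] = 1.0
            img += noise * rng.standard_normal((16, 16))
            records.append(CellRecord(f"{label}_{i}", label, img, img.copy()))
    return records


class TestMakeShuffles:
    def test_published_dataset_size_split(self):
        plan = make_shuffles([f"c{i}" for i in range(216)], n_shuffles=3,
                             master_seed=0)
        for part in plan.assignments:
            assert (len(part["train"]), len(part["val"]), len(part["test"])) == \
                (130, 43, 43)

    def test_small_dataset_split(self):
        plan = make_shuffles(list(range(10)), n_shuffles=1, master_seed=1)
        part = plan.assignments[0]
        assert (len(part["train"]), len(part["val"]), len(part["test"])) == (6, 2, 2)

    def test_partitions_disjoint_and_complete(self):
        ids = [f"c{i}" for i in range(37)]
        plan = make_shuffles(ids, n_shuffles=5, master_seed=2)
        for part in plan.assignments:
            all_ids = part["train"] + part["val"] + part["test"]
            assert sorted(all_ids) == sorted(ids)

    def test_deterministic_given_master_seed(self):
        ids = list(range(50))
        p1 = make_shuffles(ids, n_shuffles=4, master_seed=9)
        p2 = make_shuffles(ids, n_shuffles=4, master_seed=9)
        assert p1.assignments == p2.assignments

    def test_stratified_preserves_class_balance(self):
        ids = list(range(40))
        labels = ["primary"] * 20 + ["metastatic"] * 20
        plan = make_shuffles(ids, n_shuffles=2, master_seed=0, stratify=True,
                             labels=labels)
        for part in plan.assignments:
            test_labels = [labels[i] for i in part["test"]]
            assert test_labels.count("primary") == test_labels.count("metastatic")

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            make_shuffles(list(range(9)))


class TestMetrics:
    def test_hand_computed_confusion_matrix(self):
        # TP=5, FN=0, TN=4, FP=1
        labels = [1] * 5 + [0] * 5
        scores = [0.9] * 5 + [0.8] + [0.1] * 4
        m = metrics_from_scores(labels, scores)
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(1.0)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(5 / 6)

    def test_perfect_separation_auc_one(self):
        m = metrics_from_scores([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert m["auc"] == pytest.approx(1.0)

    def test_auc_concordant_pair_example(self):
        m = metrics_from_scores([1, 1, 0, 0], [0.8, 0.6, 0.7, 0.1])
        assert m["auc"] == pytest.approx(0.75)  # 3 of 4 concordant pairs

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_equals_mann_whitney_u(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]  # both classes present
        scores = rng.random(30)
        m = metrics_from_scores(labels, scores)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
        assert m["auc"] == pytest.approx(u / (len(pos) * len(neg)), rel=1e-12)

    def test_undefined_precision_flagged(self):
        m = metrics_from_scores([1, 0], [0.1, 0.2])  # no positive predictions
        assert np.isnan(m["precision"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_scores([1, 1, 1], [0.5, 0.6, 0.7])

    def test_class_preserving_reordering_invariance(self):
        rng = np.random.default_rng(7)
        labels = np.array([0, 1] * 10)
        scores = rng.random(20)
        m1 = metrics_from_scores(labels, scores)
        perm = rng.permutation(20)
        m2 = metrics_from_scores(labels[perm], scores[perm])
        for k in ("accuracy", "sensitivity", "specificity", "auc"):
            assert m1[k] == pytest.approx(m2[k])


class TestAggregate:
    def test_identical_rows_zero_std(self):
        rows = [dict(accuracy=0.8, sensitivity=0.7, specificity=0.9,
                     precision=0.75, auc=0.85)] * 4
        agg = aggregate(rows)
        assert np.allclose(agg["std"], 0.0)

    def test_two_row_closed_form(self):
        rows = [dict(accuracy=0.8, sensitivity=0.8, specificity=0.8,
                     precision=0.8, auc=0.8),
                dict(accuracy=0.9, sensitivity=0.9, specificity=0.9,
                     precision=0.9, auc=0.9)]
        agg = aggregate(rows)
        assert agg.loc["accuracy", "mean"] == pytest.approx(0.85)
        assert agg.loc["accuracy", "std"] == pytest.approx(np.sqrt(0.005))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        rows = [dict(accuracy=a, sensitivity=a, specificity=a, precision=a,
                     auc=a) for a in rng.random(20)]
        agg = aggregate(rows)
        vals = [r["accuracy"] for r in rows]
        mean = sum(vals) / 20
        std = (sum((v - mean) ** 2 for v in vals) / 19) ** 0.5
        assert agg.loc["accuracy", "mean"] == pytest.approx(mean, rel=1e-12)
        assert agg.loc["accuracy", "std"] == pytest.approx(std, rel=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            aggregate([dict(accuracy=1, sensitivity=1, specificity=1,
                            precision=1, auc=1)])


class TestTrainOneShuffle:
    def test_separable_dataset_reaches_perfect_validation(self):
        records = separable_records()
        data = prepare_dataset(records, SMALL_SINGLE)
        ids = [r.cell_id for r in records]
        plan = make_shuffles(ids, n_shuffles=1, master_seed=0, stratify=True,
                             labels=[r.label for r in records])
        cfg = TrainConfig(batch_size=4, learning_rate=1e-3, epochs=10, seed=0)
        model, curves = train_one_shuffle(SMALL_SINGLE, data,
                                          plan.partition(0), cfg)
        assert curves["val_acc"].max() == pytest.approx(1.0)
        metrics = evaluate(model, data, plan.partition(0)["test"])
        assert metrics["accuracy"] == pytest.approx(1.0)

    def test_one_epoch_selects_epoch_one(self):
        records = separable_records(n_per_class=6)
        data = prepare_dataset(records, SMALL_SINGLE)
        plan = make_shuffles([r.cell_id for r in records], n_shuffles=1,
                             master_seed=3, stratify=True,
                             labels=[r.label for r in records])
        cfg = TrainConfig(batch_size=4, learning_rate=1e-3, epochs=1, seed=0)
        _, curves = train_one_shuffle(SMALL_SINGLE, data, plan.partition(0), cfg)
        assert curves.loc[curves["selected"], "epoch"].tolist() == [1]

    def test_training_trajectory_is_deterministic(self):
        records = separable_records(n_per_class=6, seed=5)
        data = prepare_dataset(records, SMALL_SINGLE)
        plan = make_shuffles([r.cell_id for r in records], n_shuffles=1,
                             master_seed=1, stratify=True,
                             labels=[r.label for r in records])
        cfg = TrainConfig(batch_size=4, learning_rate=1e-3, epochs=3, seed=11)
        _, c1 = train_one_shuffle(SMALL_SINGLE, data, plan.partition(0), cfg)
        _, c2 = train_one_shuffle(SMALL_SINGLE, data, plan.partition(0), cfg)
        pd.testing.assert_frame_equal(c1, c2)

    def test_empty_partition_rejected(self):
        records = separable_records(n_per_class=6)
        data = prepare_dataset(records, SMALL_SINGLE)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(ValueError):
            train_one_shuffle(SMALL_SINGLE, data,
                              {"train": [], "val": [], "test": []}, cfg)
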