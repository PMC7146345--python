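import numpy as np
import pytest

from racquetclust.evaluate import (
    confusion_and_f1,
    crossval,
    proportion_criterion,
    proportion_difference,
    stratified_folds,
    sweep_k1,
)
from racquetclust.synth import default_synth_config, generate_dataset


class TestProportionCriterion:
    def test_exact_match_has_zero_difference(self):
        # both proportions 0.19161, as for a well-recognized service set
        assert proportion_difference(0.19161, 0.19161) == 0.0

    def test_walking_difference(self):
        assert proportion_difference(0.76471, 0.71649) == pytest.approx(0.04822)

    def test_all_predicted_none_true(self):
        pred = {0: np.zeros(10, dtype=int)}  # every point predicted as movement 0
        truth = {0: (0, np.zeros(10, dtype=bool))}  # no point truly belongs to it
        rep = proportion_criterion(pred, truth)
        row = rep.table.iloc[0]
        assert row["expected"] == 0.0
        assert row["abs_diff"] == row["predicted"] == 1.0

    def test_label_based_proportions(self):
        pred = {0: np.array([1, 1, 2, 1]), 1: np.array([2, 2, 2, 1])}
        truth = {0: (1, np.array([1, 1, 1, 1])), 1: (2, np.array([2, 2, 2, 2]))}
        rep = proportion_criterion(pred, truth)
        assert rep.table["predicted"].tolist() == [0.75, 0.75]
        assert rep.score == pytest.approx(1.0 - 0.25)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            proportion_criterion({0: np.zeros(3)}, {0: (0, np.zeros(4))})

    def test_invalid_proportion_rejected(self):
        with pytest.raises(ValueError):
            proportion_difference(1.2, 0.5)

    def test_relabeling_invariance(self):
        # scores depend only on per-set movement-point counts
        pred_a = {0: np.array([5, 5, 9, 9])}
        pred_b = {0: np.array([9, 9, 5, 5])}
        truth = {0: (5, np.array([5, 5, 5, 5]))}
        assert (proportion_criterion(pred_a, truth).score
                == proportion_criterion(pred_b, truth).score)


class TestConfusionAndF1:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        rep = confusion_and_f1(y, y)
        assert np.allclose(rep.confusion, np.eye(3))
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0

    def test_single_predicted_class_concentrates_mass(self):
        true = np.array([0, 0, 1, 1, 2, 2])
        pred = np.zeros(6, dtype=int)
        rep = confusion_and_f1(pred, true, classes=[0, 1, 2])
        assert np.allclose(rep.confusion[:, 0], 1.0)
        assert np.allclose(rep.confusion[:, 1:], 0.0)

    def test_two_class_toy_macro_f1(self):
        true = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 1, 1])
        rep = confusion_and_f1(pred, true)
        assert rep.f1_macro == pytest.approx((2 / 3 + 4 / 5) / 2)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_f1(np.array([0, 7]), np.array([0, 1]), classes=[0, 1])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        true = rng.integers(0, 4, 100)
        pred = rng.integers(0, 4, 100)
        rep = confusion_and_f1(pred, true, classes=[0, 1, 2, 3])
        assert np.allclose(rep.confusion.sum(axis=1), 1.0)


class _StubResults:
    def __init__(self, fn):
        self.fn = fn

    def predict_instance(self, series):
        return self.fn(series)


@pytest.fixture(scope="module")
def cv_dataset():
    return generate_dataset(default_synth_config(seed=0))


class TestCrossval:
    def test_partition_covers_every_instance_once(self, cv_dataset):
        folds = stratified_folds(cv_dataset, 5, seed=0)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == cv_dataset.n_instances
        assert len(np.unique(all_idx)) == cv_dataset.n_instances

    def test_perfect_classifier_stub(self, cv_dataset):
        truth = {id(r.series): r.class_id for r in cv_dataset.instances}

        def factory(train, config, seed):
            return _StubResults(lambda s: truth[id(s)])

        rep = crossval(cv_dataset, folds=5, seed=0, model_factory=factory)
        assert rep.accuracy == 1.0 and rep.f1_macro == 1.0

    def test_uniform_random_stub_near_chance(self, cv_dataset):
        rng = np.random.default_rng(0)

        def factory(train, config, seed):
            return _StubResults(lambda s: int(rng.integers(0, 9)))

        rep = crossval(cv_dataset, folds=5, seed=0, model_factory=factory)
        p = 1.0 / 9.0
        se = np.sqrt(p * (1 - p) / cv_dataset.n_instances)
        assert abs(rep.accuracy - p) < 3 * se

    def test_reproducible_with_same_seed(self, small_dataset):
        a = crossval(small_dataset, folds=5, seed=0)
        b = crossval(small_dataset, folds=5, seed=0)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_too_few_instances_rejected(self):
        ds = generate_dataset(default_synth_config(seed=0, n_subjects=1, reps_per_test=3))
        with pytest.raises(ValueError):
            stratified_folds(ds, 5, seed=0)


class TestSweep:
    def test_single_k(self, small_dataset):
        table = sweep_k1(small_dataset, [20], seed=0)
        assert len(table) == 1 and bool(table["best"].iloc[0])

    def test_small_k_scores_worse_than_argmax(self, small_dataset):
        # too few encode levels make neighbouring movements share features
        table = sweep_k1(small_dataset, [16, 20, 40, 70], seed=0)
        assert table["k"].tolist() == [16, 20, 40, 70]
        best_k = int(table.loc[table["score"].idxmax(), "k"])
        assert best_k in table["k"].tolist()
        assert table.loc[table["k"] == 16, "score"].iloc[0] < table["score"].max()

    def test_empty_k_list_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            sweep_k1(small_dataset, [], seed=0)


def test_single_sport_restriction_improves_sport_recall(protocol_dataset, protocol_cv):
    """Restricting the vocabulary to one sport removes cross-sport confusion,
    so the mean recall over that sport's movements should not fall below its
    value in the nine-class run on the same seed."""
    for cls_ids in ([1, 2, 3, 4], [5, 6, 7, 8]):
        sub = crossval(protocol_dataset.subset(cls_ids), folds=5, seed=0)
        full_mean = np.mean([protocol_cv.recall[protocol_cv.classes.index(c)] for c in cls_ids])
        sub_mean = np.mean([sub.recall[sub.classes.index(c)] for c in cls_ids])
        assert sub_mean >= full_mean - 1e-9
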