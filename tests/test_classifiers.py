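import numpy as np
import pytest

from psntopo.classifiers import (
    DnnSpec,
    RfSpec,
    SvmSpec,
    class_weights,
    enumerate_architectures,
    grid_search,
    stratified_split,
    train_dnn,
    train_rf,
    train_svm,
)
from psntopo.evaluation import balanced_accuracy, best_model
from psntopo.io_formats import OutcomeTable
from psntopo.topology import TopoFeatureMatrix, standardize


def _outcomes(n, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return OutcomeTable([f"s{i:03d}" for i in range(n)], {"event": y})


def _toy_features(n=200, d=10, effect=2.0, seed=0):
    """Standardized feature matrix with a strong class signal (cheap stand-in
    for a full topological pipeline)."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 5] = 1
    rng.shuffle(y)
    vals = rng.normal(size=(n, d))
    vals[:, : d // 2] += effect * y[:, None]
    ids = [f"s{i:03d}" for i in range(n)]
    feats = TopoFeatureMatrix(vals, [f"f{j}" for j in range(d)], ids,
                              "centralities")
    return standardize(feats), y, OutcomeTable(ids, {"event": y})


class TestStratifiedSplit:
    def test_498_samples_split_249_125_124(self):
        split = stratified_split(_outcomes(498, 100), "event", seed=0)
        assert (len(split.train_ids), len(split.eval_ids),
                len(split.valid_ids)) == (249, 125, 124)

    def test_four_samples_minimal_split(self):
        split = stratified_split(_outcomes(4, 2), "event", seed=0)
        assert (len(split.train_ids), len(split.eval_ids),
                len(split.valid_ids)) == (2, 1, 1)

    def test_partitions_are_disjoint_and_cover_everything(self):
        out = _outcomes(103, 31)
        split = stratified_split(out, "event", seed=5)
        union = split.train_ids + split.eval_ids + split.valid_ids
        assert sorted(union) == sorted(out.sample_ids)

    def test_per_class_proportions_stay_within_one_sample(self):
        """4:1 cohort of 500: every partition holds its share of positives to
        within one sample of the global prevalence."""
        out = _outcomes(500, 100)
        y = dict(zip(out.sample_ids, out.labels("event")))
        split = stratified_split(out, "event", seed=1)
        for ids, frac in zip((split.train_ids, split.eval_ids,
                              split.valid_ids), (0.5, 0.25, 0.25)):
            n_pos = sum(y[s] for s in ids)
            assert abs(n_pos - len(ids) * 0.2) < 1.0

    def test_deterministic_given_seed(self):
        out = _outcomes(100, 20)
        s1 = stratified_split(out, "event", seed=9)
        s2 = stratified_split(out, "event", seed=9)
        assert s1.train_ids == s2.train_ids and s1.valid_ids == s2.valid_ids

    def test_class_too_small_to_stratify_rejected(self):
        with pytest.raises(ValueError, match="too few samples"):
            stratified_split(_outcomes(10, 1), "event", seed=0)

    def test_minority_class_present_in_training_partition(self):
        out = _outcomes(12, 2)
        y = dict(zip(out.sample_ids, out.labels("event")))
        split = stratified_split(out, "event", seed=3)
        assert sum(y[s] for s in split.train_ids) >= 1


class TestClassWeights:
    def test_balanced_classes_get_unit_weights(self):
        w = class_weights(np.array([0, 0, 1, 1]))
        assert w[0] == w[1] == 1.0

    def test_four_to_one_imbalance_gives_four_to_one_weights(self):
        y = np.array([0] * 400 + [1] * 100)
        w = class_weights(y)
        assert w[1] / w[0] == pytest.approx(4.0)

    def test_mean_per_sample_weight_is_one(self, rng):
        y = (rng.random(157) < 0.3).astype(int)
        w = class_weights(y)
        per_sample = np.array([w[int(c)] for c in y])
        assert per_sample.mean() == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            class_weights(np.ones(5))


class TestEnumerateArchitectures:
    def test_depth_one_gives_three(self):
        assert len(enumerate_architectures(depths=[1])) == 3

    def test_non_increasing_grid_has_34(self):
        archs = enumerate_architectures()
        assert len(archs) == 34  # 3 + 6 + 10 + 15 multisets
        assert len(set(archs)) == 34
        assert all(all(a >= b for a, b in zip(h, h[1:])) for h in archs)

    def test_unconstrained_grid_has_120(self):
        assert len(enumerate_architectures(constraint="all")) == 120

    def test_exhaustive_oracle_agreement(self):
        """Cross-check against direct enumeration of all sequences."""
        import itertools

        ref = set()
        for depth in range(1, 5):
            for seq in itertools.product((2, 4, 8), repeat=depth):
                if all(a >= b for a, b in zip(seq, seq[1:])):
                    ref.add(seq)
        assert set(enumerate_architectures()) == ref


class TestDnnSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"hidden_sizes": (3,)},
        {"hidden_sizes": (8, 8, 8, 8, 8)},
        {"dropout": 0.5},
        {"optimizer": "sgd"},
        {"learning_rate": 1.0},
    ])
    def test_out_of_grid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DnnSpec(**kwargs)


class TestTrainDnn:
    def test_separable_features_reach_high_validation_bacc(self):
        feats, y, out = _toy_features(effect=2.0, seed=1)
        split = stratified_split(out, "event", seed=1)
        spec = DnnSpec(hidden_sizes=(8, 4), epochs=300, seed=3)
        model = train_dnn(feats, y, split, spec)
        idx = [feats.sample_ids.index(s) for s in split.valid_ids]
        bacc = balanced_accuracy(y[idx], model.predict(feats.values[idx]))
        assert bacc >= 0.95

    def test_same_spec_and_seed_give_identical_training_logs(self):
        feats, y, out = _toy_features(n=80, seed=2)
        split = stratified_split(out, "event", seed=2)
        spec = DnnSpec(hidden_sizes=(4,), epochs=60, seed=11)
        m1 = train_dnn(feats, y, split, spec)
        m2 = train_dnn(feats, y, split, spec)
        assert m1.training_log == m2.training_log
        for p1, p2 in zip(m1.params, m2.params):
            np.testing.assert_array_equal(p1, p2)

    def test_permuted_labels_give_chance_level_performance(self):
        feats, y, out = _toy_features(effect=2.0, seed=3)
        rng = np.random.default_rng(0)
        yp = rng.permutation(y)
        outp = OutcomeTable(list(feats.sample_ids), {"event": yp})
        split = stratified_split(outp, "event", seed=3)
        baccs = []
        for seed in range(10):
            spec = DnnSpec(hidden_sizes=(8, 4), epochs=200, seed=seed)
            model = train_dnn(feats, yp, split, spec)
            idx = [feats.sample_ids.index(s) for s in split.valid_ids]
            baccs.append(balanced_accuracy(yp[idx],
                                           model.predict(feats.values[idx])))
        assert 0.35 <= float(np.mean(baccs)) <= 0.65

    @pytest.mark.parametrize("optimizer",
                             ["adam", "adadelta", "adagrad", "proximal_adagrad"])
    def test_all_optimizers_learn_the_separable_toy(self, optimizer):
        """Every update rule must drive the toy problem well above chance
        (adadelta converges slowest at the grid's maximum learning rate)."""
        feats, y, out = _toy_features(n=120, effect=3.0, seed=4)
        split = stratified_split(out, "event", seed=4)
        spec = DnnSpec(hidden_sizes=(8,), epochs=800, optimizer=optimizer,
                       learning_rate=5e-2, seed=0)
        model = train_dnn(feats, y, split, spec)
        assert max(l["eval_bacc"] for l in model.training_log) >= 0.8

    def test_unstandardized_features_rejected(self):
        feats, y, out = _toy_features(n=80)
        raw = TopoFeatureMatrix(feats.values, feats.feature_names,
                                feats.sample_ids, "centralities",
                                standardized=False)
        split = stratified_split(out, "event", seed=0)
        with pytest.raises(ValueError, match="standardized"):
            train_dnn(raw, y, split, DnnSpec(epochs=10))


class TestSvmAndRf:
    def test_linear_svm_separates_a_linearly_separable_toy(self):
        feats, y, out = _toy_features(n=100, effect=4.0, seed=5)
        split = stratified_split(out, "event", seed=5)
        model = train_svm(feats, y, split, SvmSpec(kernel="linear"))
        idx = [feats.sample_ids.index(s) for s in split.train_ids]
        assert balanced_accuracy(y[idx], model.predict(feats.values[idx])) == 1.0

    def test_rf_stable_between_100_and_10000_trees(self):
        feats, y, out = _toy_features(n=200, effect=3.0, seed=6)
        split = stratified_split(out, "event", seed=6)
        idx = [feats.sample_ids.index(s) for s in split.valid_ids]
        baccs = {}
        for n_trees in (100, 10_000):
            model = train_rf(feats, y, split, RfSpec(n_trees=n_trees, seed=1))
            baccs[n_trees] = balanced_accuracy(
                y[idx], model.predict(feats.values[idx]))
        assert abs(baccs[100] - baccs[10_000]) <= 0.05

    def test_svm_grid_has_nine_cost_values(self):
        grid = [SvmSpec(kernel="linear", cost_p=p) for p in range(-4, 5)]
        assert len(grid) == 9
        assert [s.cost for s in grid] == [2.0 ** (2 * p) for p in range(-4, 5)]

    def test_out_of_grid_specs_rejected(self):
        with pytest.raises(ValueError):
            SvmSpec(cost_p=5)
        with pytest.raises(ValueError):
            RfSpec(n_trees=50)


class TestGridSearch:
    def test_record_count_is_configs_times_replicates(self):
        feats, y, out = _toy_features(n=80, seed=7)
        split = stratified_split(out, "event", seed=7)
        grid = [DnnSpec(hidden_sizes=h, learning_rate=lr, epochs=30)
                for h in ((4,), (8,)) for lr in (1e-3, 1e-2)]
        recs = grid_search("dnn", feats, y, split, grid, replicates=3,
                           master_seed=1)
        assert len(recs) == 4 * 3

    def test_svm_family_ignores_replicates(self):
        feats, y, out = _toy_features(n=80, seed=7)
        split = stratified_split(out, "event", seed=7)
        recs = grid_search("svm", feats, y, split,
                           [SvmSpec(kernel="linear")], replicates=10)
        assert len(recs) == 1

    def test_reproducible_from_master_seed(self):
        feats, y, out = _toy_features(n=80, seed=8)
        split = stratified_split(out, "event", seed=8)
        grid = [DnnSpec(hidden_sizes=(4,), epochs=40)]
        r1 = grid_search("dnn", feats, y, split, grid, replicates=3,
                         master_seed=42)
        r2 = grid_search("dnn", feats, y, split, grid, replicates=3,
                         master_seed=42)
        assert [(r.seed, r.bacc, r.eval_bacc) for r in r1] == \
               [(r.seed, r.bacc, r.eval_bacc) for r in r2]

    def test_empty_grid_rejected(self):
        feats, y, out = _toy_features(n=80)
        split = stratified_split(out, "event", seed=0)
        with pytest.raises(ValueError, match="empty grid"):
            grid_search("dnn", feats, y, split, [])

    def test_dnn_not_collapsed_relative_to_svm(self):
        """Parameter-recovery sanity: the best DNN stays within 0.05 bACC of
        the best SVM on a learnable synthetic problem."""
        feats, y, out = _toy_features(n=200, effect=1.5, seed=9)
        split = stratified_split(out, "event", seed=9)
        dnn = grid_search("dnn", feats, y, split,
                          [DnnSpec(hidden_sizes=(8, 4), epochs=300)],
                          replicates=5, master_seed=2)
        svm = grid_search("svm", feats, y, split,
                          [SvmSpec(kernel="rbf", cost_p=p, gamma_p=-2)
                           for p in (-1, 0, 1)], master_seed=2)
        assert best_model(dnn).bacc >= best_model(svm).bacc - 0.05
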