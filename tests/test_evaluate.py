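import itertools

import numpy as np
import pytest

from cas13guide.evaluate import (
    benchmark_grid,
    cross_validate,
    feature_ablation,
    noise_ceiling,
    roc_one_vs_all,
)
from cas13guide.features import FeatureMatrix, kmer_descriptor


def _matrix(values):
    values = np.asarray(values, dtype=float)
    descriptors = [
        type(kmer_descriptor(1, "A", 0))(
            name=f"f{i}", kind="positional_kmer", k=1, kmer="A", position=i
        )
        for i in range(values.shape[1])
    ]
    return FeatureMatrix([f"r{i}" for i in range(values.shape[0])], descriptors, values)


def auc_oracle(scores, positives):
    """Brute-force concordance count over all (positive, negative) pairs,
    ties counted half."""
    pos = [s for s, y in zip(scores, positives) if y]
    neg = [s for s, y in zip(scores, positives) if not y]
    total = len(pos) * len(neg)
    conc = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return conc / total


class TestNoiseCeiling:
    def test_agreeing_triple(self):
        rows = np.tile([1.0, 2.0], (3, 1))
        nc = noise_ceiling(rows, [0, 0, 0])
        assert (nc.conflicting_pairs, nc.total_pairs, nc.max_nn) == (0, 3, 1.0)

    def test_two_one_split_triple(self):
        """Labels (0,0,1) on identical features: 2 of 3 unordered pairs conflict."""
        rows = np.tile([1.0, 2.0], (3, 1))
        nc = noise_ceiling(rows, [0, 0, 1])
        assert (nc.conflicting_pairs, nc.total_pairs) == (2, 3)
        assert nc.max_nn == pytest.approx(1 / 3)

    def test_all_distinct_triple(self):
        rows = np.tile([1.0, 2.0], (3, 1))
        nc = noise_ceiling(rows, [0, 1, 2])
        assert nc.max_nn == 0.0

    def test_no_duplicate_rows_convention(self, rng):
        rows = rng.normal(size=(10, 3))
        nc = noise_ceiling(rows, rng.integers(0, 4, 10))
        assert nc.max_nn == 1.0 and not nc.measurable

    def test_explicit_group_mode_matches_feature_equality(self, small_study):
        by_features = noise_ceiling(small_study.matrix.values, small_study.labels)
        by_guide = noise_ceiling(
            small_study.matrix.values, small_study.labels, groups=small_study.guide_ids
        )
        assert by_features.max_nn == by_guide.max_nn

    def test_row_permutation_invariance(self, rng):
        rows = np.repeat(rng.normal(size=(5, 2)), 3, axis=0)
        labels = rng.integers(0, 4, 15)
        nc1 = noise_ceiling(rows, labels)
        order = rng.permutation(15)
        nc2 = noise_ceiling(rows[order], labels[order])
        assert nc1.max_nn == nc2.max_nn
        assert nc1.conflicting_pairs == nc2.conflicting_pairs


class TestRocOneVsAll:
    def test_perfect_separation(self):
        labels = [0, 1, 2, 3] * 5
        scores = np.zeros((20, 4))
        scores[np.arange(20), labels] = 1.0
        auc = roc_one_vs_all(scores, labels)
        assert all(auc[c] == 1.0 for c in range(4))

    def test_absent_class_flagged(self):
        scores = np.random.default_rng(0).uniform(size=(10, 4))
        auc = roc_one_vs_all(scores, [0, 1] * 5)
        assert np.isnan(auc[2]) and np.isnan(auc[3])
        assert np.isfinite(auc[0]) and np.isfinite(auc[1])

    def test_matches_brute_force_oracle(self, rng):
        """Midrank AUC equals concordance counting on small instances."""
        for _ in range(100):
            n = int(rng.integers(8, 21))
            labels = rng.integers(0, 4, n)
            while len(np.unique(labels)) < 2:
                labels = rng.integers(0, 4, n)
            scores = np.round(rng.uniform(size=(n, 4)), 1)  # ties likely
            auc = roc_one_vs_all(scores, labels)
            for c in np.unique(labels):
                if (labels == c).all():
                    continue
                assert auc[int(c)] == pytest.approx(
                    auc_oracle(scores[:, c], labels == c)
                )

    def test_random_scores_near_half(self, rng):
        labels = np.tile([0, 1, 2, 3], 250)
        scores = rng.uniform(size=(1000, 4))
        auc = roc_one_vs_all(scores, labels)
        assert all(abs(auc[c] - 0.5) < 0.06 for c in range(4))


class TestCrossValidate:
    def _planted(self, rng, n=120, noiseless=True):
        x = rng.integers(0, 4, n).astype(float)
        X = np.repeat(x[:, None], 3, axis=0)  # 3 replicates per "guide"
        y = np.repeat(x.astype(int), 3)
        return _matrix(X), y

    def test_noiseless_replicates_acc_nn_equals_acc(self, rng):
        m, y = self._planted(rng)
        report = cross_validate(m, y, {"architecture": "decision_tree"},
                                repeats=10, seed=0)
        assert report.max_nn == 1.0
        assert report.noise_normalized_accuracy == pytest.approx(report.raw_accuracy)
        assert report.raw_accuracy == pytest.approx(1.0)

    def test_acc_nn_never_below_acc(self, small_study):
        sub = small_study.matrix.subset(small_study.matrix.names[:200])
        report = cross_validate(sub, small_study.labels,
                                {"architecture": "decision_tree"}, repeats=5, seed=1)
        assert report.max_nn <= 1.0
        assert report.noise_normalized_accuracy >= report.raw_accuracy

    def test_determinism(self, small_study):
        sub = small_study.matrix.subset(small_study.matrix.names[:100])
        kwargs = dict(scheme="fivefold_random", repeats=5, seed=42)
        a = cross_validate(sub, small_study.labels, {"architecture": "decision_tree"}, **kwargs)
        b = cross_validate(sub, small_study.labels, {"architecture": "decision_tree"}, **kwargs)
        assert a.per_fold == b.per_fold
        assert a.per_class_auc == b.per_class_auc

    def test_threefold_replicate_rotation(self, small_study):
        sub = small_study.matrix.subset(small_study.matrix.names[:100])
        report = cross_validate(
            sub, small_study.labels, {"architecture": "decision_tree"},
            scheme="threefold_replicate", replicate_ids=small_study.replicate_ids, seed=0,
        )
        assert len(report.per_fold) == 3

    def test_threefold_needs_three_replicates(self, rng):
        m, y = self._planted(rng, n=20)
        with pytest.raises(ValueError, match="3 replicates"):
            cross_validate(m, y, {"architecture": "decision_tree"},
                           scheme="threefold_replicate",
                           replicate_ids=[1, 2] * (len(y) // 2), seed=0)

    def test_param_sweep_records_best(self, rng):
        m, y = self._planted(rng, n=60)
        report = cross_validate(
            m, y, {"architecture": "knn"}, repeats=3, seed=0,
            param_sweep={"n_neighbors": [1, 3, 5]},
        )
        assert "n_neighbors" in report.best_hyperparameters
        assert 1 <= report.best_hyperparameters["n_neighbors"] <= 5


class TestBenchmarkGrid:
    def test_grid_complete_and_deterministic(self, small_study):
        sub_names = small_study.matrix.names[:60]
        lists = {"listA": sub_names[:30], "listB": sub_names[30:], "empty": []}
        kwargs = dict(
            architectures=("decision_tree", "knn"),
            schemes=("fivefold_random",),
            repeats=2, seed=0, sweep=False,
        )
        g1 = benchmark_grid(small_study.matrix, small_study.labels, lists, **kwargs)
        g2 = benchmark_grid(small_study.matrix, small_study.labels, lists, **kwargs)
        assert len(g1) == 2  # architectures x schemes
        assert g1["empty"].isna().all()
        assert g1[["listA", "listB"]].notna().all().all()
        assert g1.equals(g2)


class TestAblation:
    def test_redundant_feature_delta_near_zero_planted_is_max(self, rng):
        n = 300
        signal = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([signal, signal, rng.normal(size=n)])
        y = signal.astype(int)
        report = feature_ablation(_matrix(X), y, {"architecture": "decision_tree"},
                                  repeats=10, seed=0)
        # duplicated informative columns: removing either leaves the other
        assert abs(report.per_feature_delta["f0"]) < 0.02
        assert abs(report.per_feature_delta["f1"]) < 0.02
        assert report.background_mean > 0.95

    def test_single_informative_feature_has_max_positive_delta(self, rng):
        n = 300
        signal = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([signal, rng.normal(size=n), rng.normal(size=n)])
        y = signal.astype(int)
        report = feature_ablation(_matrix(X), y, {"architecture": "decision_tree"},
                                  repeats=10, seed=0)
        deltas = report.per_feature_delta
        assert max(deltas, key=deltas.get) == "f0"
        assert deltas["f0"] > 0.2

    def test_accounting(self, rng):
        m = _matrix(rng.normal(size=(40, 3)))
        y = rng.integers(0, 2, 40)
        report = feature_ablation(m, y, {"architecture": "decision_tree"},
                                  repeats=4, seed=0)
        assert report.repeats == 4
        assert set(report.per_feature_delta) == {"f0", "f1", "f2"}
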