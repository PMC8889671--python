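import numpy as np
import pytest
from scipy import stats

from cas13guide.features import (
    FeatureMatrix,
    build_feature_matrix,
    default_feature_space,
    kmer_descriptor,
)
from cas13guide.guide_space import GuideCandidate
from cas13guide.select import (
    DEFAULT_GINI_TOP_N,
    kmer_representation_test,
    positional_kruskal_wallis,
    select_by_gini,
    select_by_pvalue,
    select_by_zscore,
    selection_ladder,
    univariate_significance,
)


def _matrix_from_spacers(spacers):
    guides = [GuideCandidate(f"T1|{i}", s, "T1", i) for i, s in enumerate(spacers)]
    from cas13guide.seq_io import TranscriptRecord

    t = TranscriptRecord("T1", "A" * (len(spacers) + 28))
    return build_feature_matrix(guides, {}, {}, [t])


def chi2_oracle(observed, expected):
    """Hand formula: sum (O-E)^2/E with len-1 df."""
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    stat = ((observed - expected) ** 2 / expected).sum()
    return stat, stats.chi2.sf(stat, len(observed) - 1)


def kruskal_oracle(samples):
    """Rank-based H with tie correction, computed from first principles."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    start = 0
    h = 0.0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    h /= tie
    return h, stats.chi2.sf(h, len(samples) - 1)


def f_test_oracle(x, y):
    """Simple-linear-regression p-value via scipy.linregress."""
    return stats.linregress(x, y).pvalue


class TestRepresentationTest:
    def test_uniform_composition_gives_zero_statistic(self, rng):
        spacers = ["".join(rng.permutation(list("ACGT" * 7))) for _ in range(64)]
        # force position 0 perfectly balanced: 16 of each base
        spacers = [b + s[1:] for b, s in zip("ACGT" * 16, spacers)]
        m = _matrix_from_spacers(spacers)
        result = kmer_representation_test(m, k=1, position=0)
        assert result["A"].statistic == pytest.approx(0.0)
        assert result["A"].p_value == pytest.approx(1.0)

    def test_all_one_base_hand_value(self):
        m = _matrix_from_spacers(["A" * 28] * 64)
        result = kmer_representation_test(m, k=1, position=5)
        # O=(64,0,0,0), E=16 each: 48^2/16 + 3*16 = 192
        assert result["A"].statistic == pytest.approx(192.0)
        assert result["A"].direction == "over"
        assert result["C"].direction == "under"
        assert result["A"].observed == 64 and result["A"].expected == 16

    def test_matches_chi2_oracle_on_random_counts(self, rng):
        for _ in range(100):
            counts = rng.multinomial(200, rng.dirichlet(np.ones(4)))
            spacers = []
            for base, c in zip("ACGT", counts):
                spacers.extend([base + "A" * 27] * c)
            m = _matrix_from_spacers(spacers)
            result = kmer_representation_test(m, k=1, position=0)
            stat, p = chi2_oracle(counts, [counts.sum() / 4] * 4)
            assert result["A"].statistic == pytest.approx(stat)
            assert result["A"].p_value == pytest.approx(p)

    def test_position_out_of_range(self):
        m = _matrix_from_spacers(["A" * 28] * 4)
        with pytest.raises(ValueError):
            kmer_representation_test(m, k=3, position=26)


class TestKruskalWallis:
    def test_constant_data_defines_zero(self):
        h, p = positional_kruskal_wallis([1.0] * 6, list("AAABBB"))
        assert (h, p) == (0.0, 1.0)

    def test_single_group_flagged(self):
        h, p = positional_kruskal_wallis([1, 2, 3], ["A", "A", "A"])
        assert np.isnan(h) and np.isnan(p)

    def test_two_group_textbook_value(self):
        h, _ = positional_kruskal_wallis(
            [1, 2, 3, 10, 11, 12], ["A", "A", "A", "B", "B", "B"]
        )
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_matches_rank_sum_oracle_on_random_partitions(self, rng):
        for _ in range(100):
            sizes = rng.integers(3, 10, size=rng.integers(2, 5))
            samples = [np.round(rng.normal(size=s), 1) for s in sizes]  # ties likely
            values = np.concatenate(samples)
            groups = np.concatenate(
                [[chr(65 + i)] * len(s) for i, s in enumerate(samples)]
            )
            h, p = positional_kruskal_wallis(values, groups)
            h0, p0 = kruskal_oracle(samples)
            assert h == pytest.approx(h0)
            assert p == pytest.approx(p0)


class TestUnivariateSignificance:
    def _tiny_matrix(self, columns, names=None):
        columns = np.column_stack(columns)
        names = names or [f"f{i}" for i in range(columns.shape[1])]
        descriptors = [kmer_descriptor(1, "A", i) for i in range(columns.shape[1])]
        descriptors = [
            type(d)(name=n, kind=d.kind, k=d.k, kmer=d.kmer, position=d.position)
            for d, n in zip(descriptors, names)
        ]
        return FeatureMatrix([f"r{i}" for i in range(columns.shape[0])], descriptors, columns)

    def test_identical_feature_bottoms_out(self, rng):
        y = rng.uniform(size=30)
        m = self._tiny_matrix([y])
        p = univariate_significance(m, y)["f0"]
        assert 0 < p < 1e-30

    def test_constant_feature_gets_p_one(self, rng):
        m = self._tiny_matrix([np.ones(20)])
        assert univariate_significance(m, rng.uniform(size=20))["f0"] == 1.0

    def test_matches_linregress_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            y = rng.uniform(size=n)
            m = self._tiny_matrix([x])
            p = univariate_significance(m, y)["f0"]
            assert p == pytest.approx(f_test_oracle(x, y), rel=1e-6)

    def test_rejects_tiny_n(self, rng):
        m = self._tiny_matrix([np.ones(2)])
        with pytest.raises(ValueError):
            univariate_significance(m, [0.1, 0.2])


class TestThresholdSelections:
    space = [kmer_descriptor(1, "A", i) for i in range(10)]
    space = [
        type(d)(name=f"f{i}", kind=d.kind, k=d.k, kmer=d.kmer, position=d.position)
        for i, d in enumerate(space)
    ]

    def test_pvalue_strict_boundary(self):
        pvals = {"f0": 0.01, "f1": 0.5, "f2": 0.05}
        result = select_by_pvalue(pvals, self.space)
        assert result.names == ["f0"]  # 0.05 excluded by strict <

    def test_all_insignificant_empty(self):
        result = select_by_pvalue(dict.fromkeys(["f0", "f1"], 1.0), self.space)
        assert result.names == []

    def test_zscore_outlier_detection(self, rng):
        """One p=1e-20 outlier among ~uniform nulls is the only z>3 pick."""
        space = [
            type(d)(name=f"g{i}", kind=d.kind, k=d.k, kmer=d.kmer, position=d.position)
            for i, d in enumerate([kmer_descriptor(1, "A", 0)] * 100)
        ]
        pvals = {f"g{i}": float(p) for i, p in enumerate(rng.uniform(0.3, 0.7, 99))}
        pvals["g99"] = 1e-20
        z3 = select_by_zscore(pvals, space, 3.0)
        assert z3.names == ["g99"]

    def test_nesting_pval_z2_z3(self, rng):
        pvals = {f"f{i}": float(p) for i, p in enumerate(rng.uniform(1e-12, 1, 10))}
        p_sel = set(select_by_pvalue(pvals, self.space).names)
        z2 = set(select_by_zscore(pvals, self.space, 2.0).names)
        z3 = set(select_by_zscore(pvals, self.space, 3.0).names)
        assert z3 <= z2
        assert z2 <= p_sel

    def test_degenerate_zero_variance(self):
        result = select_by_zscore(dict.fromkeys([d.name for d in self.space], 0.5),
                                  self.space, 2.0)
        assert result.names == []


class TestGiniSelection:
    def test_planted_feature_has_max_importance(self, rng):
        n = 200
        signal = rng.integers(0, 2, n).astype(float)
        noise = rng.normal(size=(n, 9))
        values = np.column_stack([signal, noise])
        descriptors = TestThresholdSelections.space
        m = FeatureMatrix([f"r{i}" for i in range(n)], descriptors, values)
        labels = signal.astype(int)  # class == the planted feature
        for learner in ("decision_tree", "random_forest"):
            result = select_by_gini(m, labels, learner, top_n=3, seed=0)
            assert result.names[0] == "f0"

    def test_importances_sum_to_one_and_determinism(self, small_study):
        m = small_study.matrix.subset(small_study.matrix.names[:300])
        a = select_by_gini(m, small_study.labels, "random_forest", top_n=20, seed=3)
        b = select_by_gini(m, small_study.labels, "random_forest", top_n=20, seed=3)
        assert a.names == b.names
        assert a.scores == b.scores

    def test_single_class_rejected(self, rng):
        m = FeatureMatrix(["r0", "r1"], TestThresholdSelections.space,
                          rng.normal(size=(2, 10)))
        with pytest.raises(ValueError):
            select_by_gini(m, [1, 1], "decision_tree", top_n=2, seed=0)


def test_selection_ladder_nesting_and_sizes(small_study):
    ladder = selection_ladder(
        small_study.matrix, small_study.expressions, small_study.labels, seed=0
    )
    assert set(ladder) == {"pval", "z2", "z3", "gini_dt", "gini_rf"}
    assert set(ladder["z3"].names) <= set(ladder["z2"].names)
    assert set(ladder["z2"].names) <= set(ladder["pval"].names)
    assert len(ladder["gini_rf"].selected) == DEFAULT_GINI_TOP_N
    # only k-mer indicators enter the ladder
    for result in ladder.values():
        assert all(d.kind == "positional_kmer" for d in result.selected)


def test_selection_export_layout(tmp_path, small_study):
    ladder = selection_ladder(
        small_study.matrix, small_study.expressions, small_study.labels, seed=0
    )
    path = tmp_path / "sel.tsv"
    ladder["pval"].to_tsv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "kmer\tposition\tscore"
    kmer, pos, score = lines[1].split("\t")
    assert set(kmer) <= set("ACGT") and int(pos) >= 1
    assert 0 <= float(score) < 0.05
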