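import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mdselect import (
    CorrelationMatrix,
    MDDataset,
    SyntheticSpec,
    correlation_matrix,
    generate_synthetic,
    overall_weights,
    rank_weights,
    select,
    selection_report,
    subset_size,
)
from mdselect.errors import ValidationError

from conftest import pearson_rawsum


def make_dataset(features, labels):
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    domains = [sorted(set(labels[:, i])) for i in range(labels.shape[1])]
    return MDDataset(
        features=features,
        targets=labels.astype(object),
        feature_names=[f"f{j}" for j in range(features.shape[1])],
        class_names=[f"c{i}" for i in range(labels.shape[1])],
        class_domains=domains,
    )


class TestCorrelationMatrix:
    def test_perfect_correlation(self):
        data = make_dataset([[0, 9], [1, 9], [0, 9], [1, 9]], [0, 1, 0, 1])
        corr = correlation_matrix(data)
        assert corr.values[0, 0] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        data = make_dataset(
            [[1, 0], [2, 0], [3, 0], [4, 0]], [[3], [2], [1], [0]]
        )
        # class domain [0..3] encodes to itself; feature f0 rises as it falls
        assert correlation_matrix(data).values[0, 0] == pytest.approx(-1.0)

    def test_zero_variance_convention(self):
        data = make_dataset([[5, 1], [5, 2], [5, 3], [5, 4]], [0, 1, 0, 1])
        corr = correlation_matrix(data)
        assert corr.values[0, 0] == 0.0

    def test_constant_class_convention(self):
        data = make_dataset([[1, 2], [2, 3], [3, 4]], [7, 7, 7])
        assert np.all(correlation_matrix(data).values == 0.0)

    def test_matches_rawsum_oracle(self):
        rng = np.random.default_rng(0)
        features = rng.normal(size=(6, 3))
        labels = rng.integers(0, 2, size=(6, 2))
        labels[0] = [0, 0]
        labels[1] = [1, 1]  # guarantee both classes vary
        data = make_dataset(features, labels)
        corr = correlation_matrix(data)
        encoded = data.encoded_targets()
        for j in range(3):
            for i in range(2):
                assert corr.values[j, i] == pytest.approx(
                    pearson_rawsum(features[:, j], encoded[:, i]), abs=1e-12
                )

    def test_too_few_instances(self, tiny_dataset):
        with pytest.raises(ValidationError):
            MDDataset(
                features=np.zeros((2, 2)),
                targets=np.array([[0], [1]], dtype=object),
                feature_names=["a", "b"],
                class_names=["c"],
                class_domains=[[0, 1]],
            )

    def test_missing_values_rejected(self, tiny_dataset):
        tiny_dataset.features[0, 0] = np.nan
        with pytest.raises(ValidationError):
            correlation_matrix(tiny_dataset)

    def test_absolute_mode(self):
        data = make_dataset(
            [[1, 0], [2, 0], [3, 0], [4, 0]], [[3], [2], [1], [0]]
        )
        corr = correlation_matrix(data, absolute=True)
        assert corr.values[0, 0] == pytest.approx(1.0)


corr_matrices = arrays(
    dtype=float,
    shape=st.tuples(st.integers(2, 12), st.integers(1, 4)),
    elements=st.floats(-1.0, 1.0),
)


class TestRankWeights:
    def test_single_class_example(self):
        corr = CorrelationMatrix(np.array([[0.2], [0.9], [0.5]]), n_used=10)
        assert rank_weights(corr).values[:, 0].tolist() == [1, 3, 2]

    def test_tie_break_prefers_lower_index(self):
        corr = CorrelationMatrix(np.array([[0.5], [0.5]]), n_used=10)
        assert rank_weights(corr).values[:, 0].tolist() == [2, 1]

    @given(corr_matrices)
    @settings(max_examples=50, deadline=None)
    def test_columns_are_permutations(self, values):
        weights = rank_weights(CorrelationMatrix(values, n_used=5)).values
        l = values.shape[0]
        for i in range(values.shape[1]):
            assert sorted(weights[:, i].tolist()) == list(range(1, l + 1))
            assert weights[:, i].sum() == l * (l + 1) // 2

    @given(corr_matrices)
    @settings(max_examples=50, deadline=None)
    def test_weights_monotone_in_correlation(self, values):
        weights = rank_weights(CorrelationMatrix(values, n_used=5)).values
        for i in range(values.shape[1]):
            order = np.argsort(-weights[:, i])
            r_sorted = values[order, i]
            assert np.all(np.diff(r_sorted) <= 1e-15)


class TestOverallWeights:
    def test_two_class_arithmetic(self):
        corr = CorrelationMatrix(np.array([[0.9, 0.4], [0.1, 0.2]]), n_used=9)
        weights = rank_weights(corr)
        assert weights.values[0].tolist() == [2, 2]
        ow = overall_weights(corr, weights)
        # (2*0.9 + 2*0.4) / 4 -- equal weights give the plain mean
        assert ow.values[0] == pytest.approx(0.65)

    def test_explicit_weighted_average(self):
        # w = (3*0.9 + 2*0.4) / 5 = 0.7
        corr = CorrelationMatrix(np.array([[0.9, 0.4]]), n_used=9)
        from mdselect.core import RankWeights

        ow = overall_weights(corr, RankWeights(np.array([[3, 2]])))
        assert ow.values[0] == pytest.approx(0.7)

    def test_single_class_is_identity(self):
        corr = CorrelationMatrix(np.array([[0.3], [-0.2], [0.8]]), n_used=9)
        ow = overall_weights(corr, rank_weights(corr))
        assert np.allclose(ow.values, corr.values[:, 0])

    @given(corr_matrices)
    @settings(max_examples=50, deadline=None)
    def test_convex_combination_bounds(self, values):
        corr = CorrelationMatrix(values, n_used=5)
        ow = overall_weights(corr, rank_weights(corr)).values
        lo = values.min(axis=1) - 1e-12
        hi = values.max(axis=1) + 1e-12
        assert np.all(ow >= lo) and np.all(ow <= hi)
        assert np.all(np.abs(ow) <= 1 + 1e-12)


class TestSubsetSize:
    @pytest.mark.parametrize(
        "l,s", [(28, 5), (10, 3), (294, 8), (71, 6), (103, 7), (2, 1)]
    )
    def test_reference_counts(self, l, s):
        assert subset_size(l) == s

    def test_half_rounds_up(self):
        # log2(11.3137...) = 3.5 exactly at l = 8*sqrt(2); nearest integers:
        assert subset_size(11) == 3  # log2(11) = 3.459
        assert subset_size(12) == 4  # log2(12) = 3.585

    def test_rejects_degenerate(self):
        with pytest.raises(ValidationError):
            subset_size(1)


class TestSelect:
    def test_recovers_planted_features(self, planted_dataset):
        result = select(planted_dataset)
        assert result.s == 6
        assert sorted(result.selected.tolist()) == [0, 1, 2, 3, 4, 5]

    def test_single_class_matches_raw_correlation_ranking(self):
        rng = np.random.default_rng(2)
        features = rng.normal(size=(40, 7))
        labels = rng.integers(0, 2, size=40)
        data = make_dataset(features, labels)
        result = select(data)
        corr = correlation_matrix(data).values[:, 0]
        expected = sorted(range(7), key=lambda j: (-corr[j], j))
        assert result.ranking.tolist() == expected

    def test_class_order_symmetry(self):
        rng = np.random.default_rng(3)
        features = rng.normal(size=(60, 8))
        labels = rng.integers(0, 2, size=(60, 3))
        data = make_dataset(features, labels)
        flipped = make_dataset(features, labels[:, ::-1])
        assert set(select(data).selected.tolist()) == set(
            select(flipped).selected.tolist()
        )

    def test_positive_affine_feature_invariance(self):
        rng = np.random.default_rng(4)
        features = rng.normal(size=(50, 6))
        labels = rng.integers(0, 2, size=(50, 2))
        data = make_dataset(features, labels)
        scaled = make_dataset(features * 3.7 + 11.0, labels)
        assert np.allclose(
            correlation_matrix(data).values, correlation_matrix(scaled).values
        )
        assert select(data).ranking.tolist() == select(scaled).ranking.tolist()

    def test_subset_size_override(self, planted_dataset):
        assert select(planted_dataset, s=3).selected.size == 3

    def test_selected_is_ranking_prefix(self, planted_dataset):
        result = select(planted_dataset)
        assert result.selected.tolist() == result.ranking[: result.s].tolist()

    def test_report_shape(self, planted_dataset):
        result = select(planted_dataset)
        report = selection_report(planted_dataset, result)
        assert len(report) == planted_dataset.l
        assert report["selected"].sum() == result.s
        assert report.iloc[0]["overall_weight"] >= report.iloc[-1]["overall_weight"]


def test_parameter_recovery_across_seeds():
    hits = 0
    for seed in range(20):
        spec = SyntheticSpec(
            n=500,
            l=50,
            m=2,
            informative={j: (j % 2, 5.0) for j in range(6)},
            noise_sd=1.0,
            seed=seed,
        )
        result = select(generate_synthetic(spec))
        hits += sorted(result.selected.tolist()) == [0, 1, 2, 3, 4, 5]
    assert hits >= 19
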