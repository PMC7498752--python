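"""Decoding pipeline: pseudo-trials, pairwise and multiclass timecourses,
temporal generalization and the Haufe activation-pattern transform."""

import numpy as np
import pytest

from eegmvpa.containers import FeatureSet
from eegmvpa.decode import (
    DecodeParams,
    average_absolute_patterns,
    decode_all_pairs,
    decode_multiclass_timecourse,
    decode_pair_timecourse,
    make_pseudotrials,
    temporal_generalization,
    weights_to_activation_pattern,
)


def make_features(data, labels, sampling_rate=100.0):
    data = np.asarray(data, dtype=float)
    n_times = data.shape[2]
    return FeatureSet(
        data=data,
        times=10.0 * np.arange(n_times),
        labels=np.asarray(labels),
        channel_names=[f"E{i}" for i in range(data.shape[1])],
        sampling_rate=sampling_rate,
    )


def separable_features(rng, n_per=12, n_ch=6, n_t=8, gap=4.0, n_cond=2):
    """Strongly separated condition means with unit noise."""
    labels = np.repeat(np.arange(n_cond), n_per)
    centers = rng.normal(scale=gap, size=(n_cond, n_ch))
    data = rng.normal(size=(n_per * n_cond, n_ch, n_t))
    data += centers[labels][:, :, None]
    return make_features(data, labels)


class TestPseudotrials:
    def test_ten_trials_four_folds_gives_sizes_3322(self, rng):
        a = np.arange(10)[:, None].astype(float)
        order_rng = np.random.default_rng(0)
        ps_a, ps_b = make_pseudotrials(a, a.copy(), 4, order_rng)
        assert ps_a.shape == (4, 1) and ps_b.shape == (4, 1)
        # reconstruct fold sizes from the permutation the same rng produces
        check = np.random.default_rng(0)
        sizes = [len(s) for s in np.array_split(check.permutation(10), 4)]
        assert sorted(sizes) == [2, 2, 3, 3]

    def test_too_few_trials_raises_naming_condition(self, rng):
        with pytest.raises(ValueError, match="B"):
            make_pseudotrials(np.zeros((5, 2)), np.zeros((3, 2)), 4, rng)

    def test_identical_trials_average_to_themselves(self, rng):
        const = np.tile([1.5, -2.0], (9, 1))
        ps_a, _ = make_pseudotrials(const, const.copy(), 4, rng)
        assert np.allclose(ps_a, [1.5, -2.0])


class TestPairwiseDecoding:
    def test_deterministic_given_seed(self, rng):
        feats = separable_features(rng, gap=1.0)
        params = DecodeParams(n_repeats=4, seed=42)
        acc1 = decode_pair_timecourse(feats, 0, 1, params)
        acc2 = decode_pair_timecourse(feats, 0, 1, params)
        assert np.array_equal(acc1, acc2)

    def test_separable_pair_near_perfect(self, rng):
        feats = separable_features(rng, gap=6.0)
        acc = decode_pair_timecourse(feats, 0, 1, DecodeParams(n_repeats=5, seed=0))
        assert acc.mean() > 95.0

    def test_null_features_near_chance(self, rng):
        feats = separable_features(rng, gap=0.0, n_per=16, n_t=12)
        acc = decode_pair_timecourse(feats, 0, 1, DecodeParams(n_repeats=20, seed=1))
        assert abs(acc.mean() - 50.0) < 8.0

    def test_accuracy_bounded(self, rng):
        feats = separable_features(rng, gap=1.0)
        acc = decode_pair_timecourse(feats, 0, 1, DecodeParams(n_repeats=3, seed=2))
        assert np.all((acc >= 0) & (acc <= 100))

    def test_invariant_to_channel_reordering(self, rng):
        feats = separable_features(rng, gap=1.5)
        perm = np.random.default_rng(5).permutation(feats.n_channels)
        shuffled = feats.replace(
            data=feats.data[:, perm, :],
            channel_names=[feats.channel_names[i] for i in perm],
        )
        params = DecodeParams(n_repeats=4, seed=7)
        assert np.allclose(
            decode_pair_timecourse(feats, 0, 1, params),
            decode_pair_timecourse(shuffled, 0, 1, params),
        )

    def test_insufficient_trials_raise(self, rng):
        feats = separable_features(rng, n_per=3)
        with pytest.raises(ValueError):
            decode_pair_timecourse(feats, 0, 1, DecodeParams(n_repeats=1))

    def test_eight_conditions_give_28_pairs(self, rng):
        feats = separable_features(rng, n_per=4, n_t=2, n_cond=8, gap=1.0)
        result = decode_all_pairs(feats, DecodeParams(n_repeats=1, seed=0))
        assert len(result.pairs) == 28
        assert result.accuracies.shape == (28, 2)
        assert result.pairs == sorted(result.pairs)

    def test_pair_and_time_averaging_commute(self, rng):
        feats = separable_features(rng, n_per=5, n_t=4, n_cond=3, gap=1.0)
        result = decode_all_pairs(feats, DecodeParams(n_repeats=2, seed=3))
        assert result.mean_timecourse().mean() == pytest.approx(
            result.accuracies.mean()
        )


class TestMulticlass:
    def test_two_conditions_equal_pairwise(self, rng):
        feats = separable_features(rng, gap=2.0)
        params = DecodeParams(n_repeats=6, seed=4)
        pair = decode_pair_timecourse(feats, 0, 1, params)
        multi = decode_multiclass_timecourse(feats, params)
        # same procedure, different rng streams: agree within Monte-Carlo error
        assert abs(pair.mean() - multi.mean()) < 10.0

    def test_null_eight_classes_near_one_eighth(self, rng):
        feats = separable_features(rng, gap=0.0, n_per=8, n_t=6, n_cond=8)
        acc = decode_multiclass_timecourse(feats, DecodeParams(n_repeats=10, seed=5))
        assert abs(acc.mean() - 12.5) < 7.0

    def test_high_snr_well_above_chance(self, rng):
        feats = separable_features(rng, gap=4.0, n_per=8, n_t=4, n_cond=8)
        acc = decode_multiclass_timecourse(feats, DecodeParams(n_repeats=4, seed=6))
        assert acc.mean() > 60.0


class TestTemporalGeneralization:
    def test_diagonal_equals_timecourse_exactly(self, rng):
        feats = separable_features(rng, gap=1.2, n_t=6)
        params = DecodeParams(n_repeats=4, seed=8)
        tgm = temporal_generalization(feats, 0, 1, params)
        timecourse = decode_pair_timecourse(feats, 0, 1, params)
        # identical rng streams -> identical training problems on the diagonal
        assert np.allclose(tgm.diagonal(), timecourse)

    def test_null_matrix_near_chance(self, rng):
        feats = separable_features(rng, gap=0.0, n_per=14, n_t=6)
        tgm = temporal_generalization(feats, 0, 1, DecodeParams(n_repeats=15, seed=9))
        assert abs(tgm.accuracy.mean() - 50.0) < 8.0

    def test_stationary_pattern_generalizes_broadly(self, rng):
        # one constant spatial pattern across all timepoints
        labels = np.repeat([0, 1], 10)
        pattern = rng.normal(size=6)
        data = rng.normal(size=(20, 6, 8))
        data += np.where(labels == 0, -1, 1)[:, None, None] * 3 * pattern[None, :, None]
        feats = make_features(data, labels)
        tgm = temporal_generalization(feats, 0, 1, DecodeParams(n_repeats=4, seed=10))
        off_diag = tgm.accuracy[~np.eye(8, dtype=bool)]
        assert off_diag.mean() > 90.0


class TestActivationPatterns:
    def test_identity_covariance_returns_weights(self):
        w = np.array([0.5, -1.0, 2.0])
        pat = weights_to_activation_pattern(w, np.eye(3))
        assert np.allclose(pat.values, w)

    def test_zero_weights_zero_pattern(self):
        pat = weights_to_activation_pattern(np.zeros(4), np.eye(4))
        assert np.allclose(pat.values, 0.0)

    def test_suppressor_channel_analytic_example(self):
        # channel 1 carries signal + noise, channel 2 the noise copy only;
        # weights load on both but the pattern loads on channel 1 alone:
        # Σ = [[2, 1], [1, 1]], w = (1, -1) -> Σw = (1, 0)
        cov = np.array([[2.0, 1.0], [1.0, 1.0]])
        w = np.array([1.0, -1.0])
        pat = weights_to_activation_pattern(w, cov)
        assert np.allclose(pat.values, [1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weights_to_activation_pattern(np.zeros(3), np.eye(4))

    def test_average_absolute_patterns(self, rng):
        p = rng.normal(size=(5, 4))
        avg = average_absolute_patterns([p])
        assert np.allclose(avg, np.abs(p).mean(axis=0))
        both = average_absolute_patterns([p, -p])
        assert np.allclose(both, np.abs(p).mean(axis=0))
        with pytest.raises(ValueError):
            average_absolute_patterns([])

    def test_patterns_returned_from_decoding_have_channel_axis(self, rng):
        feats = separable_features(rng, gap=2.0, n_t=3)
        acc, patterns = decode_pair_timecourse(
            feats, 0, 1, DecodeParams(n_repeats=2, seed=11), return_patterns=True
        )
        assert patterns.shape == (feats.n_times, feats.n_channels)
        assert np.isfinite(patterns).all()
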