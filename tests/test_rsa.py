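"""RDM construction, SSIM, noise ceilings, RDM correlations and domain
contrasts, against closed-form and loop oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from eegmvpa.decode import PairwiseDecodingResult
from eegmvpa.rsa import (
    RDM,
    build_rdm,
    correlate_rdms,
    domain_contrast_rdm,
    group_rdm_similarity_matrix,
    model_comparison,
    noise_ceiling_null,
    rdm_from_activations,
    split_half_noise_ceiling,
    ssim,
    ssim_rdm,
    subject_rdm_stack,
)
from eegmvpa.rsa import _domain_pair_masks, _spearman_brown_floor
from eegmvpa.simulate import (
    ActivationSet,
    ImageSet,
    simulate_model_activations,
    simulate_stimulus_images,
)


def fake_result(accuracies, pairs, times, subject="s0"):
    return PairwiseDecodingResult(
        accuracies=np.asarray(accuracies, float),
        pairs=pairs,
        times=np.asarray(times, float),
        subject_id=subject,
    )


def random_subject_rdms(rng, n_subjects, n_cond=8, noise=0.0, base=None):
    if base is None:
        base = rng.random((n_cond, n_cond))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
    out = []
    for _ in range(n_subjects):
        jitter = rng.normal(scale=noise, size=base.shape)
        m = base + (jitter + jitter.T) / 2
        np.fill_diagonal(m, 0.0)
        out.append(m)
    return np.stack(out)


class TestBuildRDM:
    def test_constant_pair_fills_both_entries(self):
        res = fake_result([[60.0, 60.0]], [(0, 1)], [0.0, 10.0])
        rdm = build_rdm(res, (0.0, 20.0))
        assert rdm.values[0, 1] == 60.0 and rdm.values[1, 0] == 60.0
        assert np.isnan(rdm.values[0, 0])

    def test_group_rdm_is_mean_of_subject_rdms(self, rng):
        times = 10.0 * np.arange(5)
        pairs = [(0, 1), (0, 2), (1, 2)]
        results = [
            fake_result(50 + 10 * rng.random((3, 5)), pairs, times, f"s{i}")
            for i in range(4)
        ]
        group = build_rdm(results, (0.0, 50.0))
        stack = subject_rdm_stack(results, (0.0, 50.0))
        iu = np.triu_indices(3, k=1)
        assert np.allclose(group.values[iu], stack.mean(axis=0)[iu])

    def test_matches_double_loop_oracle(self, rng):
        times = 10.0 * np.arange(6)
        pairs = [(0, 1), (0, 2), (1, 2)]
        acc = 50 + 10 * rng.random((3, 6))
        rdm = build_rdm(fake_result(acc, pairs, times), (10.0, 40.0))
        for k, (i, j) in enumerate(pairs):
            window = (times >= 10) & (times < 40)
            assert rdm.values[i, j] == pytest.approx(acc[k, window].mean())

    def test_empty_window_rejected(self):
        res = fake_result([[50.0, 50.0]], [(0, 1)], [0.0, 10.0])
        with pytest.raises(ValueError):
            build_rdm(res, (500.0, 600.0))


class TestActivationRDM:
    def test_identical_vectors_zero_dissimilarity(self):
        v = np.arange(10.0)
        acts = ActivationSet(np.stack([v, v, 2 * v + 3]), np.arange(3))
        rdm = rdm_from_activations(acts)
        assert rdm.values[0, 1] == pytest.approx(0.0)
        assert rdm.values[0, 2] == pytest.approx(0.0)  # affine copy, r = 1

    def test_anticorrelated_vectors_dissimilarity_two(self):
        v = np.arange(10.0)
        acts = ActivationSet(np.stack([v, -v]), np.arange(2))
        assert rdm_from_activations(acts).values[0, 1] == pytest.approx(2.0)

    def test_matches_pairwise_correlation_oracle(self, rng):
        X = rng.normal(size=(5, 40))
        rdm = rdm_from_activations(ActivationSet(X, np.arange(5)))
        for i in range(5):
            for j in range(i + 1, 5):
                r = sps.pearsonr(X[i], X[j]).statistic
                assert rdm.values[i, j] == pytest.approx(1 - r)

    def test_zero_variance_vector_rejected(self):
        acts = ActivationSet(np.stack([np.ones(5), np.arange(5.0)]), np.arange(2))
        with pytest.raises(ValueError):
            rdm_from_activations(acts)


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        img = rng.random((32, 32))
        assert ssim(img, img) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a, b = rng.random((2, 32, 32))
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_constant_images_closed_form(self):
        # zero variance: contrast/structure terms are 1, luminance term is
        # (2 u1 u2 + C1) / (u1^2 + u2^2 + C1) with C1 = (0.01 L)^2
        a = np.full((32, 32), 0.2)
        b = np.full((32, 32), 0.4)
        c1 = (0.01 * 1.0) ** 2
        expected = (2 * 0.2 * 0.4 + c1) / (0.2**2 + 0.4**2 + c1)
        assert ssim(a, b, data_range=1.0) == pytest.approx(expected)
        assert expected < 1

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ssim(rng.random((16, 16)), rng.random((16, 17)))

    def test_ssim_rdm_identical_images_all_zero(self):
        img = np.random.default_rng(0).random((24, 24))
        images = ImageSet(np.stack([img] * 3), np.arange(3))
        rdm = ssim_rdm(images)
        assert np.allclose(rdm.values, 0.0, atol=1e-12)

    def test_ssim_rdm_matches_elementwise_oracle(self):
        imgs = simulate_stimulus_images(4, shape=(24, 24), seed=6)
        rdm = ssim_rdm(imgs)
        assert np.allclose(np.diag(rdm.values), 0.0)
        for i in range(4):
            for j in range(i + 1, 4):
                expected = 1 - ssim(imgs.images[i], imgs.images[j])
                assert rdm.values[i, j] == pytest.approx(expected)


class TestNoiseCeiling:
    def test_identical_noiseless_rdms_give_ceiling_one(self, rng):
        stack = random_subject_rdms(rng, 6, noise=0.0)
        est = split_half_noise_ceiling(stack, n_splits=20, seed=0)
        assert est.ceiling == pytest.approx(1.0)

    def test_spearman_brown_closed_form(self):
        r = np.array([1.0 / 3.0])
        assert _spearman_brown_floor(r)[0] == pytest.approx(np.sqrt(0.5))
        assert _spearman_brown_floor(np.array([-0.4]))[0] == 0.0

    def test_independent_random_rdms_near_zero(self, rng):
        stack = np.stack(
            [random_subject_rdms(rng, 1)[0] for _ in range(12)]
        )
        est = split_half_noise_ceiling(stack, n_splits=50, seed=1)
        assert est.ceiling < 0.25

    def test_never_negative_and_order_invariant(self, rng):
        stack = random_subject_rdms(rng, 8, noise=0.5)
        est = split_half_noise_ceiling(stack, n_splits=30, seed=2)
        assert est.ceiling >= 0.0
        shuffled = stack[rng.permutation(8)]
        est2 = split_half_noise_ceiling(shuffled, n_splits=30, seed=2)
        assert abs(est.ceiling - est2.ceiling) < 0.15  # same distribution of splits

    def test_affine_rescaling_invariance(self, rng):
        stack = random_subject_rdms(rng, 6, noise=0.2)
        est1 = split_half_noise_ceiling(stack, n_splits=25, seed=3)
        est2 = split_half_noise_ceiling(3.0 * stack + 7.0, n_splits=25, seed=3)
        assert est1.ceiling == pytest.approx(est2.ceiling)

    def test_ceiling_monotone_in_between_subject_consistency(self, rng):
        base = random_subject_rdms(rng, 1)[0]
        ceilings = []
        for noise in (0.05, 0.3, 1.5):
            stack = random_subject_rdms(rng, 10, noise=noise, base=base)
            ceilings.append(
                split_half_noise_ceiling(stack, n_splits=40, seed=4).ceiling
            )
        assert ceilings[0] > ceilings[1] > ceilings[2]

    def test_structured_rdms_give_minimal_null_p(self, rng):
        stack = random_subject_rdms(rng, 8, noise=0.05)
        est = noise_ceiling_null(stack, n_null=200, n_splits=20, seed=5)
        assert est.p_value == pytest.approx(1 / 201)
        assert est.null_distribution.shape == (200,)

    def test_null_calibrated_for_unstructured_rdms(self, rng):
        ps = []
        for rep in range(15):
            stack = np.stack(
                [random_subject_rdms(rng, 1)[0] for _ in range(8)]
            )
            est = noise_ceiling_null(stack, n_null=100, n_splits=15, seed=rep)
            ps.append(est.p_value)
        # p-values should not pile up near 0 when there is no shared structure
        assert np.mean(ps) > 0.2

    def test_fewer_than_two_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            split_half_noise_ceiling(random_subject_rdms(rng, 1), n_splits=5)


class TestRDMCorrelations:
    def test_self_correlation_is_one(self, rng):
        m = random_subject_rdms(rng, 1)[0]
        coef, _ = correlate_rdms(m, m, method="pearson")
        assert coef == pytest.approx(1.0)

    def test_uses_28_upper_triangle_values_for_8_conditions(self, rng):
        m = random_subject_rdms(rng, 1)[0]
        rdm = RDM(m, "accuracy %", np.arange(8))
        assert rdm.upper_tri().shape == (28,)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        a = random_subject_rdms(rng, 1)[0]
        b = random_subject_rdms(rng, 1)[0]
        r1, _ = correlate_rdms(a, b, method="spearman")
        r2, _ = correlate_rdms(a, np.exp(b), method="spearman")
        assert r1 == pytest.approx(r2)

    def test_constant_rdm_rejected(self, rng):
        const = np.ones((4, 4))
        np.fill_diagonal(const, 0)
        with pytest.raises(ValueError):
            correlate_rdms(const, random_subject_rdms(rng, 1, n_cond=4)[0])


class TestGroupSimilarity:
    def test_six_rdms_give_family_of_21(self, rng):
        stacks = {
            f"g{i}": random_subject_rdms(rng, 6, noise=0.3) for i in range(6)
        }
        res = group_rdm_similarity_matrix(stacks, n_splits=10, n_null=20, seed=0)
        assert res.fdr_family_size == 21
        assert (res.p_values["kind"] == "correlation").sum() == 15
        assert (res.p_values["kind"] == "noise_ceiling").sum() == 6

    def test_two_rdms_give_family_of_three(self, rng):
        stacks = {
            "a": random_subject_rdms(rng, 4, noise=0.3),
            "b": random_subject_rdms(rng, 4, noise=0.3),
        }
        res = group_rdm_similarity_matrix(stacks, n_splits=10, n_null=20, seed=0)
        assert res.fdr_family_size == 3

    def test_correlation_part_symmetric(self, rng):
        stacks = {
            f"g{i}": random_subject_rdms(rng, 4, noise=0.3) for i in range(3)
        }
        res = group_rdm_similarity_matrix(stacks, n_splits=10, n_null=20, seed=0)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(res.matrix[off], res.matrix.T[off])


class TestModelComparison:
    def test_six_by_three_gives_18_tests(self, rng):
        groups = {f"g{i}": random_subject_rdms(rng, 1)[0] for i in range(6)}
        models = {f"m{i}": random_subject_rdms(rng, 1)[0] for i in range(3)}
        table = model_comparison(groups, models)
        assert len(table) == 18

    def test_model_equal_to_group_gives_coefficient_one(self, rng):
        m = random_subject_rdms(rng, 1)[0]
        table = model_comparison({"g": m}, {"m": m.copy()})
        assert table["spearman_r"].iloc[0] == pytest.approx(1.0)

    def test_matched_model_correlates_highest(self, rng):
        target = random_subject_rdms(rng, 1)[0]
        groups = {"g": target + 0.01 * random_subject_rdms(rng, 1)[0]}
        models = {
            "matched": target,
            "other1": random_subject_rdms(rng, 1)[0],
            "other2": random_subject_rdms(rng, 1)[0],
        }
        table = model_comparison(groups, models)
        best = table.loc[table["spearman_r"].idxmax(), "model_rdm"]
        assert best == "matched"


class TestDomainContrast:
    DOMAIN_MAP = {c: ("animal" if c < 4 else "body") for c in range(8)}

    def test_pair_counts_16_across_12_within(self):
        across, within = _domain_pair_masks(np.arange(8), self.DOMAIN_MAP)
        assert across.sum() == 16
        assert within.sum() == 12

    def test_constructed_difference_matches_paired_t_oracle(self, rng):
        iu = np.triu_indices(8, k=1)
        across, _ = _domain_pair_masks(np.arange(8), self.DOMAIN_MAP)
        stack = []
        diffs_oracle = []
        for s in range(6):
            vec = np.full(28, 60.0) + rng.normal(scale=1.0, size=28)
            vec[across] += 10.0 + rng.normal(scale=0.5)
            m = np.zeros((8, 8))
            m[iu] = vec
            m += m.T
            stack.append(m)
            diffs_oracle.append(vec[across].mean() - vec[~across].mean())
        table = domain_contrast_rdm({"w": np.stack(stack)}, self.DOMAIN_MAP)
        t_oracle = sps.ttest_1samp(diffs_oracle, 0.0)
        assert table["t"].iloc[0] == pytest.approx(t_oracle.statistic)
        assert table["p_value"].iloc[0] == pytest.approx(t_oracle.pvalue)
        assert table["mean_difference"].iloc[0] == pytest.approx(
            np.mean(diffs_oracle)
        )

    def test_equal_across_and_within_gives_zero_difference(self, rng):
        stack = random_subject_rdms(rng, 5, noise=0.0, base=np.zeros((8, 8)) + 5)
        for m in stack:
            np.fill_diagonal(m, 0)
        table = domain_contrast_rdm({"w": stack}, self.DOMAIN_MAP)
        assert table["mean_difference"].iloc[0] == pytest.approx(0.0)

    def test_domain_with_single_condition_rejected(self, rng):
        bad_map = {0: "a", 1: "b", 2: "b", 3: "b"}
        stack = random_subject_rdms(rng, 4, n_cond=4)
        with pytest.raises(ValueError):
            domain_contrast_rdm({"w": stack}, bad_map)
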