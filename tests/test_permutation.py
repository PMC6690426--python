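"""Exact permutation p-values: estimator, enumeration oracle, schemes, CIs."""
import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

from exactlogrank import (ConditionalScheme, conditional_resample,
                          enumerate_pvalue, ep_confidence_interval,
                          logrank_statistic, permutation_pvalue,
                          validate_dataset)
from exactlogrank.permutation import _distinct_label_vectors, _multinomial_total

from conftest import random_dataset


class TestEstimator:
    def test_add_one_lower_bound(self):
        # a strictly maximal observed statistic: no permutation exceeds it,
        # except reproductions of the observed assignment itself
        d = validate_dataset([1, 2, 3, 4, 5, 6, 7, 8], [1] * 8,
                             list("AAAABBBB"))
        r = permutation_pvalue(d, 999, seed=0)
        exact = enumerate_pvalue(d)
        assert exact == pytest.approx(2 / math.comb(8, 4))
        assert r.p_value >= 1 / 1000
        assert r.p_value <= exact + 4 * np.sqrt(exact * (1 - exact) / 999) + 1e-3

    def test_ep_bounds_and_invariant(self, rng):
        d = random_dataset(rng, n=15, n_groups=2)
        r = permutation_pvalue(d, 499, seed=3)
        assert 1 / 500 <= r.p_value <= 1.0
        assert r.p_value == (r.exceedances + 1) / (r.n_permutations + 1)
        assert 0 <= r.ci_low <= r.p_value + 1 / 500
        assert r.ci_high <= 1.0 and r.ci_low <= r.ci_high

    def test_reproducibility_bit_for_bit(self, rng):
        d = random_dataset(rng, n=20, n_groups=3, censor_prob=0.4)
        for scheme in ("label", "conditional"):
            a = permutation_pvalue(d, 299, seed=42, scheme=scheme, n_imputations=4)
            b = permutation_pvalue(d, 299, seed=42, scheme=scheme, n_imputations=4)
            assert dataclasses.asdict(a) == dataclasses.asdict(b)

    def test_invalid_arguments(self, rng):
        d = random_dataset(rng)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_pvalue(d, 0, seed=0)
        with pytest.raises(ValueError, match="scheme"):
            permutation_pvalue(d, 10, seed=0, scheme="bootstrap")

    def test_converges_to_enumeration_on_worked_example(self, d1):
        exact = enumerate_pvalue(d1)
        assert exact == pytest.approx(1 / 3)
        r = permutation_pvalue(d1, 20000, seed=7)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(r.p_value - exact) <= 4 * se + 1 / 20001

    def test_null_ep_roughly_uniform(self):
        """Under the null, EP is (super-)uniform on its achievable grid."""
        rng = np.random.default_rng(5)
        eps = []
        for _ in range(150):
            t = rng.exponential(1.0, 16)
            g = np.repeat([0, 1], 8)
            d = validate_dataset(t, np.ones(16, bool), g)
            eps.append(permutation_pvalue(d, 199, seed=int(rng.integers(2**31))).p_value)
        eps = np.asarray(eps)
        # fraction <= alpha must not exceed alpha by more than MC noise
        for alpha in (0.05, 0.1, 0.25):
            assert np.mean(eps <= alpha) <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / 150)
        assert stats.kstest(eps, "uniform").pvalue > 1e-4


class TestEnumeration:
    def test_counts_all_distinct_assignments(self):
        counts = np.array([2, 2])
        vectors = list(_distinct_label_vectors(counts))
        assert len(vectors) == _multinomial_total(counts) == 6
        assert len({tuple(v) for v in vectors}) == 6

    def test_cap_exceeded(self, rng):
        d = random_dataset(rng, n=30, n_groups=2)
        with pytest.raises(ValueError, match="cap"):
            enumerate_pvalue(d, cap=10)

    def test_complete_degeneracy_gives_one(self):
        d = validate_dataset([3, 3, 3, 3], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert enumerate_pvalue(d) == 1.0

    def test_three_group_enumeration_matches_sampling(self, rng):
        d = random_dataset(rng, n=7, n_groups=3, censor_prob=0.2)
        exact = enumerate_pvalue(d)
        r = permutation_pvalue(d, 20000, seed=11)
        se = np.sqrt(exact * (1 - exact) / 20000)
        assert abs(r.p_value - exact) <= 4 * se + 1 / 20001


class TestConfidenceInterval:
    def test_zero_exceedances_closed_form(self):
        low, high = ep_confidence_interval(0, 1000)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 1000), rel=1e-9)

    def test_all_exceedances_mirror(self):
        low, high = ep_confidence_interval(1000, 1000)
        assert high == 1.0
        assert low == pytest.approx(0.025 ** (1 / 1000), rel=1e-9)

    def test_interval_covers_point_estimate(self):
        low, high = ep_confidence_interval(50, 1000)
        assert low < 0.05 < high
        np.testing.assert_allclose(
            [low, high],
            [stats.beta.ppf(0.025, 50, 951), stats.beta.ppf(0.975, 51, 950)])

    def test_invalid_level_and_counts(self):
        with pytest.raises(ValueError, match="level"):
            ep_confidence_interval(1, 10, level=1.5)
        with pytest.raises(ValueError, match="b"):
            ep_confidence_interval(11, 10)


class TestConditionalScheme:
    def test_no_censoring_reduces_to_label_permutation(self, rng):
        d = random_dataset(rng, n=12, n_groups=2, censor_prob=0.0)
        scheme = ConditionalScheme(d)
        assert scheme.degenerate
        resampled = conditional_resample(d, np.random.default_rng(0))
        # the resample is exactly a label permutation of the original data:
        # same (time, event) multiset, all events observed
        assert sorted(resampled.time) == sorted(d.time)
        assert resampled.event.all()
        # and EP under both schemes agrees for the same seed
        a = permutation_pvalue(d, 499, seed=9, scheme="label")
        b = permutation_pvalue(d, 499, seed=9, scheme="conditional")
        assert a.p_value == b.p_value

    def test_follow_up_structure_fixed_within_imputation(self, rng):
        # unequal administrative cutoffs; within one imputation the latent
        # follow-up multiset of each group is identical across resamples
        t = np.r_[rng.exponential(1, 20), rng.exponential(1, 20)]
        cut = np.r_[np.full(20, 0.8), np.full(20, 3.0)]
        e = t <= cut
        d = validate_dataset(np.minimum(t, cut), e, np.repeat([0, 1], 20))
        scheme = ConditionalScheme(d)
        sub = np.random.default_rng(1)
        E, F = scheme.impute(sub)
        # follow-up for censored slots equals their observed cutoff
        np.testing.assert_array_equal(F[~d.event], d.time[~d.event])
        # latent event times strictly exceed censored observation times
        assert np.all(E[~d.event] > d.time[~d.event])
        for _ in range(5):
            obs, ev = scheme.resample(E, F, sub)
            finite = np.isfinite(F)
            # observed time never exceeds the slot's follow-up, and a
            # censored resampled record sits exactly at that follow-up —
            # so each group's follow-up multiset is preserved by resampling
            assert np.all(obs[finite] <= F[finite] + 1e-12)
            np.testing.assert_allclose(obs[~ev & finite], F[~ev & finite])

    def test_resample_preserves_groups_and_size(self, rng):
        d = random_dataset(rng, n=25, n_groups=3, censor_prob=0.4)
        r = conditional_resample(d, np.random.default_rng(2))
        assert r.n == d.n
        np.testing.assert_array_equal(r.group, d.group)
        assert r.event.any()

    def test_imputed_latents_respect_observed_times(self, rng):
        d = random_dataset(rng, n=40, n_groups=2, censor_prob=0.5)
        scheme = ConditionalScheme(d)
        E, F = scheme.impute(np.random.default_rng(3))
        assert np.all(E[~d.event] > d.time[~d.event])
        assert np.all(F[d.event] >= d.time[d.event])
        np.testing.assert_array_equal(E[d.event], d.time[d.event])
        np.testing.assert_array_equal(F[~d.event], d.time[~d.event])
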