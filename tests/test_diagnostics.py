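"""AP-vs-EP comparison, permutation null distribution, FPR curve."""
import numpy as np
import pytest

from exactlogrank import (Censoring, ScenarioConfig, ap_null_distribution,
                          compare_solutions, fpr_curve, generate_dataset,
                          random_clustering_labels)


@pytest.fixture(scope="module")
def null_cohort():
    """600-patient single-population cohort with ~80% events."""
    cfg = ScenarioConfig(group_sizes=(300, 300), hazards=1.0,
                         censoring=Censoring("exponential", 0.25), seed=80)
    return generate_dataset(cfg, np.random.default_rng(80))


class TestRandomClusteringLabels:
    def test_cluster_sizes_for_breast_sized_cohort(self):
        labels = random_clustering_labels(621, 4, 10, np.random.default_rng(0))
        sizes = np.bincount(labels)[1:]
        np.testing.assert_array_equal(np.sort(sizes), [10, 10, 10, 591])

    def test_two_cluster_instance(self):
        labels = random_clustering_labels(621, 2, 10, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(np.bincount(labels)[1:]), [10, 611])

    def test_infeasible_sizes_raise(self):
        with pytest.raises(ValueError, match="infeasible"):
            random_clustering_labels(25, 4, 10)
        with pytest.raises(ValueError, match="k >= 2"):
            random_clustering_labels(100, 1, 10)

    def test_assignment_is_random_but_sizes_fixed(self):
        rng = np.random.default_rng(1)
        a = random_clustering_labels(50, 3, 5, rng)
        b = random_clustering_labels(50, 3, 5, rng)
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(np.bincount(a)[1:], np.bincount(b)[1:])


class TestApNullDistribution:
    def test_single_permutation_degenerate_fraction(self, null_cohort):
        ap, frac = ap_null_distribution(null_cohort, n_permutations=1, seed=0)
        assert ap.shape == (1,) and frac in (0.0, 1.0)

    def test_balanced_large_groups_calibrated(self, null_cohort):
        ap, frac = ap_null_distribution(null_cohort, n_permutations=1500, seed=1)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1500)

    def test_small_cluster_labels_inflate_ap(self, null_cohort):
        labels = random_clustering_labels(null_cohort.n, 8, 10,
                                          np.random.default_rng(2))
        ap, frac = ap_null_distribution(null_cohort, labels,
                                        n_permutations=1500, seed=2)
        assert frac > 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1500)

    def test_invalid_n_permutations(self, null_cohort):
        with pytest.raises(ValueError, match="n_permutations"):
            ap_null_distribution(null_cohort, n_permutations=0)


class TestFprCurve:
    def test_alpha_one_rejects_everything(self, null_cohort):
        pts = fpr_curve(null_cohort, [2, 5], n_reps=20, alpha=1.0, seed=3)
        assert all(p.fraction_le_alpha == 1.0 for p in pts)

    def test_balanced_halves_calibrated(self, null_cohort):
        pts = fpr_curve(null_cohort, [2], small_size=null_cohort.n // 2,
                        n_reps=800, seed=4)
        assert abs(pts[0].fraction_le_alpha - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 800)

    def test_ci_contains_point_estimate(self, null_cohort):
        pts = fpr_curve(null_cohort, [2, 6], n_reps=100, seed=5)
        for p in pts:
            assert p.ci_low <= p.fraction_le_alpha <= p.ci_high

    def test_unknown_method(self, null_cohort):
        with pytest.raises(ValueError, match="method"):
            fpr_curve(null_cohort, [2], method="wald")


class TestCompareSolutions:
    def test_identical_partitions_identical_ap(self, null_cohort):
        labels = random_clustering_labels(null_cohort.n, 3, 10,
                                          np.random.default_rng(6))
        solutions = {"a": labels, "b": labels.copy(), "c": labels.copy()}
        records, summary = compare_solutions(null_cohort, solutions,
                                             n_permutations=400, seed=6)
        aps = {r.ap for r in records}
        assert len(aps) == 1
        eps = [r.ep for r in records]
        assert max(eps) - min(eps) < 0.08   # MC spread only
        assert summary.n_solutions == 3

    def test_fold_gap_and_flags(self, null_cohort):
        labels = random_clustering_labels(null_cohort.n, 10, 10,
                                          np.random.default_rng(7))
        records, summary = compare_solutions(null_cohort, {"s": labels},
                                             n_permutations=500, seed=7)
        r = records[0]
        assert r.fold_gap >= 1.0
        assert r.ap_in_ci == (r.ci_low <= r.ap <= r.ci_high)
        assert summary.alpha == 0.05

    def test_discordance_definition(self):
        from exactlogrank.diagnostics import ComparisonRecord
        r = ComparisonRecord(solution="x", ap=0.04, ep=0.06, ci_low=0.051,
                             ci_high=0.07, ap_in_ci=False, fold_gap=1.5,
                             discordant_at_alpha=True)
        # AP significant but the whole EP CI sits above alpha -> discordant
        assert (r.ap <= 0.05) and (r.ci_low > 0.05) and r.discordant_at_alpha

    def test_label_length_mismatch(self, null_cohort):
        with pytest.raises(ValueError, match="labels"):
            compare_solutions(null_cohort, {"bad": np.zeros(10)}, 100)

    def test_imbalanced_solution_ep_exceeds_ap(self, null_cohort):
        """Tiny-cluster solutions: the exact p-value is the larger (less
        significant) one; summary counts the AP-outside-CI cases."""
        rng = np.random.default_rng(8)
        sols = {f"s{i}": random_clustering_labels(null_cohort.n, 12, 10, rng)
                for i in range(5)}
        records, summary = compare_solutions(null_cohort, sols,
                                             n_permutations=800, seed=8)
        # direction holds on average over solutions
        assert np.mean([r.ep >= r.ap for r in records]) >= 0.6
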