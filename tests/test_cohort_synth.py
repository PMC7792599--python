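"""Sorted-Gaussian synthesis, variability swaps, height derivation,
dataset assembly, correlation validation and the lab-style fixtures."""

import numpy as np
import pytest
from scipy import stats as sps

from rehablearn.cohort_synth import (
    DEFAULT_FIXTURE_COUNTS,
    VariabilityConfig,
    assign_sex,
    derive_height,
    fixture_experiment,
    fixture_session_stream,
    generate_class,
    generate_dataset,
    insert_variability,
    sample_sorted_gaussian,
    validate_correlations,
)
from rehablearn.errors import (
    ConfigError,
    DomainError,
    InfeasibleStatsError,
    SchemaError,
    TaxonomyError,
)
from rehablearn.schema_io import (
    FEATURE_COLUMNS,
    FTSTS_CONDITION,
    TUG_CONDITION,
    CohortStats,
    default_stats_path,
    read_cohort_stats,
)


def make_stats(name="c", n=50, **kw):
    base = dict(
        class_name=name,
        n=n,
        mu_time=12.0,
        sigma_time=2.0,
        mu_age=60.0,
        sigma_age=10.0,
        mu_bmi=25.0,
        sigma_bmi=3.0,
        mu_weight=72.0,
        sigma_weight=10.0,
        mu_height=1.70,
        sigma_height=0.08,
        pct_female=0.5,
    )
    base.update(kw)
    return CohortStats(**base)


class TestSortedGaussian:
    def test_zero_sigma_is_constant(self):
        np.testing.assert_array_equal(
            sample_sorted_gaussian(10.0, 0.0, 5, seed=1), np.full(5, 10.0)
        )

    @pytest.mark.parametrize("seed", [0, 1, 42])
    def test_output_non_decreasing(self, seed):
        x = sample_sorted_gaussian(10.0, 2.0, 500, seed=seed)
        assert np.all(np.diff(x) >= 0)

    def test_moments_within_standard_error_bounds(self):
        # oracle: plain Monte-Carlo; SE of the mean is sigma/sqrt(n)
        mu, sigma, n = 10.0, 2.0, 10_000
        x = sample_sorted_gaussian(mu, sigma, n, seed=7)
        assert abs(x.mean() - mu) < 10 * sigma / np.sqrt(n)
        assert abs(x.std(ddof=0) - sigma) / sigma < 0.05

    def test_negative_sigma_rejected(self):
        with pytest.raises(DomainError):
            sample_sorted_gaussian(10.0, -1.0, 5, seed=1)

    def test_truncation_keeps_values_above_bound(self):
        x = sample_sorted_gaussian(1.0, 2.0, 2000, seed=3, lower=0.0)
        assert np.all(x > 0)


class TestInsertVariability:
    def test_zero_fraction_is_identity(self):
        col = np.arange(20.0)
        out = insert_variability(col, 0.0, None, seed=1)
        np.testing.assert_array_equal(out, col)

    @pytest.mark.parametrize("fraction", [0.1, 0.5, 1.0])
    def test_multiset_exactly_preserved(self, fraction):
        rng = np.random.default_rng(5)
        cols = [rng.normal(size=100), rng.normal(size=100)]
        outs = insert_variability(cols, fraction, 10, seed=2)
        for c, o in zip(cols, outs):
            np.testing.assert_array_equal(np.sort(o), np.sort(c))
            assert o.mean() == pytest.approx(c.mean())
            assert o.std() == pytest.approx(c.std())

    def test_same_swaps_applied_to_every_linked_column(self):
        a = np.arange(50.0)
        b = np.arange(50.0) * 2
        oa, ob = insert_variability([a, b], 0.3, 5, seed=9)
        np.testing.assert_array_equal(ob, oa * 2)  # joint permutation

    def test_length_mismatch_raises(self):
        with pytest.raises(SchemaError):
            insert_variability([np.arange(5.0), np.arange(6.0)], 0.1, 2, seed=1)

    def test_rank_correlation_decays_with_swap_fraction(self):
        # brute-force oracle: Spearman between the sorted input and the
        # shuffled output, averaged over 50 seeds, must strictly decrease
        col = np.sort(np.random.default_rng(0).normal(size=200))
        means = []
        for fraction in (0.0, 0.1, 0.3, 0.6):
            rhos = [
                sps.spearmanr(
                    col, insert_variability(col, fraction, None, seed=s)
                ).statistic
                for s in range(50)
            ]
            means.append(np.mean(rhos))
        assert all(a > b for a, b in zip(means, means[1:])), means


class TestAssignSex:
    def test_examples(self):
        np.testing.assert_array_equal(assign_sex(10, 0.4), [0] * 4 + [1] * 6)
        np.testing.assert_array_equal(assign_sex(5, 0.0), np.ones(5))
        np.testing.assert_array_equal(assign_sex(5, 1.0), np.zeros(5))

    def test_floor_rule(self):
        assert int((assign_sex(7, 0.5) == 0).sum()) == 3  # floor(3.5)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(DomainError):
            assign_sex(5, 1.5)


class TestDeriveHeight:
    def test_sqrt_form_single_row(self):
        h, bmi, _ = derive_height(np.array([80.0]), np.array([20.0]), 2.0, 0.0)
        np.testing.assert_allclose(h, [2.0])
        np.testing.assert_allclose(bmi, [20.0])

    def test_moments_match_targets_exactly(self):
        rng = np.random.default_rng(11)
        w = rng.uniform(55, 95, 200)
        z = rng.uniform(20, 30, 200)
        with np.testing.suppress_warnings() as sup:
            sup.filter(UserWarning)
            h, bmi, _ = derive_height(w, z, 1.7, 0.08)
        assert h.mean() == pytest.approx(1.7, abs=1e-9)
        assert h.std(ddof=0) == pytest.approx(0.08, abs=1e-9)
        np.testing.assert_allclose(bmi, w / h**2, rtol=1e-9)

    def test_infeasible_targets_raise(self):
        w = np.array([70.0, 71.0, 72.0])
        z = np.array([24.0, 25.0, 26.0])
        with pytest.raises(InfeasibleStatsError):
            derive_height(w, z, 0.01, 5.0)  # sd target blows past positivity

    def test_literal_ratio_compatibility_flag(self):
        h, _, _ = derive_height(
            np.array([80.0]), np.array([20.0]), 4.0, 0.0, literal_ratio=True
        )
        np.testing.assert_allclose(h, [4.0])  # 80/20, dimensionally wrong form


class TestGenerateClass:
    def test_empty_class(self):
        table = generate_class(make_stats(n=0), VariabilityConfig(seed=1))
        assert len(table) == 0

    def test_zero_variability_gives_perfect_time_age_rank_correlation(self):
        cfg = VariabilityConfig(0.0, 0.0, seed=2)
        table = generate_class(make_stats(n=50), cfg)
        assert sps.spearmanr(table.time, table.age).statistic == pytest.approx(1.0)

    def test_swaps_never_alter_column_moments(self):
        # permutation property: moments equal the pre-swap draw's moments,
        # which land within Monte-Carlo bounds of (mu, sigma) at n=280
        stats = make_stats(n=280)
        cfg0 = VariabilityConfig(0.0, 0.0, seed=3)
        cfg1 = VariabilityConfig(0.5, 0.5, seed=3)
        t0, t1 = generate_class(stats, cfg0), generate_class(stats, cfg1)
        for col in ("time", "age", "weight"):
            np.testing.assert_array_equal(
                np.sort(getattr(t1, col)), np.sort(getattr(t0, col))
            )
        for col, mu, sd in (
            ("time", stats.mu_time, stats.sigma_time),
            ("age", stats.mu_age, stats.sigma_age),
            ("weight", stats.mu_weight, stats.sigma_weight),
        ):
            x = getattr(t1, col)
            assert abs(x.mean() - mu) < 5 * sd / np.sqrt(280)
            assert abs(x.std(ddof=0) - sd) / sd < 0.15

    def test_sex_proportion_exact_and_bmi_identity(self):
        table = generate_class(make_stats(n=97, pct_female=0.37),
                               VariabilityConfig(seed=5))
        assert int((table.sex == 0).sum()) == int(np.floor(97 * 0.37))
        np.testing.assert_allclose(
            table.bmi, table.weight / table.height**2, rtol=1e-6
        )


class TestGenerateDataset:
    def test_tug_full_cohort_has_5040_rows(self):
        stats = read_cohort_stats(default_stats_path("TUG"))
        ds = generate_dataset(stats, VariabilityConfig(seed=1), TUG_CONDITION)
        assert len(ds) == 5040
        assert ds.labels("condition").nunique() == 18

    def test_ftsts_full_cohort_has_3120_rows(self):
        stats = read_cohort_stats(default_stats_path("FTSTS"))
        ds = generate_dataset(stats, VariabilityConfig(seed=1), FTSTS_CONDITION)
        assert len(ds) == 3120

    def test_single_class_subset_raises_taxonomy_error(self):
        with pytest.raises(TaxonomyError):
            generate_dataset(
                [make_stats("healthy", 7)], VariabilityConfig(seed=1), TUG_CONDITION
            )

    def test_determinism_value_for_value(self):
        stats = [make_stats(name, 15) for name in TUG_CONDITION.classes]
        cfg = VariabilityConfig(seed=9)
        a = generate_dataset(stats, cfg, TUG_CONDITION)
        b = generate_dataset(stats, cfg, TUG_CONDITION)
        np.testing.assert_array_equal(a.frame.to_numpy(), b.frame.to_numpy())


class TestValidateCorrelations:
    def test_self_comparison_is_zero(self):
        stats = [make_stats(name, 30) for name in FTSTS_CONDITION.classes]
        ds = generate_dataset(stats, VariabilityConfig(seed=2), FTSTS_CONDITION)
        feats = ds.frame[list(FEATURE_COLUMNS)].to_numpy()
        ref = np.corrcoef(feats, rowvar=False)
        report = validate_correlations(ds, ref, tolerance=1e-12)
        assert report.max_abs_diff == 0.0
        assert report.passed

    def test_matches_naive_double_loop_covariance(self):
        stats = [make_stats(name, 20) for name in FTSTS_CONDITION.classes]
        ds = generate_dataset(stats, VariabilityConfig(seed=4), FTSTS_CONDITION)
        feats = ds.frame[list(FEATURE_COLUMNS)].to_numpy()
        n, p = feats.shape
        mu = feats.mean(axis=0)
        naive = np.eye(p)
        for i in range(p):
            for j in range(p):
                cov = sum((feats[t, i] - mu[i]) * (feats[t, j] - mu[j]) for t in range(n)) / n
                si = np.sqrt(sum((feats[t, i] - mu[i]) ** 2 for t in range(n)) / n)
                sj = np.sqrt(sum((feats[t, j] - mu[j]) ** 2 for t in range(n)) / n)
                naive[i, j] = cov / (si * sj)
        report = validate_correlations(ds, naive, tolerance=1e-9)
        assert report.max_abs_diff < 1e-12

    def test_zero_swap_cohort_fails_a_moderate_reference(self):
        # with no swaps, time and age are both sorted → |corr| near 1,
        # far above a moderate reference correlation
        table_stats = [make_stats(name, 60) for name in FTSTS_CONDITION.classes[:1]]
        cfg = VariabilityConfig(0.0, 0.0, seed=6)
        from rehablearn.schema_io import LabelTaxonomy

        tax = LabelTaxonomy("FTSTS", "condition_single", ("healthy",), "healthy")
        ds = generate_dataset(
            [make_stats("healthy", 60)], cfg, tax
        )
        ref = np.eye(6)
        ref[0, 1] = ref[1, 0] = 0.4  # moderate time↔age reference
        report = validate_correlations(ds, ref, tolerance=0.2)
        assert not report.passed
        i, j = 0, 1
        assert report.matrix[i, j] > 0.9


class TestFixtures:
    def test_tug_counts_sum_to_183(self, tug_fixture_raw):
        assert len(tug_fixture_raw) == 183
        counts = tug_fixture_raw.label_names("difficulty").value_counts().to_dict()
        assert counts == DEFAULT_FIXTURE_COUNTS["TUG"]

    def test_ftsts_classes_have_disjoint_time_ranges(self, ftsts_fixture_raw):
        f = ftsts_fixture_raw.frame
        slow = f[f["difficulty"] == 0]["completion_time_s"]
        fast = f[f["difficulty"] == 1]["completion_time_s"]
        assert slow.min() > fast.max()

    def test_improving_stream_has_negative_slope(self):
        stream = fixture_session_stream(10.0, 100, "improving", seed=1)
        slope = np.polyfit(np.arange(100), stream.times, 1)[0]
        assert slope < 0

    def test_abandon_stream_truncates_last_session(self):
        stream = fixture_session_stream(10.0, 5, "abandon", seed=1)
        assert stream.events[-1] == ("start",)
        assert all(e == ("start", "complete") for e in stream.events[:-1])

    def test_unknown_trend_rejected(self):
        with pytest.raises(ConfigError):
            fixture_session_stream(10.0, 5, "wobbling", seed=1)
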