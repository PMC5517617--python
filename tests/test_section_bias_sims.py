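"""Resampling power experiments, virtual sectioning and 2D/3D bias analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from isletscope import (
    ChannelVolume,
    SynthConfig,
    classify_pair,
    compare_2d_3d,
    generate_islet_volume,
    sampling_experiment,
    slab_section_radius,
    stat_tests,
    thin_section_radius_ratio,
    top_k_comparison,
    virtual_sections,
)
from isletscope.section_bias_sims import CLASSES


class TestSamplingExperiment:
    def test_null_type_one_error_near_alpha(self, rng):
        pop = rng.normal(50, 10, 2000)
        res = sampling_experiment(pop, pop, n=50, n_reps=400, seed=5)
        # binomial 99% band around 0.05 at 400 reps
        half = 2.576 * math.sqrt(0.05 * 0.95 / 400)
        assert abs(res.proportion_significant - 0.05) <= half + 0.01

    def test_power_matches_analytic_two_sample_oracle(self, rng):
        """Means 40 vs 50 μm, sd 10, n=100 → power from the noncentral t."""
        a = rng.normal(40, 10, 20000)
        b = rng.normal(50, 10, 20000)
        res = sampling_experiment(a, b, n=100, n_reps=400, seed=9)
        nc = (50 - 40) / (10 * math.sqrt(2 / 100))  # noncentrality
        df = 2 * 100 - 2
        tcrit = stats.t.ppf(0.975, df)
        power = 1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        assert res.proportion_significant == pytest.approx(power, abs=0.06)

    def test_single_repetition_is_binary(self, rng):
        pop = rng.normal(50, 10, 100)
        res = sampling_experiment(pop, pop, n=10, n_reps=1, seed=1)
        assert res.proportion_significant in (0.0, 1.0)

    def test_power_and_range_patterns_with_true_difference(self, rng):
        """Power grows and the min–max mean range shrinks with sample size."""
        a = rng.normal(45, 10, 5000)
        b = rng.normal(49.5, 10, 5000)
        props, widths = [], []
        for i, n in enumerate((10, 50, 150)):
            res = sampling_experiment(a, b, n=n, n_reps=300, seed=100 + i)
            props.append(res.proportion_significant)
            widths.append(res.mean_range_a[1] - res.mean_range_a[0])
        assert props[0] <= props[1] + 0.06 and props[1] <= props[2] + 0.06
        assert widths[0] >= widths[1] >= widths[2] * 0.8

    def test_determinism_and_validation(self, rng):
        pop = rng.normal(50, 10, 500)
        r1 = sampling_experiment(pop, pop, n=20, n_reps=50, seed=7)
        r2 = sampling_experiment(pop, pop, n=20, n_reps=50, seed=7)
        assert r1 == r2
        with pytest.raises(ValueError):
            sampling_experiment(pop, pop, n=1)


class TestVirtualSections:
    def test_every_third_40um_from_1mm_volume(self):
        """~1 mm volume at 5 μm z-step, 40 μm slabs, every third → 8 sections, ×3."""
        vol = ChannelVolume(np.zeros((8, 8, 192)), (5.0, 5.0, 5.0))
        stack, scale = virtual_sections(vol, 40.0, spacing="every_third")
        assert len(stack.sections) == 8
        assert scale == 3.0
        assert stack.z_ranges[0] == (0, 8) and stack.z_ranges[1] == (24, 32)

    def test_full_depth_single_section_is_whole_mip(self, rng):
        arr = rng.random((10, 10, 30))
        vol = ChannelVolume(arr, (5.0, 5.0, 5.0))
        stack, scale = virtual_sections(vol, 150.0, spacing=1)
        assert len(stack.sections) == 1
        assert scale == 1.0
        assert np.array_equal(stack.sections[0], arr.max(axis=2))

    def test_slabs_match_direct_max_oracle(self, rng):
        arr = rng.random((6, 6, 50))
        vol = ChannelVolume(arr, (5.0, 5.0, 5.0))
        stack, _ = virtual_sections(vol, 40.0, spacing=2)
        for (z0, z1), sec in zip(stack.z_ranges, stack.sections):
            assert np.array_equal(sec, arr[:, :, z0:z1].max(axis=2))

    def test_too_thin_volume_raises(self):
        vol = ChannelVolume(np.zeros((4, 4, 3)), (5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            virtual_sections(vol, 40.0)


class TestClassification:
    @pytest.mark.parametrize(
        "r2d,r3d,expected",
        [
            (8.0, 15.0, "false_negative"),
            (15.0, 8.0, "false_positive"),
            (5.0, 5.0, "excluded_small"),
            (48.0, 50.0, "within_tolerance"),
            (30.0, 50.0, "underestimate_gt_10pct"),
            (70.0, 50.0, "overestimate_gt_10pct"),
            (10.0, 10.0, "within_tolerance"),  # threshold boundary: 10 is not < 10
            (45.0, 50.0, "within_tolerance"),  # ratio 0.90 exactly on tolerance
            (9.999, 50.0, "false_negative"),
        ],
    )
    def test_rules_on_boundary_cases(self, r2d, r3d, expected):
        assert classify_pair(r2d, r3d) == expected

    def test_partition_on_random_pairs(self, rng):
        r2 = rng.uniform(0, 60, 10_000)
        r3 = rng.uniform(0.1, 60, 10_000)
        classes = [classify_pair(a, b) for a, b in zip(r2, r3)]
        assert set(classes) <= set(CLASSES)
        # exclusivity/exhaustiveness: classify_pair always returns exactly one label
        assert len(classes) == 10_000

    def test_zero_underestimation_when_equal(self):
        assert classify_pair(50.0, 50.0) == "within_tolerance"


class TestChordOracle:
    def test_thin_limit_is_pi_over_four(self):
        ratio = thin_section_radius_ratio(100_000, seed=3)
        assert ratio == pytest.approx(math.pi / 4, rel=0.01)

    def test_slab_radius_thick_limit_reaches_equator(self, rng):
        # of slabs intersecting the sphere, a fraction T/(T+2R) contain the equator
        vals = [slab_section_radius(50.0, 500.0, rng) for _ in range(5000)]
        expected = 500.0 / (500.0 + 2 * 50.0)
        assert np.mean([v == 50.0 for v in vals]) == pytest.approx(expected, abs=0.02)

    def test_slab_mean_ratio_increases_with_thickness(self, rng):
        means = []
        for th in (0.01, 20.0, 100.0):
            vals = [slab_section_radius(50.0, th, rng) for _ in range(20_000)]
            means.append(np.mean([v for v in vals if v > 0]) / 50.0)
        assert means[0] < means[1] < means[2]
        assert means[0] == pytest.approx(math.pi / 4, abs=0.02)


class TestStatTests:
    def test_identical_samples_ks_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        stat, _ = stat_tests(x, x, "ks")
        assert stat == 0.0

    def test_complete_separation_mannwhitney(self):
        u, p = stat_tests([1, 2, 3], [4, 5, 6], "mannwhitney")
        assert u == 0.0
        assert p < 0.2

    def test_zero_variance_equal_means_convention(self):
        stat, p = stat_tests([2.0, 2.0], [2.0, 2.0], "t")
        assert p == 1.0

    def test_null_pvalues_are_uniform(self):
        """t-test p-values under the null pass a KS test against U(0,1)."""
        rng = np.random.default_rng(17)
        x = rng.normal(0, 1, (10_000, 10))
        y = rng.normal(0, 1, (10_000, 10))
        res = stats.ttest_ind(x, y, axis=1)
        ks = stats.kstest(res.pvalue, "uniform")
        assert ks.pvalue > 0.01

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            stat_tests([1, 2], [3, 4], "anova")


class TestTopK:
    def test_fewer_than_k_averages_all(self):
        means2d, mean3d, _, _ = top_k_comparison([[10, 20, 30, 40, 50]], [60.0] * 30, k=20)
        assert means2d == [30.0]
        assert mean3d == 60.0

    def test_identical_radii_give_high_p(self):
        r = list(np.linspace(20, 80, 25))
        means2d, mean3d, _, p = top_k_comparison([r], np.array(r), k=20)
        assert means2d[0] == pytest.approx(mean3d)
        assert p > 0.5

    def test_thin_section_topk_mean_below_3d(self, rng):
        """Top-20 2D means fall short of top-20 3D means (chord-slicing sign check)."""
        radii = rng.uniform(20, 80, 200)
        r2d = [slab_section_radius(r, 5.0, rng) for r in radii]
        means2d, mean3d, _, p = top_k_comparison([r2d], radii, k=20)
        assert means2d[0] < mean3d
        assert p < 0.05

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            top_k_comparison([], [1.0, 2.0])


@pytest.fixture(scope="module")
def bias_volume():
    """~1×1×1.2 mm noiseless volume, enough islets to resolve the thickness trend."""
    cfg = SynthConfig(
        volume_shape=(200, 200, 240),
        n_islets=40,
        radius_distribution={"name": "lognormal", "median": 40, "sigma": 0.4},
        min_center_separation=120.0,
        background_noise=0.0,
        seed=7,
    )
    islet_ch, _, truth = generate_islet_volume(cfg)
    return islet_ch, truth


class TestCompare2d3d:
    def test_underestimation_shrinks_with_thickness(self, bias_volume):
        islet_ch, _ = bias_volume
        records, summary = compare_2d_3d(islet_ch, (10, 40, 110))
        factors = summary["mean_underestimation_factor"].to_numpy()
        sems = summary["sem_underestimation_factor"].to_numpy()
        # non-increasing up to Monte-Carlo error of each adjacent difference
        assert np.all(np.diff(factors) <= 2 * np.sqrt(sems[1:] ** 2 + sems[:-1] ** 2))
        assert factors[0] > factors[-1]

    def test_every_record_classified(self, bias_volume):
        islet_ch, _ = bias_volume
        records, _ = compare_2d_3d(islet_ch, (20, 80))
        assert records
        assert all(r.classification in CLASSES for r in records)
        for r in records:
            if r.r3d_um > 0:
                assert r.underestimation_factor == pytest.approx(
                    (r.r3d_um - r.r2d_um) / r.r3d_um
                )

    def test_full_depth_sections_are_nearly_unbiased(self, bias_volume):
        islet_ch, _ = bias_volume
        depth = islet_ch.n_planes * islet_ch.voxel_size[2]
        _, summary = compare_2d_3d(islet_ch, (depth,))
        assert abs(summary["mean_underestimation_factor"].iloc[0]) < 0.05
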