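import numpy as np
import pytest
from scipy import stats as sps

from hzkit.resampling import (
    _rotation_stats,
    bonferroni_threshold,
    circular_bootstrap,
    downsample_uniform,
    leave_one_out,
    uniformity_test,
)
from hzkit.simulate import SimulationConfig, simulate_cohort
from hzkit.stats import window_metrics


def toy_layout(n_chrom=4, per_chrom=25):
    chrom = np.repeat([f"c{i}" for i in range(n_chrom)], per_chrom)
    return chrom


class TestCircularBootstrap:
    def test_offset_zero_rotation_reproduces_observed(self, rng):
        metric = rng.normal(size=30)
        mask = np.zeros(30, bool)
        mask[[2, 3, 10]] = True
        sums, counts = _rotation_stats(metric, mask)
        assert sums[0] / counts[0] == pytest.approx(metric[mask].mean())

    def test_constant_metric_gives_p_one(self, rng):
        chrom = toy_layout()
        mask = rng.random(chrom.size) < 0.3
        res = circular_bootstrap(
            np.full(chrom.size, 3.14), mask, chrom, reps=200, seed=0
        )
        assert res.p_value == 1.0
        assert np.allclose(res.null_values, res.observed)

    def test_null_length_and_seed_determinism(self, rng):
        chrom = toy_layout()
        metric = rng.normal(size=chrom.size)
        mask = np.zeros(chrom.size, bool)
        mask[::7] = True
        for scheme in ("chrom-circular", "chrom-random",
                       "genome-circular", "genome-random"):
            a = circular_bootstrap(metric, mask, chrom, scheme=scheme,
                                   reps=137, seed=5)
            b = circular_bootstrap(metric, mask, chrom, scheme=scheme,
                                   reps=137, seed=5)
            assert a.null_values.shape == (137,)
            assert np.array_equal(a.null_values, b.null_values)
            assert 0 < a.p_value <= 1

    def test_chrom_and_genome_circular_agree_on_single_chromosome(self, rng):
        chrom = np.repeat(["c1"], 40)
        metric = rng.normal(size=40)
        mask = np.zeros(40, bool)
        mask[[1, 2, 3, 17]] = True
        a = circular_bootstrap(metric, mask, chrom, "chrom-circular",
                               reps=99, seed=3)
        b = circular_bootstrap(metric, mask, chrom, "genome-circular",
                               reps=99, seed=3)
        assert np.array_equal(a.null_values, b.null_values)

    def test_degenerate_mask_rejected(self, rng):
        chrom = toy_layout(1, 10)
        with pytest.raises(ValueError, match="degenerate"):
            circular_bootstrap(np.ones(10), np.ones(10, bool), chrom)

    def test_missing_metrics_skipped(self, rng):
        chrom = toy_layout(2, 10)
        metric = rng.normal(size=20)
        metric[0] = np.nan
        mask = np.zeros(20, bool)
        mask[[0, 5]] = True
        res = circular_bootstrap(metric, mask, chrom, reps=50, seed=1)
        assert res.observed == pytest.approx(metric[5])

    def test_p_values_uniform_under_exchangeable_null(self):
        """With the metric shuffled across windows, chrom-circular p-values
        are approximately U(0,1) over seeded runs."""
        chrom = toy_layout(5, 30)
        base_mask = np.zeros(chrom.size, bool)
        base_mask[::5] = True
        master = np.random.default_rng(2024)
        ps = []
        for _ in range(200):
            metric = master.normal(size=chrom.size)
            res = circular_bootstrap(
                metric, base_mask, chrom, reps=199,
                rng=np.random.default_rng(master.integers(2**31)),
            )
            ps.append(res.p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestLeaveOneOut:
    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(6) == pytest.approx(0.05 / 6)
        assert round(bonferroni_threshold(6), 3) == 0.008
        assert bonferroni_threshold(1) == 0.05
        with pytest.raises(ValueError):
            bonferroni_threshold(0)

    def test_needs_three_hz_samples(self, rng):
        from conftest import random_cohort

        c = random_cohort(rng, n_samples=4)  # only one HZ sample
        with pytest.raises(ValueError, match="3 HZ"):
            leave_one_out(c, None, None)

    def test_per_sample_p_values_stable_on_suppressed_cohort(self):
        cohort, truth = simulate_cohort(
            SimulationConfig(seed=21, missing_rate=0.0, nuisance_private_rate=0.0)
        )
        out = leave_one_out(
            cohort, truth.windows, truth.windows.barrier,
            metric="dbar", reps=200, seed=4,
        )
        assert len(out) == 6
        assert out.attrs["bonferroni_threshold"] == pytest.approx(0.05 / 6)
        # the enrichment signal survives every exclusion
        assert (out["p_value"] < 0.05).all()


class TestDownsample:
    def test_exact_multiples_all_kept(self):
        pos = np.array([1100, 2200, 3300])
        assert downsample_uniform(pos).tolist() == [0, 1, 2]

    def test_tie_breaks_toward_smaller_position(self):
        idx = downsample_uniform(np.array([100, 1050, 1150]), spacing=1100)
        assert idx.tolist() == [1]

    def test_site_kept_for_at_most_one_multiple(self):
        # site 1650 is the argmin for both multiples 1100 and 2200 but
        # appears once in the kept set
        idx = downsample_uniform(np.array([1650, 10_000]), spacing=1100)
        assert idx.tolist() == [0, 1]

    def test_matches_per_multiple_argmin_oracle(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 60_000), size=300, replace=False))
        spacing = 1100
        got = downsample_uniform(pos, spacing).tolist()
        expected = sorted(
            {
                int(np.argmin(np.abs(pos - k * spacing)))
                for k in range(1, int(pos.max() // spacing) + 1)
            }
        )
        assert got == expected

    def test_output_strictly_increasing_subset(self, rng):
        pos = np.sort(rng.choice(np.arange(1, 100_000), size=500, replace=False))
        idx = downsample_uniform(pos)
        kept = pos[idx]
        assert (np.diff(kept) > 0).all()
        assert set(kept).issubset(set(pos))


class TestUniformity:
    def test_regular_grid_passes(self):
        res = uniformity_test(np.arange(1, 201) * 500)
        assert res.pvalue > 0.05

    def test_smooth_density_gradient_fails(self):
        # smoothly non-uniform (no isolated deserts): excision cannot fix it
        rng = np.random.default_rng(0)
        pos = np.unique((np.sort(rng.random(300)) ** 2 * 1e6).astype(int)) + 1
        res = uniformity_test(pos)
        assert res.pvalue < 0.05

    def test_no_excision_on_gap_free_data_matches_default(self):
        pos = np.arange(1, 101) * 1000  # equal gaps: excision changes nothing
        a = uniformity_test(pos, excise_largest_gaps=0)
        b = uniformity_test(pos, excise_largest_gaps=5)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_excision_rescues_gappy_but_uniform_data(self):
        rng = np.random.default_rng(3)
        left = np.sort(rng.choice(np.arange(1, 50_000), 200, replace=False))
        right = np.sort(rng.choice(np.arange(500_000, 550_000), 200, replace=False))
        pos = np.concatenate([left, right])
        assert uniformity_test(pos, excise_largest_gaps=0).pvalue < 0.05
        assert uniformity_test(pos, excise_largest_gaps=5).pvalue > 0.05

    def test_too_few_sites_flagged(self):
        with pytest.raises(ValueError):
            uniformity_test(np.arange(5))
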