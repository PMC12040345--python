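import numpy as np
import pytest

from hzkit.cohort import MISSING
from hzkit.stats import (
    count_junctions,
    dbar,
    high_di_density,
    hwe_expected_h,
    hybrid_index,
    interspecific_heterozygosity,
    ternary_table,
)
from hzkit.windows import make_windows

from conftest import build_cohort, random_cohort


def dbar_pairwise_oracle(states):
    """Brute-force O(L^2) mean across-sample covariance of dosage/2 over all
    ordered site pairs (self-pairs included); complete data only."""
    d = np.asarray(states, dtype=float) / 2.0
    n, L = d.shape
    total = 0.0
    for i in range(L):
        for j in range(L):
            total += np.mean(d[:, i] * d[:, j]) - d[:, i].mean() * d[:, j].mean()
    return total / (L * L)


WHOLE = ("chr1", 0, 10**9)


class TestHybridIndexAndH:
    def test_all_homozygous_b_gives_hi_one(self):
        c = build_cohort([[2, 2, 2]])
        assert hybrid_index(c)["hi"].tolist() == [1.0]

    def test_equal_state_frequencies_give_half(self):
        c = build_cohort([[0, 1, 2]])
        assert hybrid_index(c)["hi"].tolist() == [0.5]

    def test_empty_scope_is_nan_not_zero(self):
        c = build_cohort([[MISSING, MISSING]])
        assert np.isnan(hybrid_index(c)["hi"].iloc[0])

    def test_h_examples(self):
        f1 = build_cohort([[1, 1, 1]])
        parental = build_cohort([[0, 0, 0]])
        mixed = build_cohort([[1, 1, 0, 2]])
        assert interspecific_heterozygosity(f1)["h"].tolist() == [1.0]
        assert interspecific_heterozygosity(parental)["h"].tolist() == [0.0]
        assert interspecific_heterozygosity(mixed)["h"].tolist() == [0.5]

    def test_missing_excluded_from_denominator(self):
        c = build_cohort([[2, MISSING, 0, 2]])
        assert hybrid_index(c)["hi"].tolist() == [pytest.approx(2 / 3)]

    def test_chromosome_and_window_scopes(self):
        c = build_cohort(
            [[0, 0, 2, 2]], chrom=["chr1", "chr1", "chr2", "chr2"],
            pos=[100, 200, 100, 200],
        )
        by_chrom = hybrid_index(c, scope="chromosome")
        assert by_chrom.set_index("chromosome")["hi"].to_dict() == {
            "chr1": 0.0, "chr2": 1.0,
        }
        ws = make_windows(c.chromosomes, span=150, overlap=0.0)
        by_win = hybrid_index(c, scope="window", windows=ws)
        assert len(by_win) == len(ws)

    def test_ternary_constraint_under_fuzzing(self, rng):
        for _ in range(20):
            c = random_cohort(rng, n_samples=5, n_sites=40)
            t = ternary_table(c)
            ok = t["hi"].notna()
            hi, h = t.loc[ok, "hi"], t.loc[ok, "h"]
            assert (h <= 2 * np.minimum(hi, 1 - hi) + 1e-12).all()


class TestHWE:
    def test_values(self):
        assert hwe_expected_h(0.5) == 0.5
        assert hwe_expected_h(0.0) == 0.0
        assert hwe_expected_h(0.712) == pytest.approx(0.410112, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hwe_expected_h(1.2)


class TestDbar:
    def test_three_versus_three_pure_attains_maximum(self):
        states = [[0] * 4] * 3 + [[2] * 4] * 3
        c = build_cohort(states)
        assert dbar(c, WHOLE) == 0.25

    def test_identical_samples_give_zero(self):
        c = build_cohort([[0, 1, 2]] * 4)
        assert dbar(c, WHOLE) == 0.0

    def test_fewer_than_two_samples_is_nan(self):
        c = build_cohort([[0, 1]])
        assert np.isnan(dbar(c, WHOLE))

    def test_equals_pairwise_covariance_oracle(self, rng):
        states = rng.integers(0, 3, size=(6, 40))
        c = build_cohort(states)
        assert dbar(c, WHOLE) == pytest.approx(dbar_pairwise_oracle(states), abs=1e-12)

    def test_range_invariant(self, rng):
        for _ in range(20):
            states = rng.integers(0, 3, size=(5, 15))
            v = dbar(build_cohort(states), WHOLE)
            assert 0.0 <= v <= 0.25


class TestJunctions:
    def test_constant_states_give_zero(self):
        c = build_cohort([[1, 1, 1, 1]])
        assert count_junctions(c, WHOLE) == 0

    def test_single_sample_run(self):
        c = build_cohort([[2, 2, 1, 1, 2]])
        assert count_junctions(c, WHOLE) == 2

    def test_unique_deduplicates_shared_gaps(self):
        c = build_cohort([[0, 2, 2], [0, 2, 2], [0, 0, 2]])
        assert count_junctions(c, WHOLE) == 2  # gap1 shared, gap2 private
        per = count_junctions(c, WHOLE, per_sample=True)
        assert per.tolist() == [1, 1, 1]

    def test_missing_breaks_pair_not_counted(self):
        c = build_cohort([[0, MISSING, 2]])
        assert count_junctions(c, WHOLE) == 0

    def test_invariant_to_state_repeating_insertion(self):
        before = build_cohort([[0, 2, 2, 1]], pos=[100, 200, 300, 400])
        after = build_cohort([[0, 2, 2, 2, 1]], pos=[100, 200, 250, 300, 400])
        assert count_junctions(before, WHOLE) == count_junctions(after, WHOLE)

    def test_assigned_to_window_of_left_marker(self):
        c = build_cohort([[0, 2]], pos=[100, 300])
        assert count_junctions(c, ("chr1", 0, 150)) == 1
        assert count_junctions(c, ("chr1", 150, 400)) == 0

    def test_pooled_junctions_match_ground_truth_gaps(self, clean_cohort):
        """Each detected unique junction gap must contain >= 1 true junction,
        and every true junction interior to the marker span is detected."""
        cohort, truth = clean_cohort
        chrom_id, length = cohort.chromosomes[0]
        idx = np.nonzero(cohort.chrom == chrom_id)[0]
        pos = cohort.pos[idx]
        hz = [s for s, g in zip(cohort.sample_ids, cohort.sample_groups) if g == "HZ"]
        for sid in hz[:2]:
            st = cohort.states[cohort.sample_index(sid), idx]
            true_j = np.sort(
                truth.junctions.query("sample == @sid and chromosome == @chrom_id")[
                    "position"
                ].to_numpy()
            )
            # detected junction gaps for this sample
            changes = np.nonzero(np.diff(st) != 0)[0]
            for g in changes:
                lo, hi = pos[g], pos[g + 1]
                assert ((true_j > lo - 1) & (true_j < hi)).any()


class TestHighDI:
    def test_none_above_threshold(self):
        c = build_cohort([[0, 0]], di=[-30.0, -25.0])
        assert high_di_density(c, WHOLE) == (0, 0.0)

    def test_count_and_per_bp(self):
        c = build_cohort([[0] * 6], di=[-5, -5, -5, -5, -5, -30],
                         pos=[10, 20, 30, 40, 50, 60])
        count, per_bp = high_di_density(c, ("chr1", 0, 10_000))
        assert count == 5 and per_bp == 5e-4

    def test_matches_elementwise_oracle(self, rng):
        c = random_cohort(rng, n_sites=50)
        w = ("chr1", 0, 10_000)
        count, _ = high_di_density(c, w)
        expected = sum(
            1 for j in range(c.n_sites)
            if c.chrom[j] == "chr1" and c.pos[j] - 1 < 10_000 and c.di[j] > -20
        )
        assert count == expected


class TestLabelSwapSymmetry:
    def test_swap_0_2_maps_hi_and_preserves_h_dbar_junctions(self, rng):
        states = rng.integers(0, 3, size=(5, 30))
        c = build_cohort(states)
        swapped = build_cohort(np.where(states == MISSING, states, 2 - states))
        assert np.allclose(
            hybrid_index(swapped)["hi"], 1 - hybrid_index(c)["hi"]
        )
        assert np.allclose(
            interspecific_heterozygosity(swapped)["h"],
            interspecific_heterozygosity(c)["h"],
        )
        assert dbar(swapped, WHOLE) == pytest.approx(dbar(c, WHOLE), abs=1e-12)
        assert count_junctions(swapped, WHOLE) == count_junctions(c, WHOLE)
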