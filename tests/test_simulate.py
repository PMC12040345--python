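import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hzkit.cohort import MISSING
from hzkit.simulate import (
    SimulationConfig,
    sample_layout,
    simulate_backcross,
    simulate_cohort,
)
from hzkit.stats import hybrid_index, interspecific_heterozygosity
from hzkit.tract_model import TractModelParams
from hzkit.windows import make_windows, sites_in_window


class TestMakeWindows:
    def test_abutting_tiling(self):
        ws = make_windows([("c", 1000)], span=100, overlap=0.0)
        assert len(ws) == 10
        assert ws.start.tolist() == list(range(0, 1000, 100))

    def test_twenty_percent_overlap_steps(self):
        ws = make_windows([("c", 1000)], span=100, overlap=0.2)
        assert ws.start.tolist()[:4] == [0, 80, 160, 240]

    def test_short_partial_window_dropped(self):
        # last partial window kept only if >= half a span
        ws = make_windows([("c", 1040)], span=100, overlap=0.0)
        assert ws.end.max() == 1000
        ws2 = make_windows([("c", 1060)], span=100, overlap=0.0)
        assert ws2.end.max() == 1060

    def test_span_longer_than_chromosome(self):
        ws = make_windows([("c", 50)], span=100, overlap=0.0)
        assert len(ws) == 1 and (ws.start[0], ws.end[0]) == (0, 50)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        span=st.integers(min_value=1, max_value=500),
        overlap=st.floats(min_value=0.0, max_value=0.9),
        length=st.integers(min_value=1, max_value=5000),
    )
    def test_invariants_on_random_configs(self, span, overlap, length):
        ws = make_windows([("c", length)], span, overlap)
        assert (ws.start < ws.end).all()
        assert (np.diff(ws.start) > 0).all()
        assert ws.end.max() <= length
        assert len(ws) >= 1

    def test_bad_args_rejected(self):
        with pytest.raises(ValueError):
            make_windows([("c", 100)], span=0)
        with pytest.raises(ValueError):
            make_windows([("c", 100)], span=10, overlap=1.0)


class TestSimulateCohort:
    def test_zero_occupancy_gives_pure_samples(self):
        cfg = SimulationConfig(
            seed=1, minority_occupancy=0.0, missing_rate=0.0,
            nuisance_private_rate=0.0,
            chromosomes=[["chr1", 2_000_000]],
        )
        cohort, truth = simulate_cohort(cfg)
        hi = hybrid_index(cohort).set_index("sample")["hi"]
        _, _, majority = sample_layout(cfg)
        for sid, g in zip(cohort.sample_ids, cohort.sample_groups):
            assert hi[sid] == (0.0 if majority[sid] == "A" else 1.0)
        assert len(truth.junctions) == 0

    def test_fixed_seed_is_deterministic(self, sim_cohort):
        cohort, truth = sim_cohort
        c2, t2 = simulate_cohort(SimulationConfig(seed=3))
        assert cohort.equals(c2)
        assert truth.tracts.equals(t2.tracts)
        assert truth.junctions.equals(t2.junctions)

    def test_junction_count_matches_tract_count(self, clean_cohort):
        """Per sample-chromosome: junctions = (segments - 1) summed over both
        haplotypes."""
        _, truth = clean_cohort
        tcount = truth.tracts.groupby(
            ["sample", "chromosome", "haplotype"]
        ).size()
        jcount = truth.junctions.groupby(
            ["sample", "chromosome", "haplotype"]
        ).size()
        for key, n_seg in tcount.items():
            assert jcount.get(key, 0) == n_seg - 1

    def test_states_consistent_with_haplotype_paths(self, clean_cohort):
        """Emitted diploid states equal the sum of the two haplotype
        ancestries at every marker (noise-free generator)."""
        cohort, truth = clean_cohort
        _, _, majority = sample_layout(truth.config)
        chrom_id = cohort.chromosomes[0][0]
        idx = np.nonzero(cohort.chrom == chrom_id)[0]
        pos = cohort.pos[idx]
        for sid in cohort.samples_in_group("HZ")[:3]:
            states = cohort.states[cohort.sample_index(sid), idx]
            dosage = np.zeros(pos.size, dtype=int)
            for h in (0, 1):
                segs = truth.tracts.query(
                    "sample == @sid and chromosome == @chrom_id and haplotype == @h"
                ).sort_values("start")
                ends = segs["end"].to_numpy()
                anc = (segs["ancestry"] == "B").to_numpy().astype(int)
                j = np.searchsorted(ends, pos - 0.5, side="right")
                dosage += anc[np.minimum(j, len(anc) - 1)]
            assert np.array_equal(states, dosage)

    def test_barrier_suppression_reduces_minority_occupancy(self, clean_cohort):
        cohort, truth = clean_cohort
        _, _, majority = sample_layout(truth.config)
        minority = truth.minority_tracts(majority)
        minority = minority[minority["sample"].str.startswith("HZ")]
        ws = truth.windows
        occ = np.zeros(len(ws))
        for i in range(len(ws)):
            sel = minority["chromosome"] == ws.chrom[i]
            ov = np.minimum(minority.loc[sel, "end"], ws.end[i]) - np.maximum(
                minority.loc[sel, "start"], ws.start[i]
            )
            occ[i] = ov.clip(lower=0).sum() / ws.span[i]
        assert occ[ws.barrier].mean() < 0.5 * occ[~ws.barrier].mean()

    def test_marker_density_scales_with_multiplier(self, clean_cohort):
        """Marker counts per bp in barrier vs non-barrier windows reflect the
        configured density multiplier (chi-squared on pooled counts)."""
        from hzkit.simulate import _barrier_union

        cohort, truth = clean_cohort
        mult = truth.config.barrier_marker_multiplier
        n_b = n_n = 0
        bp_b = bp_n = 0
        for chrom_id, length in cohort.chromosomes:
            union = _barrier_union(truth.windows, chrom_id)
            bp_in = sum(e - s for s, e in union)
            bp_b += bp_in
            bp_n += length - bp_in
            pos0 = cohort.pos[cohort.chrom == chrom_id] - 1
            inside = np.zeros(pos0.size, dtype=bool)
            for s, e in union:
                inside |= (pos0 >= s) & (pos0 < e)
            n_b += int(inside.sum())
            n_n += int((~inside).sum())
        w_b, w_n = mult * bp_b, bp_n
        f_exp = np.array([w_b, w_n]) / (w_b + w_n) * (n_b + n_n)
        p = sps.chisquare([n_b, n_n], f_exp=f_exp).pvalue
        assert p > 0.01

    def test_nuisance_private_sites_flagged_and_censorable(self, sim_cohort):
        from hzkit.cohort import censor_nuisance_sites

        cohort, truth = sim_cohort
        kept = censor_nuisance_sites(cohort)
        removed = cohort.n_sites - kept.n_sites
        assert removed >= 0.9 * truth.nuisance_private_sites.size

    def test_secondary_contact_mode_runs(self):
        params = TractModelParams(M=5.0, S=0.0, R=0.25, T=50)
        cfg = SimulationConfig(
            seed=7, mode="secondary_contact",
            sc_params_into_a=params, sc_params_into_b=params,
            chromosomes=[["chr1", 5_000_000]], missing_rate=0.0,
            nuisance_private_rate=0.0,
        )
        cohort, truth = simulate_cohort(cfg)
        assert (truth.tracts.groupby(["sample", "chromosome", "haplotype"]).size()
                - 1).sum() == len(truth.junctions)


class TestBackcross:
    def test_f1_everywhere_heterozygous(self):
        bc = simulate_backcross(1, SimulationConfig(seed=2), n_individuals=3)
        assert (bc.states == 1).all()
        assert interspecific_heterozygosity(bc)["h"].tolist() == [1.0] * 3

    def test_no_homozygous_b_in_backcrosses_to_a(self):
        for n in (2, 3, 4):
            bc = simulate_backcross(n, SimulationConfig(seed=n), n_individuals=20)
            assert not (bc.states == 2).any()

    def test_requires_positive_generation(self):
        with pytest.raises(ValueError):
            simulate_backcross(0, SimulationConfig())
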