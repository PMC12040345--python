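# hzkit

Hybrid-zone ancestry analysis from polarised diploid genomes.

When two hybridising sister species meet at a narrow contact zone, a handful
of admixed genomes contains a surprising amount of information about the
barrier to gene flow between them.  Given genotypes that have been
*polarised* — each allele labelled by species of origin, so every site of
every diploid is homozygous species A (`0`), heterozygous by source (`1`),
homozygous species B (`2`) or missing — `hzkit` quantifies recent
introgression along the genome and fits the aggregate strength of the
multilocus barrier.  It is aimed at population geneticists analysing
hybrid-zone cohorts downstream of a genome-polarisation step, and at anyone
who wants a tested reference implementation of the statistics involved.

## What it computes

**Per-sample and per-window statistics.**  The hybrid index
*HI* = mean allele dosage / 2 (0 and 1 are the pure species) and
interspecific heterozygosity *H* (the fraction of heterozygous-by-source
genotypes; 1 in an F1) place each genome in the ternary diagram whose
Hardy-Weinberg expectation is *H* = 2·*HI*·(1 − *HI*); an *n*-th generation
backcross has expected *HI* = (1/2)ⁿ.  Window-wise barrier strength is
measured by D̄, the multi-site mean pairwise linkage disequilibrium among
polarised markers — numerically the variance of per-sample window *HI*,
ranging from 0 (uncorrelated sites) to 0.25 (every sample pure) — together
with the density of unique ancestry junctions (depleted where selection
removes admixed ancestry) and of strongly diagnostic sites (DI > −20).

**Tracts and the coupling coefficient.**  States are low-pass filtered with
a truncated Laplace kernel (scale 10⁻⁴ × chromosome length, 95% truncation)
and parsed parsimoniously into minority-ancestry haplotype tracts.  Under
secondary contact at time *T* with *M* migrant genomes per generation,
recombination *R* (Morgans per chromosome) and aggregate selection *S*
against heterospecific ancestry, the equilibrium tract-length distribution
is a power law whose log-log gradient is −(3 + θ)/(1 + θ), where
θ = *S*/*R* is the coupling coefficient: −3 when introgression is neutral,
approaching −1 as coupling grows, with θ = 1 the tipping point where
multilocus clines congeal.  `hzkit` implements the exact finite-*T*
expectation of this model, a forward simulator, and maximum-likelihood
fitting of θ (and a lower bound on *T*) from observed relative tract
lengths *x* > 0.04.

**Significance by circular bootstrap.**  Because windows overlap and are
autocorrelated, enrichment of any metric in barrier-labelled windows is
tested by rotating the barrier labels around each circularised chromosome
(or the whole genome) by random offsets — preserving label clustering while
breaking the label–metric association — with leave-one-sample-out reruns
and marker-downsampling (spacing chosen by a Cramér–von Mises uniformity
test) as robustness checks.

**Synthetic cohorts with ground truth.**  A generator emulates the data
such a study produces — ~20 diploids over several autosomes, mosaic
two-ancestry tracts with suppressed minority occupancy inside barrier
windows, heterogeneous marker density and DI, nuisance-group private
homozygous states — recording every haplotype tract and junction, so each
stage is validated against known truth.

## Worked example

```python
import numpy as np
from hzkit import (
    SimulationConfig, simulate_cohort, censor_nuisance_sites, filter_by_di,
    ternary_table, window_metrics, circular_bootstrap,
    TractModelParams, simulate_tract_lengths, fit_tract_model,
)

# a synthetic hybrid-zone cohort: 6 admixed + 12 parental + 2 nuisance diploids
cohort, truth = simulate_cohort(SimulationConfig(seed=3))
cohort = censor_nuisance_sites(cohort)           # drop second-barrier sites

hi_h = ternary_table(filter_by_di(cohort, -20.0))
print(hi_h[hi_h["sample"] == "HZ1"].round(3).to_string(index=False))

wm = window_metrics(cohort, truth.windows, di_threshold=-20.0)
res = circular_bootstrap(
    wm["dbar"].to_numpy(), truth.windows.barrier, truth.windows.chrom,
    scheme="chrom-circular", reps=1000, seed=7, alternative="greater",
)
print(f"mean D-bar in barrier windows: {res.observed:.3f}, "
      f"null mean: {np.mean(res.null_values):.3f}, p = {res.p_value:.4f}")

# neutral tract-length cohort and the equilibrium gradient
lengths = simulate_tract_lengths(
    TractModelParams(M=40, S=0.0, R=0.25, T=150), n_tracts=100_000, seed=1
)
fit = fit_tract_model(lengths, l_min=0.04, R=0.25, T=150)
print(f"fitted theta = {fit.theta:.3f}, log-log gradient = {fit.gradient:.3f}")
```

prints

```
sample    hi     h  h_hwe  hwe_deficit
   HZ1 0.108 0.201  0.193        0.009
mean D-bar in barrier windows: 0.191, null mean: 0.174, p = 0.0040
fitted theta = 0.013, log-log gradient = -2.974
```

Sample HZ1 is a complex hybrid (≈11% species-B ancestry, slightly *above*
its Hardy-Weinberg heterozygosity expectation); D̄ in barrier windows
exceeds its circular-bootstrap null (introgression is suppressed exactly
where the barrier labels sit, p ≈ 0.004); and 10⁵ tracts simulated under
the neutral model recover the −3 equilibrium gradient (θ ≈ 0).

## The analysis, step by step

The `analysis/` directory is a numbered, re-runnable account of the full
study on synthetic data, writing tables under `results/`:

| script | does |
|---|---|
| `01_simulate_cohort.py` | generate the study-scale cohort + ground truth |
| `02_window_statistics.py` | filters, HI–H ternary tables, window metrics |
| `03_smooth_and_parse_tracts.py` | Laplace smoothing, tract parsing |
| `04_fit_tract_model.py` | coupling-coefficient fits, direction asymmetry |
| `05_barrier_bootstraps.py` | four bootstrap schemes, leave-one-out, downsampling |
| `06_demography_identity.py` | scaled-migration arithmetic M/2 = 2·Nₑ·mₑ |

The same pipeline is scriptable end to end via `hzkit run config.yaml` (see
`hzkit --help` for the per-stage subcommands: `stats`, `smooth`, `tracts`,
`fit-tracts`, `bootstrap`, `downsample`).

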