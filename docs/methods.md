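# Methods

This note documents the models implemented in `hzkit`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data tests
do and do not establish about real data.

## Polarised genotypes and coordinates

All analyses start from diploid genotypes polarised with respect to a single
species barrier: per site, `0` = homozygous species A, `1` = heterozygous by
source, `2` = homozygous species B, `.` = missing.  The per-site diagnostic
index (DI) is treated as an opaque input on a negative log-like scale
(larger = more diagnostic); the default keep-rule retains sites with
DI > −20.  Marker positions are 1-based; windows and tract intervals are
0-based half-open (BED convention), so a marker at position *p* lies in
window [start, end) iff start ≤ *p* − 1 < end.

Site filters are site-wise predicates, hence idempotent and mutually
commuting (property-tested):

- **DI filter** — keep sites with DI strictly above the threshold.
- **Singleton removal** — drop sites whose pooled minority allele dosage is
  exactly 1 (uninformative for polarisation by association); allele dosage
  counts exclude missing genotypes, and an all-missing site is dropped with
  a warning.
- **Nuisance censoring** — when a second barrier segregates in the cohort
  (e.g. a geographic split inside one species), sites whose *minority
  homozygous state* is carried only by the designated nuisance samples are
  censored.  A tie between the two homozygote counts is *not* censored:
  only unambiguous private-nuisance signal is removed.

## Window statistics

Per window (default tiling: fixed span, 20% overlap, last partial window
kept if ≥ half a span):

- **D̄** — the multi-site mean pairwise LD among polarised markers,
  computed as the *population* (divide-by-n) variance across samples of the
  per-sample window hybrid index.  The divide-by-n convention is required
  for the maximum of 0.25 to be attained by a 3-versus-3 pure
  configuration; the equivalence of var(HI) with the mean across-sample
  covariance of dosage/2 over all ordered site pairs (self-pairs included)
  is asserted in tests to 1e-12 on complete data.  A sample with no
  non-missing site in the window is excluded; fewer than two contributing
  samples gives a missing value, never 0.
- **Unique ancestry junctions** — an adjacent-marker pair (both genotypes
  present) whose states differ for a sample, located in the inter-marker
  gap.  Junction gaps are deduplicated across samples by default (a
  per-sample mode exists); a junction belongs to the window containing its
  left marker, which is deterministic under overlapping windows.  Counts
  are also reported per bp of span.
- **High-DI site density** — count and per-bp density of sites above the DI
  threshold.

The ternary constraint H ≤ 2·min(HI, 1 − HI), the 0↔2 label-swap symmetry
(HI → 1 − HI with H, D̄ and junction counts invariant), and the backcross
expectation E[HI] = (1/2)ⁿ are enforced as property tests.

## Kernel smoothing

Polarisation is per-site, so single miscalled or mispolarised sites fragment
tracts — and a single interior error halves the estimated tract length on
average.  Smoothing therefore acts as a low-pass filter before parsing:
each site takes the state with the greatest summed truncated-Laplace kernel
weight over its neighbourhood (weights exp(−|Δ|/b) within the 95% central
mass, radius b·ln 20 ≈ 3b; zero outside).

- The scale stated as a fraction of chromosome length (default 10⁻⁴) is
  interpreted as the Laplace scale parameter *b*, with truncation applied on
  top.  The alternative reading (fraction = truncation radius) changes the
  effective bandwidth about threefold and is available via
  `scale_is_radius=True`.
- Ties keep the centre site's original state (minimal change, and no
  scan-direction chirality).  A missing centre takes the neighbour argmax
  and stays missing only if no non-missing neighbour is in range.
- Consequence, verified against generator truth: tracts much shorter than
  the kernel scale are censored (a known false-negative class), tracts much
  longer are preserved with cleaner boundaries.

## Tract parsing

Against a majority homozygous background (the homozygote covering more
non-missing markers; an exact tie skips the chromosome with a warning),
every maximal run of non-background states — heterozygous,
minority-homozygous, or mixed — is counted as **one** tract on one
haplotype spanning the run.  The alternative explanation (two haplotype
tracts abutting perfectly without overlap) is treated as negligibly rare.
This deliberately censors smaller blocks positionally inside a larger
counted block of the same diploid, so tract counts are a lower bound for
overlapping-haplotype configurations (asserted ≤ truth on generator
output; an exhaustive 4⁶ six-marker comparison against a brute-force
run-length oracle covers the parser logic).

Missing states inside a run neither break nor extend it.  Tract boundaries
default to the midpoints of the flanking gaps to the nearest background
marker (chromosome ends when unflanked), so lengths are not biased downward
by marker sparsity; a marker-span mode is available.  Relative length
x = span / chromosome length; with one obligate crossover per male meiosis
and achiasmatic females the sex-averaged map length is R = 0.25 Morgans per
chromosome, so a tract's map length is 0.25·x Morgans.

## The secondary-contact tract-length model

Assumptions: introgression into each species starts T generations ago and
proceeds at a constant rate of M migrant genomes per generation; the
recipient population is infinite, so introgressed material only ever
backcrosses and every crossover product persists in some descendant;
selection against heterospecific ancestry is aggregate and linear in tract
map length (weak-selection regime), removing a tract of relative length x
with probability S·x per generation; crossovers fall as a homogeneous
Poisson process of rate R per unit relative length per generation.

The expected number density n(x, t) then obeys

    dn/dt = M δ(x−1) − (R + S)·x·n(x) + 2R ∫ₓ¹ n(y) dy,

whose stationary small-x solution is the power law x^−(1 + 2/(1+θ)) with
θ = S/R — i.e. a log-log gradient of −(3 + θ)/(1 + θ): −3 neutral, −1 in
the strong-coupling limit, θ = 1 the congealing threshold.

Implementation:

- `density_on_grid` iterates the exact per-generation operator (influx,
  viability 1 − S·x, Poisson fragmentation) on a 3000-point log grid,
  carrying the never-recombined full-length tracts as an explicit atom at
  x = 1.  For S = 0 a closed form exists (each migrant cohort of age t is
  [0,1] fragmented by a Poisson(R·t) process), and the recursion is checked
  against it.
- `simulate_tract_lengths` runs the same process forward with Poisson(M)
  influx per generation; simulator and expectation agree by
  Kolmogorov–Smirnov on the recombined part at n = 10⁴ for both study-style
  parameter sets.
- **Fitting.**  Long tracts (x > 0.04; 20 equal log₁₀ bins up to the
  longest observed tract, a binning chosen to stabilise the tail) are
  fitted by maximising the Poisson likelihood of the bin counts against the
  finite-T expectation, with the scale M profiled out analytically and
  θ ∈ [0, 4] optimised; T is fixed when known, otherwise profiled over a
  log-spaced grid and reported as a **lower bound** (short tracts
  equilibrate slowly, so finite data cannot exclude older contact).  The
  short-tract regime is excluded both because of that slow equilibration
  and because smoothing censorship and local recombination-rate variation
  distort it in real data.
- Two deliberate deviations from the plainer recipe of fitting a straight
  line to the log-binned histogram: (i) at the study's time scales the raw
  histogram slope is biased — the expected neutral slope at [R = 0.25,
  T = 150] is −2.63, not −3, purely from finite-T truncation — so the
  default estimator matches the finite-T curve instead (the raw slope is
  still reported as `slope_raw`); (ii) least squares on *log* counts is
  further biased upward in θ at small sample sizes (empty tail bins are
  dropped and E[log N] < log E[N]; at 400 tracts a neutral truth fits as
  θ ≈ 0.67), whereas the Poisson likelihood keeps empty bins informative
  (θ ≈ 0.25 at 400 tracts, errors < 0.04 at 10⁵ tracts across
  θ ∈ {0, 0.2, 0.44, 0.8}).
- Fits should be read with their sample sizes: at a few hundred parsed
  tracts per direction, θ̂ carries a standard deviation of roughly 0.15–0.2
  plus a small upward bias from diploid merging of overlapping haplotype
  tracts, so only orderings and large contrasts are interpretable at desk
  scale.

## Circularised bootstraps

Windows overlap and their metrics are autocorrelated, so barrier-window
enrichment is tested by resampling that preserves the clustering of barrier
labels: per replicate the labels are rotated around each circularised
chromosome by independent uniform offsets (`chrom-circular`, the most
conservative and the default), or around the concatenated genome by one
offset (`genome-circular`); matched-count draws without replacement
(`chrom-random`, `genome-random`) are included for comparison.  The
statistic is the mean metric over labelled windows (missing values
skipped); p-values are one-sided with the add-one permutation estimator
(1 + #extreme)/(1 + reps), so never 0.  Directions follow the biology:
`greater` for D̄ and high-DI density, `less` for junctions.  Under an
exchangeable null the chrom-circular p-values are uniform (KS-tested over
200 seeded runs).

Robustness harnesses: leave-one-sample-out reruns of the chrom-circular
test with a Bonferroni threshold 0.05/k (0.05/6 ≈ 0.008 for the canonical
six-sample cohort), and marker downsampling toward positional uniformity —
keep the single site nearest each multiple of a spacing (distance ties to
the smaller position, each site kept at most once), with the spacing chosen
as the smallest at which every chromosome passes a Cramér–von Mises
uniformity test.  Because downsampling cannot remove marker deserts, the
five largest inter-site gaps are excised before testing; excision caps each
at the largest remaining gap, which removes exactly the excess desert and
leaves equal-gap data untouched.

## Demographic arithmetic

The long-term parameters (effective sizes, split time, effective migration
rate mₑ) come from an upstream isolation-with-migration fit and are treated
as given inputs.  The migrants-per-generation identity M/2 = 2·Nₑ·mₑ uses
the **donor** population's Nₑ — the only choice consistent with reading mₑ
as the rate at which lineages trace into the donor (the recipient-Nₑ
alternative is exposed for comparison).

## The synthetic-data generator

Defaults emulate a desk-scale version of a real hybrid-zone study: 6
hybrid-zone diploids (alternating A- and B-majority backgrounds, as a
centered zone sees both sides) plus 6 + 6 parental and 2 nuisance samples
over five 15-Mb autosomes; ~0.2 markers/kb, doubled inside barrier windows;
DI a two-component Gaussian mixture (strongly diagnostic class at −8 ± 4
with weight 0.6, elevated to 0.85 in barriers; weakly diagnostic at
−30 ± 5); 500-kb windows at 20% overlap with a quarter labelled barrier;
1% missingness and 2% nuisance-private sites.  Ancestry paths are a
two-state Markov renewal process along each haplotype with stationary
minority occupancy 0.15 (suppressed five-fold inside barrier windows) and
junction intensity 40 per Morgan at the base occupancy, calibrated so that
suppressing occupancy also depletes junctions — giving minority tracts of
~450 kb mean length, i.e. a mosaic resolvable at the default marker
density.  A secondary-contact mode instead places tracts with
model-drawn lengths uniformly, and a pedigree mode simulates explicit
backcrosses (one obligate crossover per transmitted gamete in the
recombining sex, achiasmy as a sex-averaged halving).  All draws come from
one seeded generator; a fixed config is byte-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: coalescent noise and incomplete lineage
sorting, linked selection, spatial structure within the zone, polarisation
error (states are emitted error-free apart from missingness), real
recombination-rate variation along chromosomes, and gene conversion.  The
nuisance-private sites are overlaid on the two-ancestry structure (they
model mispolarisation due to a second barrier), so they are flagged in the
ground truth and excluded from haplotype-consistency checks.

## Problem sizes

Test and acceptance runs use the desk-scale defaults above (≈20k markers,
185 windows), 10⁵-tract simulations for gradient/θ recovery, 1000-replicate
bootstraps (200 replicates in repeated harnesses), and 200-seed uniformity
checks — sizes chosen so the full suite exercises every claim at
comfortable statistical power while remaining quick to re-run.

## Known limitations

- Diploid parsimony parsing merges overlapping haplotype tracts; tract
  counts are lower bounds and θ̂ from parsed (rather than haplotype-true)
  tracts is slightly inflated at high occupancy.
- The selection model is linear in tract map length; strong selection
  (S·x → 1) would need a different viability form.
- T estimates are lower bounds by construction.
- The tract model ignores hybrid-hybrid matings, gene conversion and space;
  the short-tract regime (x ≤ 0.04) is excluded from fits rather than
  modelled.
- DI is input, not computed; polarisation itself is out of scope.
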