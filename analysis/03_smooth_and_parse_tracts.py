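#!/usr/bin/env python
"""Kernel smoothing and tract parsing.

Low-pass filters the diploid states along each chromosome with a truncated
Laplace kernel (scale 1e-4 x chromosome length, 95% truncation) to remove
isolated state errors, then parses each hybrid-zone sample's chromosomes
into minority-ancestry haplotype tracts and writes their relative lengths x
for the model fit, split by the direction of introgression.
"""

import warnings
from pathlib import Path

from hzkit.cohort import (
    censor_nuisance_sites,
    drop_uninformative,
    filter_by_di,
    read_chromosome_lengths,
    read_cohort,
    write_cohort,
)
from hzkit.smoothing import SmoothingSpec, smooth_states
from hzkit.tracts import parse_minority_tracts, write_tracts_bed

IN = Path("results/cohort")
OUT = Path("results/tracts")
GROUPS = {**{f"A{i}": "speciesA" for i in range(1, 7)},
          **{f"B{i}": "speciesB" for i in range(1, 7)},
          **{f"N{i}": "nuisance" for i in range(1, 3)}}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = read_cohort(
        IN / "cohort.tsv",
        chromosomes=read_chromosome_lengths(IN / "chromosomes.tsv"),
        sample_groups=GROUPS,
    )
    clean = filter_by_di(drop_uninformative(censor_nuisance_sites(cohort)), -20.0)

    spec = SmoothingSpec(scale_fraction=1e-4, truncation=0.95)
    smoothed = smooth_states(clean, spec)
    changed = (smoothed.states != clean.states).mean()
    write_cohort(smoothed, OUT / "cohort_smoothed.tsv")
    print(f"smoothing changed {changed:.2%} of genotype calls")

    hz = [s for s in cohort.sample_ids if s.startswith("HZ")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tracts = parse_minority_tracts(smoothed, samples=hz)
    write_tracts_bed(tracts, OUT / "tracts.bed")
    tracts[["sample", "chromosome", "ancestry", "composition", "x"]].to_csv(
        OUT / "tract_lengths.tsv", sep="\t", index=False
    )
    print(f"parsed {len(tracts)} minority tracts from {len(hz)} HZ samples")
    for anc, grp in tracts.groupby("ancestry"):
        print(f"  ancestry {anc}: n={len(grp)}, median x={grp['x'].median():.4f}, "
              f"long (x>0.04): {(grp['x'] > 0.04).sum()}")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
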