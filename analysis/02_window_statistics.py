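#!/usr/bin/env python
"""Site filters and recent-hybridisation statistics.

Censors nuisance-private sites (the second, geographic barrier), drops
singletons, restricts to strongly diagnostic markers (DI > -20), then
computes per-sample and per-chromosome hybrid index (HI) and interspecific
heterozygosity (H) — the ternary-plot coordinates — and per-window D-bar,
unique ancestry junction counts, and high-DI site density.
"""

from pathlib import Path

import numpy as np

from hzkit.cohort import (
    censor_nuisance_sites,
    drop_uninformative,
    filter_by_di,
    read_chromosome_lengths,
    read_cohort,
)
from hzkit.stats import ternary_table, window_metrics
from hzkit.windows import read_windows

IN = Path("results/cohort")
OUT = Path("results/stats")
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
    windows = read_windows(IN / "windows.bed")

    censored = censor_nuisance_sites(cohort)
    print(f"censored {cohort.n_sites - censored.n_sites} nuisance-private sites")
    informative = drop_uninformative(censored)
    print(f"dropped {censored.n_sites - informative.n_sites} singleton sites")
    high_di = filter_by_di(informative, -20.0)
    print(f"{high_di.n_sites} strongly diagnostic sites (DI > -20) retained")

    tt = ternary_table(high_di, scope="sample")
    tt.to_csv(OUT / "ternary_sample.tsv", sep="\t", index=False)
    ternary_table(high_di, scope="chromosome").to_csv(
        OUT / "ternary_chromosome.tsv", sep="\t", index=False
    )
    hz = tt[tt["sample"].str.startswith("HZ")]
    print("\nhybrid-zone samples (HI / H / HWE deficit):")
    for _, r in hz.iterrows():
        print(f"  {r['sample']}: HI={r['hi']:.3f}  H={r['h']:.3f}  "
              f"deficit={r['hwe_deficit']:+.3f}")

    wm = window_metrics(censored, windows, di_threshold=-20.0)
    wm.to_csv(OUT / "window_metrics.tsv", sep="\t", index=False)
    b = windows.barrier
    print("\nwindow means (barrier vs migrating):")
    for col in ("dbar", "junctions_per_bp", "high_di_per_bp"):
        print(f"  {col}: {np.nanmean(wm[col][b]):.3g} vs "
              f"{np.nanmean(wm[col][~b]):.3g}")
    print(f"\ntables written to {OUT}/")


if __name__ == "__main__":
    main()
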