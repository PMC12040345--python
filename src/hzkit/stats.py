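"""Per-sample, per-chromosome and per-window statistics of recent hybridisation.

The hybrid index (HI) of an individual is the mean polarised allele dosage / 2
over non-missing sites: 0 and 1 are the two pure species.  Interspecific
heterozygosity (H) is the fraction of sites heterozygous by source; an F1 has
H = 1.  D-bar is the window-level multi-site mean pairwise linkage
disequilibrium among polarised markers, numerically the population variance of
per-sample window HI, with range [0, 0.25]: 0 when all samples look alike,
0.25 when each sample is pure and the two species are equally represented.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import MISSING, PolarisedCohort
from .windows import WindowSet, sites_in_window

__all__ = [
    "hybrid_index",
    "interspecific_heterozygosity",
    "hwe_expected_h",
    "hwe_deficit",
    "dbar",
    "count_junctions",
    "high_di_density",
    "window_metrics",
    "ternary_table",
]


def _per_sample_mean(values: np.ndarray, states: np.ndarray) -> np.ndarray:
    """Mean of ``values`` over non-missing entries per sample; NaN if none."""
    present = states != MISSING
    n = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(present, values, 0.0).sum(axis=1) / n
    return np.where(n > 0, out, np.nan)


def _scoped(cohort: PolarisedCohort, scope: str, windows: WindowSet | None):
    """Yield (label dict, site index array) per scope unit."""
    if scope == "sample":
        yield {}, np.arange(cohort.n_sites)
    elif scope == "chromosome":
        for c, _ in cohort.chromosomes:
            yield {"chromosome": c}, np.nonzero(cohort.chrom == c)[0]
    elif scope == "window":
        if windows is None:
            raise ValueError("window scope requires a WindowSet")
        for i in range(len(windows)):
            idx = sites_in_window(
                cohort.chrom, cohort.pos, windows.chrom[i],
                windows.start[i], windows.end[i],
            )
            yield {"window": windows.table["name"].iloc[i]}, idx
    else:
        raise ValueError(f"unknown scope {scope!r}")


def _scoped_stat(cohort, scope, windows, site_values_fn) -> pd.DataFrame:
    rows = []
    for labels, idx in _scoped(cohort, scope, windows):
        st = cohort.states[:, idx]
        vals = _per_sample_mean(site_values_fn(st), st)
        for s, v in zip(cohort.sample_ids, vals):
            rows.append({**labels, "sample": s, "value": v})
    return pd.DataFrame(rows)


def hybrid_index(
    cohort: PolarisedCohort,
    scope: str = "sample",
    windows: WindowSet | None = None,
) -> pd.DataFrame:
    """Per-sample HI at the requested scope (sample, chromosome or window).

    A scope unit with no non-missing site for a sample yields NaN, never 0.
    Apply :func:`hzkit.cohort.filter_by_di` beforehand to restrict to the
    high-DI marker set.
    """
    df = _scoped_stat(cohort, scope, windows, lambda st: st / 2.0)
    return df.rename(columns={"value": "hi"})


def interspecific_heterozygosity(
    cohort: PolarisedCohort,
    scope: str = "sample",
    windows: WindowSet | None = None,
) -> pd.DataFrame:
    """Fraction of non-missing genotypes heterozygous by source, per scope."""
    df = _scoped_stat(cohort, scope, windows, lambda st: (st == 1).astype(float))
    return df.rename(columns={"value": "h"})


def hwe_expected_h(hi):
    """Expected interspecific heterozygosity 2*HI*(1-HI) under Hardy-Weinberg."""
    hi = np.asarray(hi, dtype=float)
    if np.any((hi < 0) | (hi > 1)):
        raise ValueError("hybrid index must lie in [0, 1]")
    out = 2.0 * hi * (1.0 - hi)
    return float(out) if out.ndim == 0 else out


def hwe_deficit(h, hi):
    """Signed deviation H - 2*HI*(1-HI); negative marks a heterozygosity deficit."""
    return np.asarray(h, dtype=float) - hwe_expected_h(hi)


def ternary_table(cohort: PolarisedCohort, scope: str = "sample") -> pd.DataFrame:
    """HI-H table (ternary-plot-ready) with the HWE expectation and deficit."""
    hi = hybrid_index(cohort, scope)
    h = interspecific_heterozygosity(cohort, scope)
    keys = [c for c in hi.columns if c != "hi"]
    out = hi.merge(h, on=keys)
    ok = out["hi"].notna()
    out["h_hwe"] = np.nan
    out.loc[ok, "h_hwe"] = hwe_expected_h(out.loc[ok, "hi"])
    out["hwe_deficit"] = out["h"] - out["h_hwe"]
    return out


def dbar(cohort: PolarisedCohort, window: tuple[str, int, int]) -> float:
    """Multi-site mean pairwise LD of a window: the variance of per-sample HI.

    Computed as the population (divide-by-n) variance across samples of the
    per-sample window HI, which for complete data equals the mean over all
    ordered site pairs (self-pairs included) of the across-sample covariance
    of dosage/2.  Samples with no non-missing site in the window are excluded;
    fewer than two contributing samples yields NaN.
    """
    w_chrom, w_start, w_end = window
    idx = sites_in_window(cohort.chrom, cohort.pos, w_chrom, w_start, w_end)
    if idx.size == 0:
        return float("nan")
    st = cohort.states[:, idx]
    hi = _per_sample_mean(st / 2.0, st)
    hi = hi[~np.isnan(hi)]
    if hi.size < 2:
        return float("nan")
    return float(np.var(hi))


def count_junctions(
    cohort: PolarisedCohort,
    window: tuple[str, int, int],
    per_sample: bool = False,
):
    """Ancestry junctions in a window.

    A junction is an adjacent-marker pair (both genotypes non-missing) whose
    diploid states differ for a sample; the change is located in the
    inter-marker gap.  A junction belongs to the window containing its left
    marker, which keeps assignment deterministic for overlapping windows.
    With ``per_sample`` off, junction gaps are deduplicated across samples
    ("unique" junctions); with it on, a per-sample Series of counts is
    returned.
    """
    w_chrom, w_start, w_end = window
    on_chrom = np.nonzero(cohort.chrom == w_chrom)[0]
    if on_chrom.size < 2:
        return (
            pd.Series(0, index=cohort.sample_ids) if per_sample else 0
        )
    st = cohort.states[:, on_chrom]
    pos = cohort.pos[on_chrom]
    left_in = (pos[:-1] - 1 >= w_start) & (pos[:-1] - 1 < w_end)
    a, b = st[:, :-1], st[:, 1:]
    diff = (a != b) & (a != MISSING) & (b != MISSING)
    diff = diff[:, left_in]
    if per_sample:
        return pd.Series(diff.sum(axis=1), index=cohort.sample_ids)
    return int(diff.any(axis=0).sum())


def high_di_density(
    cohort: PolarisedCohort,
    window: tuple[str, int, int],
    threshold: float = -20.0,
) -> tuple[int, float]:
    """Count and per-bp density of strongly diagnostic sites (DI > threshold)."""
    w_chrom, w_start, w_end = window
    idx = sites_in_window(cohort.chrom, cohort.pos, w_chrom, w_start, w_end)
    count = int((cohort.di[idx] > threshold).sum())
    return count, count / (w_end - w_start)


def window_metrics(
    cohort: PolarisedCohort,
    windows: WindowSet,
    di_threshold: float | None = -20.0,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-window D-bar, junction counts, high-DI density and mean HI.

    D-bar, junctions and mean HI are computed on the high-DI marker subset
    (sites with DI > ``di_threshold``; pass None to use all sites) restricted
    to ``samples`` (default: the HZ group if present, else all samples).
    The high-DI site count always uses the full marker table.  Count metrics
    are also reported per bp of window span.
    """
    from .cohort import filter_by_di

    if samples is None:
        hz = cohort.samples_in_group("HZ")
        samples = hz if hz else list(cohort.sample_ids)
    drop = [s for s in cohort.sample_ids if s not in set(samples)]
    sub = cohort.drop_samples(drop) if drop else cohort
    hi_di = filter_by_di(sub, di_threshold) if di_threshold is not None else sub

    rows = []
    for i in range(len(windows)):
        w = (windows.chrom[i], int(windows.start[i]), int(windows.end[i]))
        span = w[2] - w[1]
        idx = sites_in_window(hi_di.chrom, hi_di.pos, *w)
        st = hi_di.states[:, idx]
        hi = _per_sample_mean(st / 2.0, st) if idx.size else np.full(len(samples), np.nan)
        n_used = int((~np.isnan(hi)).sum())
        junc = count_junctions(hi_di, w)
        n_hi_di, hi_di_per_bp = high_di_density(
            cohort, w, -np.inf if di_threshold is None else di_threshold
        )
        rows.append(
            {
                "name": windows.table["name"].iloc[i],
                "dbar": dbar(hi_di, w),
                "junctions": junc,
                "junctions_per_bp": junc / span,
                "high_di_sites": n_hi_di,
                "high_di_per_bp": hi_di_per_bp,
                "mean_hi": float(np.nanmean(hi)) if n_used else np.nan,
                "n_samples": n_used,
            }
        )
    return pd.DataFrame(rows)
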