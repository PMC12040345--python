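"""Circularised bootstraps for window-metric enrichment, marker-density
robustness tools, and the leave-one-sample-out harness.

Genomic windows overlap and their metrics are autocorrelated, so tests that
assume independence are wildly overconfident.  The circular bootstrap keeps
the clustering of barrier labels intact while breaking the label-metric
association: labels are rotated around a circularised chromosome (or the
circularised genome) by a random offset per replicate.  Plain random schemes
(matched counts drawn without replacement) are included for comparison; they
ignore clustering and are anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

SCHEMES = ("chrom-circular", "chrom-random", "genome-circular", "genome-random")


@dataclass
class BootstrapResult:
    """Observed statistic, its null distribution and a one-sided p-value.

    ``p_value`` uses the add-one permutation estimator
    ``(1 + #{null at least as extreme}) / (1 + reps)`` so it is never 0.
    """

    observed: float
    null_values: np.ndarray
    scheme: str
    seed: int | None
    alternative: str
    reps: int

    @property
    def p_value(self) -> float:
        null = np.asarray(self.null_values)
        if self.alternative == "greater":
            extreme = int((null >= self.observed).sum())
        elif self.alternative == "less":
            extreme = int((null <= self.observed).sum())
        else:
            raise ValueError(f"unknown alternative {self.alternative!r}")
        return (1 + extreme) / (1 + self.reps)


def _rotation_stats(metric: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked-mean numerator/denominator for every rotation offset.

    For offset o the statistic uses windows at positions (i + o) mod n for
    each masked position i.  Missing metrics (NaN) are skipped.
    """
    n = metric.size
    vals = np.where(np.isnan(metric), 0.0, metric)
    cnts = (~np.isnan(metric)).astype(float)
    pos = np.nonzero(mask)[0]
    sums = np.zeros(n)
    counts = np.zeros(n)
    for o in range(n):
        idx = (pos + o) % n
        sums[o] = vals[idx].sum()
        counts[o] = cnts[idx].sum()
    return sums, counts


def circular_bootstrap(
    metric: np.ndarray,
    mask: np.ndarray,
    chrom: np.ndarray,
    scheme: str = "chrom-circular",
    reps: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Test whether the mean metric over masked windows is extreme.

    Parameters
    ----------
    metric, mask, chrom:
        Aligned per-window arrays: the metric value (NaN = missing), the
        barrier flag being tested, and the chromosome id of each window
        (windows in genome order).
    scheme:
        ``chrom-circular`` rotates each chromosome's mask by an independent
        uniform offset per replicate; ``genome-circular`` rotates the
        concatenated genome-order mask by a single offset; the ``-random``
        variants draw matched per-chromosome / total window counts without
        replacement.
    alternative:
        ``greater`` (e.g. D-bar, high-DI density in barrier windows) or
        ``less`` (junction counts).
    """
    metric = np.asarray(metric, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    chrom = np.asarray(chrom)
    if not (metric.size == mask.size == chrom.size):
        raise ValueError("metric, mask and chrom must be aligned")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if mask.all() or not mask.any():
        raise ValueError("mask is all-true or all-false: degenerate null")
    if rng is None:
        rng = np.random.default_rng(seed)

    with np.errstate(invalid="ignore"):
        observed = float(np.nanmean(metric[mask]))

    chrom_ids = list(dict.fromkeys(chrom))
    groups = [np.nonzero(chrom == c)[0] for c in chrom_ids]

    if scheme in ("chrom-circular", "genome-circular"):
        null_sum = np.zeros(reps)
        null_cnt = np.zeros(reps)
        if scheme == "genome-circular":
            sums, counts = _rotation_stats(metric, mask)
            offs = rng.integers(0, metric.size, size=reps)
            null_sum, null_cnt = sums[offs], counts[offs]
        else:
            for g in groups:
                if not mask[g].any():
                    continue
                sums, counts = _rotation_stats(metric[g], mask[g])
                offs = rng.integers(0, g.size, size=reps)
                null_sum += sums[offs]
                null_cnt += counts[offs]
        with np.errstate(invalid="ignore"):
            null = null_sum / null_cnt
    else:
        vals = np.where(np.isnan(metric), 0.0, metric)
        cnts = (~np.isnan(metric)).astype(float)
        null_sum = np.zeros(reps)
        null_cnt = np.zeros(reps)
        if scheme == "genome-random":
            k = int(mask.sum())
            for r in range(reps):
                idx = rng.choice(metric.size, size=k, replace=False)
                null_sum[r] = vals[idx].sum()
                null_cnt[r] = cnts[idx].sum()
        else:  # chrom-random
            for g in groups:
                k = int(mask[g].sum())
                if k == 0:
                    continue
                for r in range(reps):
                    idx = g[rng.choice(g.size, size=k, replace=False)]
                    null_sum[r] += vals[idx].sum()
                    null_cnt[r] += cnts[idx].sum()
        with np.errstate(invalid="ignore"):
            null = null_sum / null_cnt

    return BootstrapResult(
        observed=observed,
        null_values=null,
        scheme=scheme,
        seed=seed,
        alternative=alternative,
        reps=reps,
    )


def leave_one_out(
    cohort,
    windows,
    mask: np.ndarray,
    metric: str = "dbar",
    reps: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
    di_threshold: float = -20.0,
) -> pd.DataFrame:
    """Rerun the chrom-circular bootstrap excluding each HZ sample in turn.

    Window metrics are recomputed without the excluded sample each time.
    Returns a table of per-excluded-sample p-values with the Bonferroni
    threshold 0.05/k for k exclusions attached (0.05/6 ~ 0.008 for the
    canonical six-sample hybrid-zone cohort).
    """
    from .stats import window_metrics

    hz = cohort.samples_in_group("HZ")
    if len(hz) < 3:
        raise ValueError("leave-one-out needs at least 3 HZ samples")
    rows = []
    rng = np.random.default_rng(seed)
    for excluded in hz:
        keep = [s for s in hz if s != excluded]
        wm = window_metrics(cohort, windows, di_threshold=di_threshold, samples=keep)
        res = circular_bootstrap(
            wm[metric].to_numpy(),
            mask,
            windows.chrom,
            scheme="chrom-circular",
            reps=reps,
            rng=rng,
            alternative=alternative,
        )
        rows.append({"excluded": excluded, "observed": res.observed,
                     "p_value": res.p_value})
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = bonferroni_threshold(len(hz))
    return out


def bonferroni_threshold(k: int, alpha: float = 0.05) -> float:
    """Adjusted significance threshold alpha / k for k leave-one-out tests."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


def downsample_uniform(positions: np.ndarray, spacing: int = 1100) -> np.ndarray:
    """Indices of sites closest to multiples of ``spacing`` (over-dispersed
    downsampling on the physical metric).

    For each multiple k*spacing (k = 1 .. floor(max_pos / spacing)) the
    single site with minimal |pos - k*spacing| is kept; distance ties break
    toward the smaller position, and a site is kept for at most one
    multiple.  The default spacing of 1100 nt is the smallest at which all
    chromosomes of the motivating dataset pass the uniformity test after
    downsampling.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        return np.empty(0, dtype=np.int64)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    kept: set[int] = set()
    for k in range(1, int(pos.max() // spacing) + 1):
        target = k * spacing
        i = int(np.argmin(np.abs(pos - target)))  # first minimum = smaller pos
        kept.add(i)
    return np.array(sorted(kept), dtype=np.int64)


def uniformity_test(positions: np.ndarray, excise_largest_gaps: int = 5):
    """Cramer-von Mises test of positional uniformity after gap excision.

    Downsampling cannot remove marker deserts, so the ``excise_largest_gaps``
    largest inter-site gaps are excised before testing: coordinates across
    each of them are collapsed so the gap shrinks to the largest remaining
    gap (the excess is what gets excised; data whose gaps are all equal are
    left untouched).  The collapsed coordinates are rescaled to [0, 1] and
    the one-sample Cramer-von Mises test against the uniform distribution is
    applied.  Returns the scipy result object (``.pvalue``, ``.statistic``).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size < 10:
        raise ValueError("need at least 10 positions for a uniformity test")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    x = pos.copy()
    if excise_largest_gaps > 0:
        gaps = np.diff(x)
        order = np.argsort(gaps)
        g = min(excise_largest_gaps, gaps.size - 1)
        worst = order[-g:] if g > 0 else []
        cap = gaps[order[-g - 1]] if g > 0 else np.inf
        shift = np.zeros_like(x)
        for i in worst:
            shift[i + 1 :] += gaps[i] - cap
        x = x - shift
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("degenerate positions after gap excision")
    u = (x - lo) / (hi - lo)
    return sps.cramervonmises(u, "uniform")
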