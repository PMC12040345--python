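"""Parsimony parsing of diploid polarised genotypes into haplotype tracts.

On a chromosome whose majority background is homozygous for one species, an
interval of heterozygous sites indicates a single minority-ancestry tract on
one haplotype; the alternative (two tracts, one per haplotype, abutting
perfectly without overlap) is so rare it is treated as negligible.  Runs of
minority-homozygous sites, or of mixed heterozygous and minority-homozygous
sites, are likewise counted as ONE tract on one haplotype spanning the run.
This deliberately censors smaller blocks positionally inside a larger counted
block of the same individual, so overlapping-haplotype configurations are
undercounted by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MISSING, PolarisedCohort

#: per-chromosome map length in Morgans (one crossover per male meiosis,
#: achiasmatic females, sex-averaged)
DEFAULT_MAP_LENGTH = 0.25


@dataclass(frozen=True)
class AncestryTract:
    """One minority-ancestry haplotype block.

    ``start``/``end`` are 0-based half-open bp coordinates; ``ancestry`` is
    the minority species ('A' or 'B'); ``x`` is span / chromosome length;
    ``composition`` is het-only, hom-only or mixed.
    """

    sample: str
    chromosome: str
    start: int
    end: int
    ancestry: str
    composition: str
    x: float


def tract_relative_length(span_bp: float, chromosome_length: float) -> float:
    """Relative tract length x = physical span / chromosome length."""
    return span_bp / chromosome_length


def map_length_morgans(x: float, map_length: float = DEFAULT_MAP_LENGTH) -> float:
    """Map length of a tract of relative length x, in Morgans."""
    return map_length * x


def parse_sample_chromosome(
    states: np.ndarray,
    positions: np.ndarray,
    chromosome_length: int,
    boundary: str = "midpoint",
) -> list[tuple[int, int, str, str]]:
    """Parse one sample-chromosome state vector into minority tracts.

    The majority homozygous state (0 or 2, whichever covers more non-missing
    markers) defines the background; each maximal run of non-background
    states yields exactly one tract ``(start, end, ancestry, composition)``.
    Missing states inside a run do not break it and missing states at run
    edges are excluded from the span.  Tract boundaries sit at the midpoints
    of the flanking inter-marker gaps (``boundary="midpoint"``; chromosome
    ends when unflanked) so lengths are not biased downward by marker
    sparsity, or at the outer markers themselves (``boundary="markers"``).

    Returns an empty list (with a warning) when no homozygous majority is
    determinable (all-heterozygous chromosome, or an exact 0/2 tie).
    """
    states = np.asarray(states)
    positions = np.asarray(positions)
    present = states != MISSING
    n0 = int((states == 0).sum())
    n2 = int((states == 2).sum())
    if n0 == n2:
        warnings.warn(
            "no homozygous majority determinable; chromosome skipped", stacklevel=2
        )
        return []
    background = 0 if n0 > n2 else 2
    minority_hom = 2 - background
    ancestry = "B" if minority_hom == 2 else "A"

    # 0-based marker coordinates
    coord = positions - 1
    tracts: list[tuple[int, int, str, str]] = []
    run: list[int] = []  # indices of non-background, non-missing markers

    def flush(run_idx: list[int]) -> None:
        if not run_idx:
            return
        first, last = run_idx[0], run_idx[-1]
        run_states = states[run_idx]
        if np.all(run_states == 1):
            comp = "het-only"
        elif np.all(run_states == minority_hom):
            comp = "hom-only"
        else:
            comp = "mixed"
        if boundary == "midpoint":
            # nearest flanking background markers (non-missing)
            left_bg = [i for i in range(first - 1, -1, -1) if present[i] and states[i] == background]
            right_bg = [i for i in range(last + 1, len(states)) if present[i] and states[i] == background]
            start = (coord[left_bg[0]] + coord[first] + 1) // 2 if left_bg else 0
            end = (
                (coord[last] + coord[right_bg[0]] + 1) // 2
                if right_bg
                else chromosome_length
            )
        elif boundary == "markers":
            start, end = int(coord[first]), int(coord[last]) + 1
        else:
            raise ValueError(f"unknown boundary mode {boundary!r}")
        tracts.append((int(start), int(max(end, start + 1)), ancestry, comp))

    for i in range(len(states)):
        if not present[i]:
            continue  # missing never breaks nor extends a run
        if states[i] == background:
            flush(run)
            run = []
        else:
            run.append(i)
    flush(run)
    return tracts


def parse_minority_tracts(
    cohort: PolarisedCohort,
    samples: list[str] | None = None,
    boundary: str = "midpoint",
) -> pd.DataFrame:
    """Parse minority tracts for each sample and chromosome of a cohort.

    Returns a DataFrame with columns sample, chromosome, start, end,
    ancestry, composition, x (relative length).  States should be smoothed
    first (see :mod:`hzkit.smoothing`) so isolated errors do not fragment
    tracts.
    """
    samples = samples if samples is not None else list(cohort.sample_ids)
    rows = []
    for chrom_id, chrom_len in cohort.chromosomes:
        idx = np.nonzero(cohort.chrom == chrom_id)[0]
        if idx.size == 0:
            continue
        pos = cohort.pos[idx]
        for s in samples:
            st = cohort.states[cohort.sample_index(s), idx]
            for start, end, anc, comp in parse_sample_chromosome(
                st, pos, chrom_len, boundary=boundary
            ):
                rows.append(
                    {
                        "sample": s,
                        "chromosome": chrom_id,
                        "start": start,
                        "end": end,
                        "ancestry": anc,
                        "composition": comp,
                        "x": tract_relative_length(end - start, chrom_len),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["sample", "chromosome", "start", "end", "ancestry", "composition", "x"],
    )


def write_tracts_bed(tracts: pd.DataFrame, path) -> None:
    """BED6-like tract output; name = sample:ancestry:composition."""
    out = tracts.copy()
    out["name"] = out["sample"] + ":" + out["ancestry"] + ":" + out["composition"]
    out["score"] = 0
    out["strand"] = "."
    out[["chromosome", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_tracts_bed(path, chromosomes: list[tuple[str, int]]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chromosome", "start", "end", "name", "score", "strand"],
    )
    parts = df["name"].str.split(":", expand=True)
    df["sample"], df["ancestry"], df["composition"] = parts[0], parts[1], parts[2]
    lengths = dict(chromosomes)
    df["x"] = (df["end"] - df["start"]) / df["chromosome"].map(lengths)
    return df[["sample", "chromosome", "start", "end", "ancestry", "composition", "x"]]
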