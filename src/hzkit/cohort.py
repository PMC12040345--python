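"""Polarised diploid cohorts: container, TSV I/O, and site-level filters.

A *polarised* genotype labels alleles by species of origin rather than by
reference/alternate: at every site each diploid sample is homozygous for
species A (0), heterozygous by source (1), homozygous for species B (2), or
missing.  Each site carries a diagnostic index (DI) measuring how diagnostic
the marker is for the species barrier (larger = more diagnostic); DI is an
opaque input here, produced upstream by the polarisation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: integer code for a missing genotype in the states matrix
MISSING: int = -1

#: symbol used for missing genotypes in the cohort table dialect
MISSING_SYMBOL: str = "."

VALID_GROUPS = ("speciesA", "speciesB", "HZ", "nuisance")


class CohortFormatError(ValueError):
    """Raised when a cohort table violates the dialect or its invariants."""


@dataclass
class PolarisedCohort:
    """Samples x polarised markers with diploid source-states.

    Attributes
    ----------
    sample_ids:
        Sample identifiers, one per row of ``states``.
    sample_groups:
        Group label per sample: ``speciesA``, ``speciesB``, ``HZ`` or
        ``nuisance``.
    chromosomes:
        ``(id, length_bp)`` pairs for every chromosome markers may sit on.
    chrom, pos, di:
        Per-marker chromosome id, 1-based position and diagnostic index.
    states:
        ``(n_samples, n_sites)`` int8 matrix over {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    sample_groups: list[str]
    chromosomes: list[tuple[str, int]]
    chrom: np.ndarray
    pos: np.ndarray
    di: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.di = np.asarray(self.di, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.int8)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        n_samples, n_sites = self.states.shape
        if len(self.sample_ids) != n_samples:
            raise CohortFormatError("sample_ids/states shape mismatch")
        if len(self.sample_groups) != n_samples:
            raise CohortFormatError("sample_groups/states shape mismatch")
        for g in self.sample_groups:
            if g not in VALID_GROUPS:
                raise CohortFormatError(f"unknown sample group {g!r}")
        if not (len(self.chrom) == len(self.pos) == len(self.di) == n_sites):
            raise CohortFormatError("marker column lengths disagree")
        known = {c for c, _ in self.chromosomes}
        bad = set(self.chrom) - known
        if bad:
            raise CohortFormatError(f"markers on unknown chromosome(s): {sorted(bad)}")
        ok = np.isin(self.states, (0, 1, 2, MISSING))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise CohortFormatError(
                f"invalid state {self.states[i, j]} for sample "
                f"{self.sample_ids[i]} at {self.chrom[j]}:{self.pos[j]}"
            )
        # positions strictly increasing within each chromosome (row order)
        for c in dict.fromkeys(self.chrom):  # preserves order
            p = self.pos[self.chrom == c]
            bad_idx = np.nonzero(np.diff(p) <= 0)[0]
            if bad_idx.size:
                raise CohortFormatError(
                    f"positions not strictly increasing on {c} at "
                    f"{c}:{p[bad_idx[0] + 1]}"
                )

    # -- basic queries ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def chromosome_length(self, chrom_id: str) -> int:
        for c, ln in self.chromosomes:
            if c == chrom_id:
                return ln
        raise KeyError(chrom_id)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s, g in zip(self.sample_ids, self.sample_groups) if g == group]

    # -- subsetting ------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "PolarisedCohort":
        """New cohort restricted to the given site indices (order preserved)."""
        index = np.asarray(index)
        return PolarisedCohort(
            sample_ids=list(self.sample_ids),
            sample_groups=list(self.sample_groups),
            chromosomes=list(self.chromosomes),
            chrom=self.chrom[index],
            pos=self.pos[index],
            di=self.di[index],
            states=self.states[:, index],
        )

    def drop_samples(self, sample_ids: list[str]) -> "PolarisedCohort":
        drop = set(sample_ids)
        keep = [i for i, s in enumerate(self.sample_ids) if s not in drop]
        return PolarisedCohort(
            sample_ids=[self.sample_ids[i] for i in keep],
            sample_groups=[self.sample_groups[i] for i in keep],
            chromosomes=list(self.chromosomes),
            chrom=self.chrom,
            pos=self.pos,
            di=self.di,
            states=self.states[keep, :],
        )

    def equals(self, other: "PolarisedCohort") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.sample_groups == other.sample_groups
            and self.chromosomes == other.chromosomes
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.di, other.di)
            and np.array_equal(self.states, other.states)
        )


# ---------------------------------------------------------------------------
# I/O: tab-separated cohort dialect
# ---------------------------------------------------------------------------
# header: chrom  pos  DI  <sample1>  <sample2> ...
# one row per marker; states in {0,1,2,.}


def read_cohort(
    path,
    chromosomes: list[tuple[str, int]] | None = None,
    sample_groups: dict[str, str] | None = None,
) -> PolarisedCohort:
    """Read a cohort from the tab-separated dialect.

    Parameters
    ----------
    path:
        TSV with header ``chrom pos DI s1 s2 ...`` and one row per marker.
    chromosomes:
        Optional ``(id, length)`` list.  When omitted, lengths default to the
        last marker position per chromosome (adequate for round-tripping but
        not for relative tract lengths).
    sample_groups:
        Optional ``sample_id -> group`` mapping; unlisted samples are ``HZ``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if cols[:3] != ["chrom", "pos", "DI"]:
        raise CohortFormatError(f"expected header chrom/pos/DI..., got {cols[:3]}")
    sample_ids = cols[3:]
    chrom = df["chrom"].to_numpy(dtype=object)
    pos = df["pos"].astype(np.int64).to_numpy()
    di = df["DI"].astype(np.float64).to_numpy()

    # duplicate positions are rejected with their location
    for c in dict.fromkeys(chrom):
        p = pos[chrom == c]
        dup = np.nonzero(np.diff(p) == 0)[0]
        if dup.size:
            raise CohortFormatError(f"duplicate position {c}:{p[dup[0]]}")

    states = np.empty((len(sample_ids), len(df)), dtype=np.int8)
    mapping = {"0": 0, "1": 1, "2": 2, MISSING_SYMBOL: MISSING}
    for i, s in enumerate(sample_ids):
        col = df[s].to_numpy(dtype=object)
        try:
            states[i] = [mapping[str(v)] for v in col]
        except KeyError as e:
            raise CohortFormatError(f"unknown state symbol {e} in column {s}") from None

    if chromosomes is None:
        chromosomes = [(c, int(pos[chrom == c].max())) for c in dict.fromkeys(chrom)]
    groups = [
        (sample_groups or {}).get(s, "HZ") for s in sample_ids
    ]
    return PolarisedCohort(
        sample_ids=sample_ids,
        sample_groups=groups,
        chromosomes=chromosomes,
        chrom=chrom,
        pos=pos,
        di=di,
        states=states,
    )


def write_cohort(cohort: PolarisedCohort, path) -> None:
    """Write the cohort in the dialect read by :func:`read_cohort`."""
    inv = {0: "0", 1: "1", 2: "2", MISSING: MISSING_SYMBOL}
    data = {
        "chrom": cohort.chrom,
        "pos": cohort.pos,
        "DI": cohort.di,
        **{
            s: [inv[int(v)] for v in cohort.states[i]]
            for i, s in enumerate(cohort.sample_ids)
        },
    }
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_chromosome_lengths(path) -> list[tuple[str, int]]:
    """Two-column TSV (id, length in bp), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return [(str(c), int(l)) for c, l in zip(df["chrom"], df["length"])]


def write_chromosome_lengths(chromosomes: list[tuple[str, int]], path) -> None:
    pd.DataFrame(chromosomes).to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Site-level filters (each a site-wise predicate: idempotent and commuting)
# ---------------------------------------------------------------------------


def filter_by_di(cohort: PolarisedCohort, threshold: float = -20.0) -> PolarisedCohort:
    """Keep exactly the sites with DI strictly greater than ``threshold``."""
    return cohort.take_sites(np.nonzero(cohort.di > threshold)[0])


def _allele_dosage(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site counts of species-B and species-A allele copies (missing excluded)."""
    present = states != MISSING
    b = np.where(present, states, 0).sum(axis=0)
    a = 2 * present.sum(axis=0) - b
    return a, b


def drop_uninformative(cohort: PolarisedCohort) -> PolarisedCohort:
    """Remove singleton sites (pooled minority allele count of exactly 1).

    Singletons carry no information for polarisation by association in state.
    Sites where every genotype is missing are also dropped, with a warning.
    """
    a, b = _allele_dosage(cohort.states)
    minority = np.minimum(a, b)
    all_missing = (cohort.states == MISSING).all(axis=0)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} site(s) with all-missing genotypes",
            stacklevel=2,
        )
    keep = (minority != 1) & ~all_missing
    return cohort.take_sites(np.nonzero(keep)[0])


def censor_nuisance_sites(
    cohort: PolarisedCohort, nuisance_ids: set[str] | list[str] | None = None
) -> PolarisedCohort:
    """Censor sites whose minority homozygous state is private to nuisance samples.

    When a second, nuisance barrier segregates in the data (e.g. a geographic
    split within one species), polarisation can pick up sites where a
    homozygous state occurs only in the nuisance samples.  A site is censored
    when (a) one homozygous state has strictly fewer carriers than the other
    (ties are kept: only unambiguous private-nuisance signal is censored) and
    (b) all carriers of that minority homozygous state are nuisance samples.

    ``nuisance_ids`` defaults to the samples whose group label is
    ``nuisance``.
    """
    if nuisance_ids is None:
        nuisance_ids = cohort.samples_in_group("nuisance")
    nuisance_ids = set(nuisance_ids)
    unknown = nuisance_ids - set(cohort.sample_ids)
    if unknown:
        raise ValueError(f"nuisance ids not in cohort: {sorted(unknown)}")
    if not nuisance_ids:
        return cohort.take_sites(np.arange(cohort.n_sites))

    is_nuis = np.array([s in nuisance_ids for s in cohort.sample_ids])
    hom0 = cohort.states == 0
    hom2 = cohort.states == 2
    n0 = hom0.sum(axis=0)
    n2 = hom2.sum(axis=0)
    # minority homozygous state per site; ties -> not censored
    min_is_0 = (n0 < n2) & (n0 > 0)
    min_is_2 = (n2 < n0) & (n2 > 0)
    private0 = min_is_0 & ~(hom0 & ~is_nuis[:, None]).any(axis=0)
    private2 = min_is_2 & ~(hom2 & ~is_nuis[:, None]).any(axis=0)
    keep = ~(private0 | private2)
    return cohort.take_sites(np.nonzero(keep)[0])
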