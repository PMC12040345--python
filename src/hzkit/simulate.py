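"""Synthetic admixed cohorts with known ground truth.

The generator emulates the data a genome-polarisation pipeline emits for a
narrow hybrid zone between two butterfly-like species: ~20 diploid samples
(a hybrid-zone set plus parental reference sets and a small nuisance group)
over a handful of autosomes, a mosaic of two-ancestry tracts along every
chromosome of the admixed samples, heterogeneous marker density and
diagnostic-index (DI) values, and suppressed minority ancestry inside
designated barrier windows.  Every haplotype tract and junction is recorded
as ground truth so downstream window statistics, smoothing, tract parsing
and bootstraps can be validated without external data.

Two ancestry-path modes are available: ``markov`` draws alternating tracts
from a two-state Markov renewal process whose minority occupancy is
multiplied by a suppression factor inside barrier windows; and
``secondary_contact`` places minority tracts with lengths drawn from the
[M, S, R, T] tract-length model uniformly along chromosomes.  A separate
pedigree mode simulates explicit n-th generation backcrosses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import MISSING, PolarisedCohort
from .tract_model import TractModelParams, simulate_tract_lengths
from .tracts import DEFAULT_MAP_LENGTH
from .windows import WindowSet, make_windows

DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (f"chr{i}", 15_000_000) for i in range(1, 6)
)


@dataclass
class DIMixture:
    """Two-component description of per-site diagnostic indices.

    DI is on a negative log-like scale: less negative = more diagnostic.
    ``weight_high`` is the probability a marker belongs to the strongly
    diagnostic class (elevated to ``weight_high_barrier`` inside barrier
    windows, mirroring the enrichment of diagnostic sites in barriers).
    """

    high_loc: float = -8.0
    high_scale: float = 4.0
    low_loc: float = -30.0
    low_scale: float = 5.0
    weight_high: float = 0.6
    weight_high_barrier: float = 0.85


@dataclass
class SimulationConfig:
    """Study-scale defaults: 6 hybrid-zone + 6 + 6 parental + 2 nuisance
    diploids over five 15-Mb autosomes (a desk-scale stand-in for ~20
    samples over ~30 autosomes), ~0.2 markers/kb doubled inside barrier
    windows, 500-kb windows at 20% overlap, a quarter of windows labelled
    barrier, and minority occupancy suppressed five-fold inside barriers."""

    seed: int = 0
    n_hz: int = 6
    n_species_a: int = 6
    n_species_b: int = 6
    n_nuisance: int = 2
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [list(c) for c in DEFAULT_CHROMOSOMES]
    )
    marker_rate: float = 2e-4
    barrier_marker_multiplier: float = 2.0
    di: DIMixture = field(default_factory=DIMixture)
    window_span: int = 500_000
    window_overlap: float = 0.2
    barrier_fraction: float = 0.25
    barrier_labels: list[bool] | None = None
    mode: str = "markov"
    # markov-mode parameters
    junction_intensity: float = 40.0  # junctions per Morgan per haplotype
    minority_occupancy: float = 0.15
    barrier_suppression: float = 0.2  # occupancy multiplier inside barriers
    map_length: float = DEFAULT_MAP_LENGTH  # Morgans per chromosome
    # secondary-contact-mode parameters (tract cohorts per direction)
    sc_params_into_a: TractModelParams | None = None
    sc_params_into_b: TractModelParams | None = None
    sc_tracts_per_chromosome: float = 3.0
    # pedigree mode
    backcross_n: int | None = None
    # noise
    missing_rate: float = 0.01
    nuisance_private_rate: float = 0.02

    def __post_init__(self) -> None:
        self.chromosomes = [(str(c), int(l)) for c, l in self.chromosomes]
        if self.marker_rate < 0 or self.junction_intensity < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.window_overlap < 1:
            raise ValueError("window overlap must be in [0, 1)")
        if not 0 <= self.minority_occupancy <= 0.5:
            raise ValueError("minority occupancy must be in [0, 0.5]")


@dataclass
class GroundTruth:
    """Everything the generator knows: per-haplotype ancestry segments,
    junction positions, window labels, and nuisance-private marker indices."""

    tracts: pd.DataFrame  # sample, chromosome, haplotype, start, end, ancestry
    junctions: pd.DataFrame  # sample, chromosome, haplotype, position
    windows: WindowSet
    nuisance_private_sites: np.ndarray
    config: SimulationConfig

    def minority_tracts(self, majority: dict[str, str]) -> pd.DataFrame:
        """Tracts whose ancestry differs from each sample's majority."""
        t = self.tracts
        maj = t["sample"].map(majority)
        return t[t["ancestry"] != maj].reset_index(drop=True)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "di" in raw and isinstance(raw["di"], dict):
        raw["di"] = DIMixture(**raw["di"])
    for key in ("sc_params_into_a", "sc_params_into_b"):
        if raw.get(key) is not None:
            raw[key] = TractModelParams(**raw[key])
    return SimulationConfig(**raw)


def write_config(config: SimulationConfig, path) -> None:
    raw = asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------


def _barrier_union(windows: WindowSet, chrom: str) -> list[tuple[int, int]]:
    """Merged barrier intervals on one chromosome."""
    sel = (windows.chrom == chrom) & windows.barrier
    ivs = sorted(zip(windows.start[sel], windows.end[sel]))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([int(s), int(e)])
    return [tuple(iv) for iv in merged]


def _segments(length: int, barrier_ivs: list[tuple[int, int]]):
    """(start, end, in_barrier) partition of [0, length)."""
    edges = [0]
    for s, e in barrier_ivs:
        edges += [s, e]
    edges.append(length)
    edges = sorted(set(min(max(e, 0), length) for e in edges))
    out = []
    for a, b in zip(edges[:-1], edges[1:]):
        inb = any(s <= a and b <= e for s, e in barrier_ivs)
        out.append((a, b, inb))
    return out


def _draw_markers(config, windows, chrom, length, rng):
    """Positions (1-based) and DI values, denser/more diagnostic in barriers."""
    ivs = _barrier_union(windows, chrom)
    pos_parts, hi_flags = [], []
    for a, b, inb in _segments(length, ivs):
        rate = config.marker_rate * (config.barrier_marker_multiplier if inb else 1.0)
        n = rng.poisson(rate * (b - a))
        p = np.unique(rng.integers(a + 1, b + 1, size=n))
        pos_parts.append(p)
        w = config.di.weight_high_barrier if inb else config.di.weight_high
        hi_flags.append(rng.random(p.size) < w)
    pos = np.concatenate(pos_parts)
    hi = np.concatenate(hi_flags)
    order = np.argsort(pos)
    pos, hi = pos[order], hi[order]
    di = np.where(
        hi,
        rng.normal(config.di.high_loc, config.di.high_scale, size=pos.size),
        rng.normal(config.di.low_loc, config.di.low_scale, size=pos.size),
    )
    return pos.astype(np.int64), di


# ---------------------------------------------------------------------------
# ancestry paths
# ---------------------------------------------------------------------------


def _markov_path(config, windows, chrom, length, rng):
    """One haplotype ancestry path: list of (start, end, ancestry) segments,
    ancestry 0 = majority, 1 = minority; plus junction positions."""
    J = config.junction_intensity
    R = config.map_length
    morgan_per_bp = R / length
    ivs = _barrier_union(windows, chrom)
    segs = _segments(length, ivs)

    pi0 = config.minority_occupancy
    if pi0 == 0 or J == 0:
        return [(0.0, float(length), 0)], []
    # two-state Markov rates r01 = c*pi, r10 = c*(1-pi): stationary minority
    # occupancy pi, junction intensity 2*c*pi*(1-pi).  c is calibrated so the
    # configured intensity J holds at the base occupancy; suppressing the
    # occupancy inside barrier windows then also depletes junctions there.
    c = J * morgan_per_bp / (2.0 * pi0 * (1.0 - pi0))

    def rates(inb: bool) -> tuple[float, float]:
        pi = pi0 * (config.barrier_suppression if inb else 1.0)
        return c * pi, c * (1.0 - pi)

    # initial state from the first segment's stationary occupancy
    r01, r10 = rates(segs[0][2])
    state = int(rng.random() < r01 / (r01 + r10))
    path, junctions = [], []
    seg_start = 0.0
    p = 0.0
    for a, b, inb in segs:
        r01, r10 = rates(inb)
        while True:
            rate = r01 if state == 0 else r10
            jump = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if p + jump >= b:
                p = float(b)
                break
            p += jump
            junctions.append(p)
            path.append((seg_start, p, state))
            seg_start = p
            state = 1 - state
    path.append((seg_start, float(length), state))
    return path, junctions


def _sc_path(config, params, length, rng):
    """Secondary-contact haplotype path: minority tracts of model-drawn
    relative lengths placed uniformly; overlaps merge."""
    n = rng.poisson(config.sc_tracts_per_chromosome)
    if n == 0:
        return [(0.0, float(length), 0)], []
    xs = simulate_tract_lengths(params, n_tracts=n, rng=rng)
    spans = np.minimum(xs * length, length)
    starts = rng.random(n) * (length - spans)
    ivs = sorted(zip(starts, starts + spans))
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([float(s), float(e)])
    path, junctions = [], []
    cursor = 0.0
    for s, e in merged:
        if s > cursor:
            path.append((cursor, s, 0))
        if s > 0:
            junctions.append(s)
        path.append((s, e, 1))
        if e < length:
            junctions.append(e)
        cursor = e
    if cursor < length:
        path.append((cursor, float(length), 0))
    return path, junctions


def _ancestry_at(path, positions: np.ndarray) -> np.ndarray:
    """Ancestry (0 majority / 1 minority) of a path at 1-based positions."""
    ends = np.array([e for _, e, _ in path])
    anc = np.array([s for _, _, s in path])
    idx = np.searchsorted(ends, positions - 0.5, side="right")
    idx = np.minimum(idx, len(path) - 1)
    return anc[idx]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


def sample_layout(config: SimulationConfig) -> tuple[list[str], list[str], dict[str, str]]:
    """Sample ids, groups, and each sample's majority ancestry (A/B).

    Hybrid-zone samples alternate between A-majority and B-majority
    backgrounds (a centered zone sees both sides)."""
    ids, groups, majority = [], [], {}
    for i in range(config.n_species_a):
        ids.append(f"A{i + 1}"); groups.append("speciesA"); majority[ids[-1]] = "A"
    for i in range(config.n_species_b):
        ids.append(f"B{i + 1}"); groups.append("speciesB"); majority[ids[-1]] = "B"
    for i in range(config.n_nuisance):
        ids.append(f"N{i + 1}"); groups.append("nuisance"); majority[ids[-1]] = "B"
    for i in range(config.n_hz):
        ids.append(f"HZ{i + 1}"); groups.append("HZ")
        majority[ids[-1]] = "A" if i % 2 == 0 else "B"
    return ids, groups, majority


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> tuple[PolarisedCohort, GroundTruth]:
    """Generate a polarised cohort and its ground truth.

    Deterministic for a fixed config (``seed`` overrides ``config.seed``).
    Parental and nuisance samples are pure for their species; hybrid-zone
    samples carry mosaic ancestry along both haplotypes.  Diploid states at
    each marker are the sum of the two haplotype ancestries (0/1/2 copies of
    the species-B allele), then nuisance-private sites and missingness are
    overlaid (both recorded in the ground truth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    windows = _make_labelled_windows(config, rng)
    ids, groups, majority = sample_layout(config)
    n_samples = len(ids)

    chrom_cols, pos_cols, di_cols, state_cols = [], [], [], []
    tract_rows, junction_rows = [], []
    for chrom, length in config.chromosomes:
        pos, di = _draw_markers(config, windows, chrom, length, rng)
        states = np.zeros((n_samples, pos.size), dtype=np.int8)
        for si, (sid, grp) in enumerate(zip(ids, groups)):
            maj = majority[sid]
            if grp != "HZ":
                hapB = 1 if maj == "B" else 0
                states[si] = 2 * hapB
                tract_rows += [
                    {"sample": sid, "chromosome": chrom, "haplotype": h,
                     "start": 0, "end": length, "ancestry": maj}
                    for h in (0, 1)
                ]
                continue
            dosage = np.zeros(pos.size, dtype=np.int8)
            for h in (0, 1):
                if config.mode == "markov":
                    path, junc = _markov_path(config, windows, chrom, length, rng)
                elif config.mode == "secondary_contact":
                    params = (
                        config.sc_params_into_a if maj == "A" else config.sc_params_into_b
                    )
                    if params is None:
                        raise ValueError(
                            "secondary_contact mode needs sc_params_into_a/b"
                        )
                    path, junc = _sc_path(config, params, length, rng)
                else:
                    raise ValueError(f"unknown mode {config.mode!r}")
                minority = "B" if maj == "A" else "A"
                anc_name = {0: maj, 1: minority}
                for s, e, a in path:
                    tract_rows.append(
                        {"sample": sid, "chromosome": chrom, "haplotype": h,
                         "start": s, "end": e, "ancestry": anc_name[a]}
                    )
                junction_rows += [
                    {"sample": sid, "chromosome": chrom, "haplotype": h, "position": j}
                    for j in junc
                ]
                hap_anc = _ancestry_at(path, pos)  # 0 majority / 1 minority
                hapB = hap_anc if maj == "A" else 1 - hap_anc
                dosage += hapB.astype(np.int8)
            states[si] = dosage
        chrom_cols.append(np.full(pos.size, chrom, dtype=object))
        pos_cols.append(pos)
        di_cols.append(di)
        state_cols.append(states)

    chrom_arr = np.concatenate(chrom_cols)
    pos_arr = np.concatenate(pos_cols)
    di_arr = np.concatenate(di_cols)
    states = np.concatenate(state_cols, axis=1)

    # nuisance-private homozygous sites: a second, geographic barrier the
    # polarisation confuses with the focal one; flagged in the ground truth
    is_nuis = np.array([g == "nuisance" for g in groups])
    n_sites = states.shape[1]
    if is_nuis.any() and config.nuisance_private_rate > 0:
        private = np.nonzero(rng.random(n_sites) < config.nuisance_private_rate)[0]
        states[np.ix_(is_nuis, private)] = 2
        states[np.ix_(~is_nuis, private)] = 0
    else:
        private = np.empty(0, dtype=np.int64)

    if config.missing_rate > 0:
        miss = rng.random(states.shape) < config.missing_rate
        states[miss] = MISSING

    cohort = PolarisedCohort(
        sample_ids=ids,
        sample_groups=groups,
        chromosomes=list(config.chromosomes),
        chrom=chrom_arr,
        pos=pos_arr,
        di=di_arr,
        states=states,
    )
    truth = GroundTruth(
        tracts=pd.DataFrame(
            tract_rows,
            columns=["sample", "chromosome", "haplotype", "start", "end", "ancestry"],
        ),
        junctions=pd.DataFrame(
            junction_rows, columns=["sample", "chromosome", "haplotype", "position"]
        ),
        windows=windows,
        nuisance_private_sites=private,
        config=config,
    )
    return cohort, truth


def _make_labelled_windows(config: SimulationConfig, rng) -> WindowSet:
    ws = make_windows(config.chromosomes, config.window_span, config.window_overlap)
    if config.barrier_labels is not None:
        labels = np.asarray(config.barrier_labels, dtype=bool)
        if labels.size != len(ws):
            raise ValueError("barrier_labels do not match the window count")
    else:
        labels = rng.random(len(ws)) < config.barrier_fraction
    t = ws.table.copy()
    t["barrier"] = labels
    return WindowSet(t)


# ---------------------------------------------------------------------------
# pedigree (backcross) mode
# ---------------------------------------------------------------------------


def _gamete(hap_pair, length, rng):
    """One transmitted gamete: achiasmatic transmission (no crossover) with
    probability 1/2, else exactly one crossover at a uniform position.
    This is the sex-averaged reading of one obligate crossover per male
    meiosis and achiasmatic females."""
    h = [hap_pair[0], hap_pair[1]]
    rng.shuffle(h)
    if rng.random() < 0.5:
        return list(h[0])
    cut = rng.random() * length
    out = [(s, min(e, cut), a) for s, e, a in h[0] if s < cut]
    out += [(max(s, cut), e, a) for s, e, a in h[1] if e > cut]
    return out


def simulate_backcross(
    n: int,
    config: SimulationConfig,
    n_individuals: int | None = None,
    seed: int | None = None,
) -> PolarisedCohort:
    """Pedigree simulation of n-th generation backcross hybrids.

    Generation 1 is the F1; each later generation crosses the previous
    hybrid back to pure species A.  The expected hybrid index of the
    offspring is (1/2)^n, and no genotype is ever homozygous species-B
    (backcrossing to A only erodes the single F1 species-B haplotype).
    Returns a cohort of ``n_individuals`` independent final-generation
    individuals (default: ``config.n_hz``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_individuals = n_individuals or config.n_hz
    plain = SimulationConfig(
        seed=config.seed, chromosomes=[list(c) for c in config.chromosomes],
        marker_rate=config.marker_rate, di=config.di,
        window_span=config.window_span, window_overlap=config.window_overlap,
        barrier_fraction=0.0,
    )
    windows = make_windows(plain.chromosomes, plain.window_span, plain.window_overlap)

    chrom_cols, pos_cols, di_cols, state_cols = [], [], [], []
    for chrom, length in config.chromosomes:
        pos, di = _draw_markers(plain, windows, chrom, length, rng)
        states = np.zeros((n_individuals, pos.size), dtype=np.int8)
        pure_a = [(0.0, float(length), 0)]
        pure_b = [(0.0, float(length), 1)]
        for ind in range(n_individuals):
            hyb = (list(pure_a), list(pure_b))  # the F1
            for _ in range(n - 1):
                hyb = (_gamete(hyb, length, rng), list(pure_a))
            dosage = np.zeros(pos.size, dtype=np.int8)
            for hap in hyb:
                seg = [(s, e, a) for s, e, a in hap if e > s]
                dosage += _ancestry_at(seg, pos).astype(np.int8)
            states[ind] = dosage
        chrom_cols.append(np.full(pos.size, chrom, dtype=object))
        pos_cols.append(pos)
        di_cols.append(di)
        state_cols.append(states)

    ids = [f"BC{n}_{i + 1}" for i in range(n_individuals)]
    return PolarisedCohort(
        sample_ids=ids,
        sample_groups=["HZ"] * n_individuals,
        chromosomes=list(config.chromosomes),
        chrom=np.concatenate(chrom_cols),
        pos=np.concatenate(pos_cols),
        di=np.concatenate(di_cols),
        states=np.concatenate(state_cols, axis=1),
    )
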