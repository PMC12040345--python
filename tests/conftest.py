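import numpy as np
import pytest

from hzkit.cohort import PolarisedCohort
from hzkit.simulate import SimulationConfig, simulate_cohort


def build_cohort(
    states,
    pos=None,
    di=None,
    chrom=None,
    chromosomes=None,
    sample_ids=None,
    sample_groups=None,
):
    """Assemble a small cohort from a states matrix with sensible defaults."""
    states = np.asarray(states, dtype=np.int8)
    n_samples, n_sites = states.shape
    pos = np.arange(1, n_sites + 1) * 100 if pos is None else np.asarray(pos)
    chrom = np.array(["chr1"] * n_sites, dtype=object) if chrom is None else np.asarray(chrom, dtype=object)
    if chromosomes is None:
        chromosomes = [
            (c, int(pos[chrom == c].max()) + 100) for c in dict.fromkeys(chrom)
        ]
    di = np.full(n_sites, -5.0) if di is None else np.asarray(di, dtype=float)
    sample_ids = sample_ids or [f"s{i}" for i in range(n_samples)]
    sample_groups = sample_groups or ["HZ"] * n_samples
    return PolarisedCohort(
        sample_ids=sample_ids,
        sample_groups=sample_groups,
        chromosomes=chromosomes,
        chrom=chrom,
        pos=pos,
        di=di,
        states=states,
    )


def random_cohort(rng, n_samples=4, n_sites=30, missing_rate=0.1, n_chrom=2):
    """A random (not biologically structured) cohort for property tests."""
    states = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    states[rng.random(states.shape) < missing_rate] = -1
    per = n_sites // n_chrom
    chrom = np.concatenate(
        [[f"chr{c + 1}"] * (per if c < n_chrom - 1 else n_sites - per * (n_chrom - 1))
         for c in range(n_chrom)]
    ).astype(object)
    pos = np.concatenate(
        [np.sort(rng.choice(np.arange(1, 10_000), size=(chrom == c).sum(), replace=False))
         for c in dict.fromkeys(chrom)]
    )
    di = rng.normal(-15, 10, size=n_sites)
    if n_samples >= 4:
        groups = ["speciesA", "speciesB"] + ["HZ"] * (n_samples - 3) + ["nuisance"]
    else:
        groups = (["speciesA", "speciesB", "HZ"])[:n_samples]
    return build_cohort(states, pos=pos, di=di, chrom=chrom, sample_groups=groups)


@pytest.fixture(scope="session")
def sim_cohort():
    """Default study-scale synthetic cohort with noise features on."""
    return simulate_cohort(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free synthetic cohort (no missingness, no nuisance-private sites)."""
    return simulate_cohort(
        SimulationConfig(seed=5, missing_rate=0.0, nuisance_private_rate=0.0)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
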