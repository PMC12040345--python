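"""Externally supplied long-term demographic parameters and the
scaled-migration identity.

The isolation-with-migration fit that produces these numbers is upstream of
this package; here they are a minimal container so that the conversion from
an effective per-lineage migration rate ``m_e`` to migrants per generation,
``M/2 = 2 * Ne * m_e``, is reproducible arithmetic.  The ``Ne`` entering the
identity is the donor population's size.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml


@dataclass(frozen=True)
class DemographyParams:
    """Effective sizes (individuals), split time (generations) and effective
    migration rate (per lineage per generation) of a two-population
    isolation-with-migration history.  ``direction`` records donor ->
    recipient for the (unidirectional) gene flow."""

    n_donor: float
    n_recipient: float
    n_ancestral: float
    t_split: float
    m: float
    direction: str = "donor->recipient"

    def __post_init__(self) -> None:
        for name in ("n_donor", "n_recipient", "n_ancestral", "t_split"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m < 0:
            raise ValueError("m must be non-negative")


def scaled_migrants(params: DemographyParams, donor_ne: float | None = None) -> float:
    """Migrants per generation M/2 = 2 * Ne * m_e.

    ``donor_ne`` defaults to the donor population's effective size, the
    choice consistent with treating gene flow as lineages leaving the donor.
    """
    ne = params.n_donor if donor_ne is None else donor_ne
    return 2.0 * ne * params.m


def read_demography(path) -> DemographyParams:
    """Read parameters from a small key/value YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DemographyParams(**raw)


def write_demography(params: DemographyParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "n_donor": params.n_donor,
                "n_recipient": params.n_recipient,
                "n_ancestral": params.n_ancestral,
                "t_split": params.t_split,
                "m": params.m,
                "direction": params.direction,
            },
            fh,
        )
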