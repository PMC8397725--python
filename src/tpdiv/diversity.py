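"""Taxonomic and functional diversity indices.

* TRic: taxonomic richness, the number of species in an assemblage.
* Endemicity: the fraction of a realm's species occurring only there.
* FRic: functional richness, the volume of trait space occupied by a
  thresholded density spectrum (occupied cells x cell volume); usually
  also reported as a fraction of the world's FRic on the same grid.
* TDiss: Jaccard dissimilarity between species sets.
* FDiss: overlap-based dissimilarity between density spectra,
  ``1 - sum(min(mass_a, mass_b))``; 0 means complete overlap, 1 none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UsageError
from .tpd import TPDGrid

__all__ = [
    "Assemblage",
    "DiversitySummary",
    "fric",
    "functional_dissimilarity",
    "jaccard_dissimilarity",
    "endemicity",
]


@dataclass(frozen=True)
class Assemblage:
    """A realm's species set, optionally with IUCN statuses."""

    realm: str
    species_ids: frozenset[str]
    statuses: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not set(self.statuses) <= set(self.species_ids):
            raise InputError("statuses contain species outside the assemblage")


@dataclass(frozen=True)
class DiversitySummary:
    TRic: int
    endemicity: float
    FRic: float
    FRic_fraction_of_world: float


def fric(tpd: TPDGrid) -> float:
    """Functional richness: occupied cells times cell volume.

    Only meaningful after outlier thresholding; raw kernel mixtures have
    (numerically) positive mass almost everywhere on the grid.
    """
    if not tpd.thresholded:
        raise UsageError("threshold the TPD before measuring functional richness")
    return float(np.count_nonzero(tpd.mass) * tpd.grid.cell_volume)


def functional_dissimilarity(tpd_a: TPDGrid, tpd_b: TPDGrid) -> float:
    """Overlap-based dissimilarity between two spectra on the same grid."""
    if tpd_a.grid != tpd_b.grid:
        raise InputError("spectra are defined on different grids")
    return float(1.0 - np.minimum(tpd_a.mass, tpd_b.mass).sum())


def jaccard_dissimilarity(a, b) -> float:
    """Jaccard dissimilarity: proportion of species unique to either set."""
    a, b = set(a), set(b)
    if not a and not b:
        raise InputError("both species sets are empty")
    return 1.0 - len(a & b) / len(a | b)


def endemicity(memberships: pd.DataFrame, realm: str) -> float:
    """Fraction of a realm's species occurring in no other realm."""
    realms_present = memberships["realm"].unique()
    if realm not in realms_present:
        raise InputError(f"unknown realm {realm!r}")
    counts = memberships.groupby("species_id")["realm"].nunique()
    in_realm = memberships.loc[memberships["realm"] == realm, "species_id"].unique()
    exclusive = sum(1 for sp in in_realm if counts[sp] == 1)
    return exclusive / len(in_realm)
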