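"""Reading, validating and quality-screening the input tables.

Three CSV schemas are consumed:

* trait tables: ``species_id`` column then one positive numeric column per
  trait (missing cells allowed);
* realm memberships: ``species_id, realm`` pairs, unique;
* IUCN statuses: ``species_id, iucn_status`` with status in the closed set
  CR/EN/VU/NT/LC/DD/NE.

Occurrence records (``species_id, latitude, longitude, basis, realm``) go
through the coordinate-screening filters typically applied to aggregated
occurrence downloads: impossible or placeholder coordinates are dropped,
records from captive or museum provenance are dropped, and species with
fewer than a minimum number of records in a realm are removed from that
realm altogether, since sparse records are often misidentifications.

Two QA statistics assess whether Red List coverage is biased: a chi-squared
test of per-realm assessed counts against the realm proportions of the full
spatial dataset, and the functional overlap between the density spectrum of
all species and that of the IUCN-evaluated subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .iucn import IUCN_CATEGORIES

__all__ = [
    "BASIS_VALUES",
    "EXCLUDED_BASIS",
    "CoverageTestResult",
    "read_trait_table",
    "read_memberships",
    "read_status",
    "clean_occurrences",
    "coverage_bias_test",
    "iucn_functional_coverage",
    "assign_realms_by_box",
]

BASIS_VALUES = ("preserved_specimen", "living_specimen", "observation", "unknown", "other")

#: Provenance classes removed during cleaning: captive animals
#: (living_specimen), museum material (preserved_specimen) and records of
#: unknown origin.
EXCLUDED_BASIS = frozenset({"living_specimen", "preserved_specimen", "unknown"})


def read_trait_table(path) -> pd.DataFrame:
    """Read and validate a species x traits CSV."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise InputError("trait table must have a species_id column")
    if df["species_id"].duplicated().any():
        dup = df["species_id"][df["species_id"].duplicated()].iloc[0]
        raise InputError(f"duplicate species_id {dup!r}")
    df = df.set_index("species_id")
    if df.shape[1] < 1:
        raise InputError("trait table needs at least one trait column")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        bad_type = df[col].notna() & values.isna()
        if bad_type.any():
            row = df.index[bad_type][0]
            raise InputError(f"non-numeric trait value for {row!r} in column {col!r}")
        non_positive = values.notna() & (values <= 0)
        if non_positive.any():
            row = df.index[non_positive][0]
            raise InputError(
                f"non-positive trait value for {row!r} in column {col!r}; "
                "traits must be strictly positive"
            )
        df[col] = values
    return df


def read_memberships(path) -> pd.DataFrame:
    """Read a species_id, realm membership CSV."""
    df = pd.read_csv(path)
    for col in ("species_id", "realm"):
        if col not in df.columns:
            raise InputError(f"membership table must have a {col} column")
    df = df[["species_id", "realm"]]
    if df.duplicated().any():
        pair = df[df.duplicated()].iloc[0]
        raise InputError(
            f"duplicate membership pair ({pair['species_id']!r}, {pair['realm']!r})"
        )
    return df.reset_index(drop=True)


def read_status(path) -> pd.Series:
    """Read a species_id, iucn_status CSV into a Series."""
    df = pd.read_csv(path)
    for col in ("species_id", "iucn_status"):
        if col not in df.columns:
            raise InputError(f"status table must have a {col} column")
    if df["species_id"].duplicated().any():
        dup = df["species_id"][df["species_id"].duplicated()].iloc[0]
        raise InputError(f"duplicate status for species {dup!r}")
    unknown = ~df["iucn_status"].isin(IUCN_CATEGORIES)
    if unknown.any():
        row = df[unknown].iloc[0]
        raise InputError(
            f"unknown IUCN category {row['iucn_status']!r} for {row['species_id']!r}; "
            f"allowed: {', '.join(IUCN_CATEGORIES)}"
        )
    return df.set_index("species_id")["iucn_status"]


def clean_occurrences(records: pd.DataFrame, min_records: int = 50) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the occurrence-record screening filters.

    Drops, in order: records missing coordinates; latitude exactly equal to
    longitude (strict float equality — the filter targets data-entry
    artefacts, including the 0/0 placeholder); coordinates outside the
    valid range; captive, museum and unknown-provenance records; records
    without a realm label; and finally every (species, realm) group with
    fewer than ``min_records`` records. Row order is otherwise preserved,
    so the operation is idempotent.

    Returns the cleaned records plus a per-(species, realm) report with
    raw and retained record counts.
    """
    if records.empty:
        raise InputError("no occurrence records supplied")
    df = records.copy()
    raw_counts = (
        df.dropna(subset=["realm"]).groupby(["species_id", "realm"]).size().rename("n_raw")
    )
    df = df.dropna(subset=["latitude", "longitude"])
    df = df[df["latitude"] != df["longitude"]]
    df = df[(df["latitude"].abs() <= 90) & (df["longitude"].abs() <= 180)]
    df = df[~df["basis"].isin(EXCLUDED_BASIS)]
    df = df.dropna(subset=["realm"])
    group_sizes = df.groupby(["species_id", "realm"])["species_id"].transform("size")
    df = df[group_sizes >= min_records]
    kept_counts = df.groupby(["species_id", "realm"]).size().rename("n_kept")
    report = (
        pd.concat([raw_counts, kept_counts], axis=1)
        .fillna(0)
        .astype(int)
        .reset_index()
    )
    report["retained"] = report["n_kept"] > 0
    return df.reset_index(drop=True), report


@dataclass(frozen=True)
class CoverageTestResult:
    """Chi-squared comparison of per-realm counts against reference proportions."""

    chi2: float
    df: int
    p: float
    deviations: pd.Series  # observed - expected per realm


def coverage_bias_test(observed: pd.Series, expected_source: pd.Series) -> CoverageTestResult:
    """Test whether per-realm coverage deviates from reference proportions.

    ``observed`` holds counts (e.g. species assessed by IUCN per realm);
    ``expected_source`` holds reference counts (e.g. spatially informed
    species per realm) whose proportions define the expectation. Pearson's
    chi-squared with ``n_realms - 1`` degrees of freedom.
    """
    observed = observed.astype(float)
    expected_source = expected_source.astype(float)
    if len(observed) != len(expected_source) or not observed.index.equals(
        expected_source.index
    ):
        raise InputError("observed and expected realms must match")
    if len(observed) < 2:
        raise InputError("need at least 2 realms")
    if (expected_source <= 0).any():
        raise InputError("expected_source counts must all be positive")
    expected = expected_source / expected_source.sum() * observed.sum()
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = float(stats.chi2.sf(chi2, df))
    return CoverageTestResult(chi2=chi2, df=df, p=p, deviations=observed - expected)


def iucn_functional_coverage(tpd_all, tpd_evaluated) -> float:
    """Functional overlap between the all-species and IUCN-evaluated spectra.

    Both density grids must share the same grid specification. Returns
    ``sum(min(mass_all, mass_evaluated))`` in [0, 1]; values above ~0.9
    indicate the evaluated subset spans essentially the same trait space
    as the full species set.
    """
    if tpd_all.grid != tpd_evaluated.grid:
        raise InputError("spectra are defined on different grids")
    return float(np.minimum(tpd_all.mass, tpd_evaluated.mass).sum())


def assign_realms_by_box(records: pd.DataFrame, boxes: dict[str, tuple[float, float, float, float]]) -> pd.DataFrame:
    """Test helper: label records with realms from rectangular lat/lon boxes.

    ``boxes`` maps realm name to (lat_min, lat_max, lon_min, lon_max).
    The first matching box wins; unmatched records get a null realm.
    Real analyses overlay occurrences on realm polygons; this helper exists
    so that the realm-aware cleaning path can be tested without GIS data.
    """
    df = records.copy()
    realm = pd.Series(pd.NA, index=df.index, dtype=object)
    for name, (lat_min, lat_max, lon_min, lon_max) in boxes.items():
        inside = (
            realm.isna()
            & df["latitude"].between(lat_min, lat_max)
            & df["longitude"].between(lon_min, lon_max)
        )
        realm[inside] = name
    df["realm"] = realm
    return df
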