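"""Functional trait space: PCA of log-transformed, standardized traits.

Species traits (all strictly positive: masses, lengths, longevities,
clutch sizes...) are log-transformed, centred and scaled to unit standard
deviation per trait, and the leading principal components define a
D-dimensional functional space. Two dimensions suffice for most vertebrate
groups; four are used for morphologically richer groups such as freshwater
fishes. The standardization constants and loadings are frozen at fit time
so that later species (e.g. imputed ones) can be projected into the same
space without refitting.

Axis signs are fixed deterministically: within each axis the loading of
largest magnitude is made positive, so results do not depend on the
platform's eigensolver conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["FunctionalSpace", "fit_space", "project"]


@dataclass(frozen=True)
class FunctionalSpace:
    """A fitted PCA trait space.

    Attributes
    ----------
    trait_names : list of str
    log_means, log_sds : per-trait standardization constants (natural log scale)
    loadings : (n_traits, D) orthonormal axis matrix
    eigenvalues : variances along the D retained axes, non-increasing
    explained : fraction of total variance per retained axis
    coords : (n_species, D) DataFrame of species scores
    """

    trait_names: list[str]
    log_means: np.ndarray
    log_sds: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained: np.ndarray
    coords: pd.DataFrame

    @property
    def D(self) -> int:
        return self.loadings.shape[1]

    def save(self, directory) -> None:
        """Write loadings and coordinates as CSV plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            self.loadings,
            index=pd.Index(self.trait_names, name="trait"),
            columns=[f"PC{k + 1}" for k in range(self.D)],
        ).to_csv(directory / "loadings.csv")
        self.coords.to_csv(directory / "coordinates.csv", index_label="species_id")
        sidecar = {
            "trait_names": self.trait_names,
            "log_means": self.log_means.tolist(),
            "log_sds": self.log_sds.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained": self.explained.tolist(),
        }
        (directory / "space.json").write_text(json.dumps(sidecar, indent=2))


def _standardize(traits: pd.DataFrame, log_means: np.ndarray, log_sds: np.ndarray) -> np.ndarray:
    values = traits.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InputError(
            "trait table has missing values; impute before building the space"
        )
    if (values <= 0).any():
        raise InputError("trait values must be strictly positive")
    return (np.log(values) - log_means) / log_sds


def fit_space(traits: pd.DataFrame, D: int = 2) -> FunctionalSpace:
    """Build the functional space from a complete, positive trait table.

    Uses the correlation-matrix form of PCA (each log trait scaled to unit
    SD, ddof=1 as in standard statistical practice) and keeps the first
    ``D`` axes.
    """
    n, p = traits.shape
    if D < 1 or D > p:
        raise InputError(f"D must lie in [1, {p}]")
    if n <= D:
        raise InputError("need more species than retained dimensions")
    values = traits.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise InputError(
            "trait table has missing values; impute before building the space"
        )
    if (values <= 0).any():
        raise InputError("trait values must be strictly positive")
    log_values = np.log(values)
    log_means = log_values.mean(axis=0)
    log_sds = log_values.std(axis=0, ddof=1)
    if (log_sds == 0).any():
        bad = traits.columns[np.flatnonzero(log_sds == 0)[0]]
        raise InputError(f"trait {bad!r} is constant; PCA is undefined")
    Z = (log_values - log_means) / log_sds
    # SVD of the standardized matrix = eigendecomposition of the correlation matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    loadings = vt.T[:, :D].copy()
    for k in range(D):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = Z @ loadings
    coords = pd.DataFrame(
        scores, index=traits.index, columns=[f"PC{k + 1}" for k in range(D)]
    )
    return FunctionalSpace(
        trait_names=list(traits.columns),
        log_means=log_means,
        log_sds=log_sds,
        loadings=loadings,
        eigenvalues=eigenvalues[:D].copy(),
        explained=(eigenvalues / eigenvalues.sum())[:D].copy(),
        coords=coords,
    )


def project(space: FunctionalSpace, traits: pd.DataFrame) -> pd.DataFrame:
    """Project new species into a fitted space without refitting.

    The stored log/centre/scale constants and loadings are applied; trait
    columns must match the fitted ones exactly.
    """
    if list(traits.columns) != space.trait_names:
        raise InputError(
            f"trait columns {list(traits.columns)} do not match fitted "
            f"columns {space.trait_names}"
        )
    Z = _standardize(traits, space.log_means, space.log_sds)
    scores = Z @ space.loadings
    return pd.DataFrame(scores, index=traits.index, columns=space.coords.columns)
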