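"""Trait probability densities (TPD) on fixed grids.

A TPD represents an assemblage as a probability density over the
functional space: the mixture, with equal weights, of one multivariate
Gaussian kernel per species centred on the species' coordinates. For
computation the space is discretized into a D-dimensional grid of
equal-sized cells (typically 200 per dimension in 2-D, 30 per dimension in
4-D) and each cell carries the probability mass evaluated at its centre
times the cell volume.

Key conventions:

* the bandwidth matrix is fitted ONCE on the global species cloud and
  reused for every assemblage and scenario subset, so all spectra are
  directly comparable cell by cell;
* each species' kernel is renormalized on the grid (capturing truncation
  at the grid edges), which makes an assemblage TPD exactly the average of
  its members' single-species TPDs;
* densities are thresholded at a probability quantile (default 0.99, the
  99% highest-density region) to strip outlier tails before measuring
  occupied volume, then renormalized;
* cell probabilities can be re-expressed as quantiles — a cell's quantile
  is the cumulative mass of all cells at least as dense, so dense hotspot
  cells get small quantiles and the q=0.99 contour encloses 99% of mass.

Ties in cell mass are kept or dropped as whole blocks in both the
threshold and the quantile transform, making results independent of sort
stability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError, UsageError

__all__ = [
    "GridSpec",
    "KernelConfig",
    "TPDGrid",
    "QuantileField",
    "build_grid",
    "bandwidth_matrix",
    "species_cell_masses",
    "assemblage_tpd",
    "tpd_from_masses",
    "threshold_tpd",
    "quantile_field",
]

#: Cell masses below this value after renormalization are zeroed so that
#: occupancy masks are clean.
MASS_FLOOR = 1e-15


@dataclass(frozen=True)
class GridSpec:
    """A fixed D-dimensional grid of equal-sized cells.

    ``mins``/``maxs`` are the outer bounds per dimension and ``n_cells``
    the number of cells per dimension. Cells are indexed in C order (last
    dimension fastest) and all mass arrays are flat in that order.
    """

    mins: tuple[float, ...]
    maxs: tuple[float, ...]
    n_cells: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.mins) == len(self.maxs) == len(self.n_cells)):
            raise ConfigurationError("mins, maxs and n_cells must have equal length")
        for lo, hi, n in zip(self.mins, self.maxs, self.n_cells):
            if not lo < hi:
                raise ConfigurationError("each dimension needs min < max")
            if n < 2:
                raise ConfigurationError("need at least 2 cells per dimension")

    @property
    def D(self) -> int:
        return len(self.mins)

    @property
    def cell_widths(self) -> np.ndarray:
        return (np.asarray(self.maxs) - np.asarray(self.mins)) / np.asarray(self.n_cells)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.cell_widths))

    @property
    def total_cells(self) -> int:
        return int(np.prod(self.n_cells))

    def axis_centres(self) -> list[np.ndarray]:
        widths = self.cell_widths
        return [
            self.mins[d] + widths[d] * (np.arange(self.n_cells[d]) + 0.5)
            for d in range(self.D)
        ]

    def cell_centres(self) -> np.ndarray:
        """(total_cells, D) matrix of cell centres, C order."""
        grids = np.meshgrid(*self.axis_centres(), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def to_json(self) -> str:
        return json.dumps(
            {"mins": list(self.mins), "maxs": list(self.maxs), "n_cells": list(self.n_cells)}
        )

    @classmethod
    def from_json(cls, text: str) -> "GridSpec":
        d = json.loads(text)
        return cls(tuple(d["mins"]), tuple(d["maxs"]), tuple(d["n_cells"]))


@dataclass(frozen=True)
class KernelConfig:
    """A fitted Gaussian kernel: bandwidth matrix plus selector label."""

    H: np.ndarray  # (D, D) symmetric positive definite
    selector: str

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if H.ndim != 2 or H.shape[0] != H.shape[1]:
            raise ConfigurationError("H must be square")
        if not np.allclose(H, H.T, atol=1e-10):
            raise ConfigurationError("H must be symmetric")
        if np.linalg.eigvalsh(H).min() <= 0:
            raise ConfigurationError("H must be positive definite")

    def checksum(self) -> str:
        return np.asarray(self.H, dtype=float).tobytes().hex()[:32]


@dataclass(frozen=True)
class TPDGrid:
    """Probability mass of an assemblage over a grid."""

    grid: GridSpec
    mass: np.ndarray  # flat, C order, sums to 1
    thresholded: bool = False
    threshold_q: float | None = None
    n_species: int = 0

    @property
    def occupied(self) -> np.ndarray:
        return self.mass > 0

    def save(self, path) -> None:
        """CSV of cell masses (last dimension fastest) + GridSpec sidecar."""
        path = Path(path)
        np.savetxt(path, self.mass, fmt="%.17g")
        meta = {
            "grid": json.loads(self.grid.to_json()),
            "thresholded": self.thresholded,
            "threshold_q": self.threshold_q,
            "n_species": self.n_species,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "TPDGrid":
        path = Path(path)
        mass = np.loadtxt(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            grid=GridSpec.from_json(json.dumps(meta["grid"])),
            mass=mass,
            thresholded=meta["thresholded"],
            threshold_q=meta["threshold_q"],
            n_species=meta["n_species"],
        )


@dataclass(frozen=True)
class QuantileField:
    """Cell probabilities re-expressed as quantiles.

    ``quantile`` is NaN on unoccupied cells; on occupied cells it is the
    cumulative mass of all cells at least as dense (tie blocks share the
    block's final cumulative value), so it lies in (0, 1] and the densest
    cell's quantile equals its own mass.
    """

    grid: GridSpec
    quantile: np.ndarray
    occupied: np.ndarray


def build_grid(coords: np.ndarray, cells_per_dim: int, pad_fraction: float = 0.05) -> GridSpec:
    """Frame the species cloud with an equal-cell grid, padded per side.

    Bounds per dimension are ``[min - pad * range, max + pad * range]``.
    The grid should be built once from the global species cloud and reused
    for every assemblage, so that spectra are comparable cell by cell.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if cells_per_dim < 2:
        raise ConfigurationError("cells_per_dim must be >= 2")
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    rng = hi - lo
    if (rng == 0).any():
        raise InputError("a dimension of the species cloud has zero range")
    return GridSpec(
        mins=tuple(lo - pad_fraction * rng),
        maxs=tuple(hi + pad_fraction * rng),
        n_cells=(cells_per_dim,) * coords.shape[1],
    )


def _phi_deriv4(x: np.ndarray) -> np.ndarray:
    return (x**4 - 6 * x**2 + 3) * np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)


def _phi_deriv6(x: np.ndarray) -> np.ndarray:
    return (x**6 - 15 * x**4 + 45 * x**2 - 15) * np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)


def _dpi_bandwidth_1d(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for a univariate sample.

    Stage 0 estimates the 8th-order density functional under a normal
    reference, then two kernel functional estimates (orders 6 and 4) feed
    the final AMISE-optimal bandwidth. O(n^2) in the sample size.
    """
    n = len(x)
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise InputError("sample is degenerate (zero variance)")
    phi0 = 1.0 / np.sqrt(2 * np.pi)
    psi8 = 105.0 / (32.0 * np.sqrt(np.pi) * sd**9)
    g6 = (30.0 * phi0 / (psi8 * n)) ** (1.0 / 9.0)
    diffs = (x[:, None] - x[None, :]).ravel()
    psi6 = float(_phi_deriv6(diffs / g6).sum()) / (n**2 * g6**7)
    if psi6 >= 0:  # numerical fallback: normal-scale value
        psi6 = -15.0 / (16.0 * np.sqrt(np.pi) * sd**7)
    g4 = (-6.0 * phi0 / (psi6 * n)) ** (1.0 / 7.0)
    psi4 = float(_phi_deriv4(diffs / g4).sum()) / (n**2 * g4**5)
    if psi4 <= 0:
        psi4 = 3.0 / (8.0 * np.sqrt(np.pi) * sd**5)
    return float((1.0 / (2.0 * np.sqrt(np.pi) * psi4 * n)) ** 0.2)


def bandwidth_matrix(coords: np.ndarray, selector: str = "normal_reference") -> KernelConfig:
    """Fit an unconstrained SPD bandwidth matrix for the Gaussian kernels.

    ``normal_reference`` is exact: ``H = n**(-2/(D+4)) * Sigma_hat`` with
    the sample covariance. ``plugin`` approximates a two-stage multivariate
    plug-in: the cloud is whitened with the sample covariance, a univariate
    two-stage direct plug-in bandwidth is fitted per whitened coordinate,
    and the diagonal bandwidth is rotated back
    (``H = L diag(h_i^2) L.T`` with ``Sigma_hat = L L.T``).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n, D = coords.shape
    if n < D + 2:
        raise InputError(f"need at least D + 2 = {D + 2} species to fit a bandwidth")
    if not np.isfinite(coords).all():
        raise InputError("coordinates must be finite")
    cov = np.cov(coords, rowvar=False, ddof=1).reshape(D, D)
    if np.linalg.matrix_rank(cov) < D or np.linalg.eigvalsh(cov).min() <= 0:
        raise InputError(
            "singular sample covariance; jitter the coordinates or use the "
            "normal_reference selector on a non-degenerate subset"
        )
    if selector == "normal_reference":
        H = n ** (-2.0 / (D + 4)) * cov
    elif selector == "plugin":
        L = np.linalg.cholesky(cov)
        white = coords @ np.linalg.inv(L).T
        h = np.array([_dpi_bandwidth_1d(white[:, d]) for d in range(D)])
        H = L @ np.diag(h**2) @ L.T
    else:
        raise ConfigurationError(f"unknown bandwidth selector {selector!r}")
    return KernelConfig(H=H, selector=selector)


def species_cell_masses(coords: np.ndarray, kernel: KernelConfig, grid: GridSpec) -> np.ndarray:
    """Per-species normalized cell-mass vectors, shape (n_species, n_cells).

    Each row is the species' Gaussian kernel evaluated at the cell centres,
    multiplied by the cell volume and renormalized to sum 1 (capturing
    truncation at the grid edges). Assemblage TPDs are plain averages of
    these rows, which is what makes caching them worthwhile in the null
    model hot loops.
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.shape[1] != grid.D:
        raise InputError("coordinate dimensionality does not match the grid")
    centres = grid.cell_centres()
    L = np.linalg.cholesky(np.asarray(kernel.H, dtype=float))
    Linv = np.linalg.inv(L)
    out = np.empty((coords.shape[0], grid.total_cells))
    for i, mu in enumerate(coords):
        delta = (centres - mu) @ Linv.T
        logpdf = -0.5 * np.einsum("ij,ij->i", delta, delta)
        dens = np.exp(logpdf)
        total = dens.sum()
        if total <= 0:
            raise InputError(
                "a species kernel has no mass on the grid; enlarge the grid"
            )
        out[i] = dens / total
    return out


def tpd_from_masses(masses: np.ndarray, subset: np.ndarray | None, grid: GridSpec) -> TPDGrid:
    """Average cached per-species mass rows into an assemblage TPD."""
    if subset is not None:
        masses = masses[subset]
    if masses.shape[0] == 0:
        raise InputError("assemblage has no species")
    mass = masses.mean(axis=0)
    return TPDGrid(grid=grid, mass=mass, thresholded=False, n_species=masses.shape[0])


def assemblage_tpd(coords: np.ndarray, kernel: KernelConfig, grid: GridSpec) -> TPDGrid:
    """TPD of an assemblage: equal-weight Gaussian mixture over its species.

    The kernel must be the one fitted on the global species cloud; passing
    per-assemblage kernels would break cell-wise comparability.
    """
    masses = species_cell_masses(coords, kernel, grid)
    return tpd_from_masses(masses, None, grid)


def _descending_blocks(mass: np.ndarray):
    """Unique positive masses in descending order with their cell indices."""
    occupied = np.flatnonzero(mass > 0)
    values = mass[occupied]
    order = np.argsort(values)[::-1]
    sorted_idx = occupied[order]
    sorted_val = values[order]
    # block boundaries where the sorted value changes
    change = np.flatnonzero(np.diff(sorted_val) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(sorted_val)]))
    return sorted_idx, sorted_val, starts, ends


def threshold_tpd(tpd: TPDGrid, q: float = 0.99) -> TPDGrid:
    """Retain the highest-density region holding at least mass ``q``.

    Cells are ranked by mass; the smallest set of densest cells whose
    cumulative mass reaches ``q`` is kept (equal-mass cells as whole
    blocks), the rest is zeroed, and the result renormalized to sum 1.
    """
    if not 0.0 < q <= 1.0:
        raise ConfigurationError("q must lie in (0, 1]")
    if tpd.thresholded:
        raise UsageError("TPD is already thresholded")
    sorted_idx, sorted_val, starts, ends = _descending_blocks(tpd.mass)
    cum = np.cumsum(sorted_val)
    block_cum = cum[ends - 1]
    last_block = int(np.searchsorted(block_cum, q * (1 - 1e-12)))
    last_block = min(last_block, len(starts) - 1)
    keep = sorted_idx[: ends[last_block]]
    mass = np.zeros_like(tpd.mass)
    mass[keep] = tpd.mass[keep]
    mass = mass / mass.sum()
    mass[mass < MASS_FLOOR] = 0.0
    mass = mass / mass.sum()
    return replace(tpd, mass=mass, thresholded=True, threshold_q=q)


def quantile_field(tpd: TPDGrid) -> QuantileField:
    """Re-express cell probabilities as quantiles.

    A cell's quantile is the cumulative mass of all cells at least as
    dense as it; equal-mass cells share their block's final cumulative
    value. Dense cells get small quantiles; the maximum occupied quantile
    is 1.
    """
    total = tpd.mass.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise UsageError("TPD mass must be normalized before taking quantiles")
    sorted_idx, _, starts, ends = _descending_blocks(tpd.mass)
    quantile = np.full(tpd.mass.shape, np.nan)
    cum = np.cumsum(tpd.mass[sorted_idx])
    for s, e in zip(starts, ends):
        quantile[sorted_idx[s:e]] = cum[e - 1]
    occupied = tpd.mass > 0
    return QuantileField(grid=tpd.grid, quantile=quantile, occupied=occupied)
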