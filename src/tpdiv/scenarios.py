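"""Progressive IUCN-category extinction scenarios.

Scenarios remove whole Red List categories cumulatively, from the most
threatened outward: -CR removes only critically endangered species, -EN
adds endangered, -VU vulnerable, -NT near threatened, and -DD finally
also removes all data-deficient species (the pessimistic assumption that
every unassessable species is threatened). The baseline pool is always
the species assessed by the Red List, i.e. everything except NE.

For each scenario two spectra are built on the shared kernel and grid:
the assessed-species spectrum ("before") and the survivor spectrum
("after"), both thresholded at the outlier quantile. Reported quantities:

* ``loss_pct``: functional-richness loss as a percentage of the before
  value (marginally negative values are possible when removing an outlier
  shrinks the tails enough that the survivor highest-density region
  grows; the raw value is reported, never clamped);
* ``deltaT``: share of assessed species removed (exactly
  ``n_removed / n_assessed``);
* ``deltaF``: share of the before-occupied cells that become empty;
* a shift map: per-cell difference of quantile values, before minus
  after, so negative cells hold trait combinations becoming relatively
  rarer, and ``mean_abs_delta`` summarizes the magnitude of the
  rearrangement over the cells occupied before.

The randomized-identity null removes the same number of species uniformly
from the assessed pool (threatened and non-threatened alike) and rebuilds
the loss, yielding a 95% interval, SES and rank p for the observed loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import Assemblage, fric
from .errors import ConfigurationError, InputError
from .iucn import ASSESSED
from .nulls import NullDistribution, SESResult, ses_and_p
from .tpd import (
    GridSpec,
    KernelConfig,
    QuantileField,
    quantile_field,
    species_cell_masses,
    threshold_tpd,
    tpd_from_masses,
)

__all__ = [
    "SCENARIO_ORDER",
    "ScenarioSpec",
    "ShiftMap",
    "ScenarioResult",
    "scenario_species",
    "scenario_loss",
    "shift_map",
    "scenario_null",
]

#: Cumulative removal sets, most threatened first.
_SCENARIOS: dict[str, tuple[str, ...]] = {
    "-CR": ("CR",),
    "-EN": ("CR", "EN"),
    "-VU": ("CR", "EN", "VU"),
    "-NT": ("CR", "EN", "VU", "NT"),
    "-DD": ("CR", "EN", "VU", "NT", "DD"),
}

SCENARIO_ORDER: tuple[str, ...] = tuple(_SCENARIOS)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named cumulative extinction scenario."""

    name: str
    removed_categories: frozenset[str]

    @classmethod
    def named(cls, name: str) -> "ScenarioSpec":
        if name not in _SCENARIOS:
            raise ConfigurationError(
                f"unknown scenario {name!r}; expected one of {', '.join(_SCENARIOS)}"
            )
        return cls(name=name, removed_categories=frozenset(_SCENARIOS[name]))

    @classmethod
    def custom(cls, categories) -> "ScenarioSpec":
        cats = frozenset(categories)
        if not cats <= set(ASSESSED):
            raise ConfigurationError("custom scenarios may only remove assessed categories")
        return cls(name="custom:" + "+".join(sorted(cats)), removed_categories=cats)


@dataclass(frozen=True)
class ShiftMap:
    """Quantile-difference map between the before and after spectra."""

    grid: GridSpec
    delta: np.ndarray  # before - after; NaN where neither field occupied
    mean_abs_delta: float
    lost_cells: np.ndarray  # occupied before, empty after
    deltaF: float
    deltaT: float


@dataclass(frozen=True)
class ScenarioResult:
    scenario: ScenarioSpec
    realm: str
    n_assessed: int
    n_removed: int
    fric_before: float
    fric_after: float
    loss_pct: float
    shift: ShiftMap | None
    null: NullDistribution | None = None
    ci95: tuple[float, float] | None = None
    ses: SESResult | None = None


def _assessed_ids(assemblage: Assemblage) -> list[str]:
    if not assemblage.statuses:
        raise InputError("assemblage has no IUCN statuses")
    return sorted(
        sp for sp, status in assemblage.statuses.items() if status != "NE"
    )


def scenario_species(assemblage: Assemblage, spec: ScenarioSpec) -> set[str]:
    """Species removed by a scenario: assessed species in the removed categories."""
    return {
        sp
        for sp in _assessed_ids(assemblage)
        if assemblage.statuses[sp] in spec.removed_categories
    }


def shift_map(
    before: QuantileField, after: QuantileField, deltaT: float = float("nan")
) -> ShiftMap:
    """Quantile-difference map (before - after) with lost-space summary.

    Cells empty in one field take quantile 1 there (the limit of the least
    dense occupied cell), so a lost cell's delta is its before-quantile
    minus 1 — always negative, matching the convention that negative
    values mark trait combinations becoming less frequent. Cells empty in
    both fields are undefined (NaN). ``mean_abs_delta`` averages |delta|
    over the cells occupied before; ``deltaF`` is the lost fraction of the
    before-occupied cells.
    """
    if before.grid != after.grid:
        raise InputError("quantile fields are defined on different grids")
    either = before.occupied | after.occupied
    q_before = np.where(before.occupied, before.quantile, 1.0)
    q_after = np.where(after.occupied, after.quantile, 1.0)
    delta = np.full(before.quantile.shape, np.nan)
    delta[either] = q_before[either] - q_after[either]
    lost = before.occupied & ~after.occupied
    n_before = int(np.count_nonzero(before.occupied))
    if n_before == 0:
        raise InputError("before-field occupies no cells")
    mean_abs = float(np.abs(delta[before.occupied]).mean())
    return ShiftMap(
        grid=before.grid,
        delta=delta,
        mean_abs_delta=mean_abs,
        lost_cells=lost,
        deltaF=float(np.count_nonzero(lost) / n_before),
        deltaT=float(deltaT),
    )


def scenario_loss(
    assemblage: Assemblage,
    spec: ScenarioSpec,
    coords_by_species: dict[str, np.ndarray],
    *,
    kernel: KernelConfig,
    grid: GridSpec,
    q: float = 0.99,
    masses: np.ndarray | None = None,
    mass_index: dict[str, int] | None = None,
) -> ScenarioResult:
    """Before/after spectra, functional loss and shift map for one scenario.

    ``coords_by_species`` maps species to their functional-space
    coordinates. ``masses``/``mass_index`` optionally carry cached
    per-species cell masses (rows of ``masses`` indexed by
    ``mass_index[species]``); caching changes no result.
    """
    assessed = _assessed_ids(assemblage)
    if not assessed:
        raise InputError("assemblage has no assessed species")
    removed = scenario_species(assemblage, spec)
    survivors = [sp for sp in assessed if sp not in removed]

    if masses is None or mass_index is None:
        coords = np.array([coords_by_species[sp] for sp in assessed])
        masses = species_cell_masses(coords, kernel, grid)
        mass_index = {sp: i for i, sp in enumerate(assessed)}

    idx_before = np.array([mass_index[sp] for sp in assessed])
    tpd_before = threshold_tpd(tpd_from_masses(masses, idx_before, grid), q)
    fric_before = fric(tpd_before)
    deltaT = len(removed) / len(assessed)

    if not survivors:
        return ScenarioResult(
            scenario=spec,
            realm=assemblage.realm,
            n_assessed=len(assessed),
            n_removed=len(removed),
            fric_before=fric_before,
            fric_after=0.0,
            loss_pct=100.0,
            shift=None,
        )

    idx_after = np.array([mass_index[sp] for sp in survivors])
    tpd_after = threshold_tpd(tpd_from_masses(masses, idx_after, grid), q)
    fric_after = fric(tpd_after)
    shift = shift_map(quantile_field(tpd_before), quantile_field(tpd_after), deltaT)
    return ScenarioResult(
        scenario=spec,
        realm=assemblage.realm,
        n_assessed=len(assessed),
        n_removed=len(removed),
        fric_before=fric_before,
        fric_after=fric_after,
        loss_pct=100.0 * (fric_before - fric_after) / fric_before,
        shift=shift,
    )


def scenario_null(
    assemblage: Assemblage,
    n_removed: int,
    *,
    coords_by_species: dict[str, np.ndarray],
    kernel: KernelConfig,
    grid: GridSpec,
    q: float = 0.99,
    reps: int = 999,
    seed: int = 0,
    observed_loss: float | None = None,
    masses: np.ndarray | None = None,
    mass_index: dict[str, int] | None = None,
) -> tuple[NullDistribution, tuple[float, float], SESResult | None]:
    """Randomized-identity extinction null for one scenario.

    Each repetition removes ``n_removed`` species uniformly from the
    assessed pool and recomputes the functional-richness loss percentage.
    Returns the null losses, their empirical 2.5-97.5 percentile interval
    and, if ``observed_loss`` is given, SES and rank p of the observed
    loss against the null.
    """
    assessed = _assessed_ids(assemblage)
    n_assessed = len(assessed)
    if n_removed >= n_assessed:
        raise InputError("n_removed must be smaller than the assessed pool")
    if masses is None or mass_index is None:
        coords = np.array([coords_by_species[sp] for sp in assessed])
        masses = species_cell_masses(coords, kernel, grid)
        mass_index = {sp: i for i, sp in enumerate(assessed)}
    idx_all = np.array([mass_index[sp] for sp in assessed])
    tpd_before = threshold_tpd(tpd_from_masses(masses, idx_all, grid), q)
    fric_before = fric(tpd_before)

    rng = np.random.default_rng(seed)
    losses = np.zeros(reps)
    if n_removed > 0:
        for r in range(reps):
            drop = rng.choice(n_assessed, size=n_removed, replace=False)
            keep = np.delete(idx_all, drop)
            tpd_after = threshold_tpd(tpd_from_masses(masses, keep, grid), q)
            losses[r] = 100.0 * (fric_before - fric(tpd_after)) / fric_before
    null = NullDistribution(
        values=losses, n_draw=n_removed, pool=f"assessed:{assemblage.realm}", seed=seed
    )
    ci95 = (float(np.percentile(losses, 2.5)), float(np.percentile(losses, 97.5)))
    ses = None
    if observed_loss is not None and not null.degenerate:
        ses = ses_and_p(observed_loss, null)
    return null, ci95, ses
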