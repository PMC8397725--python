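"""Extinction scenarios: removal algebra, losses, shift maps, nulls."""

import numpy as np
import pytest

from tpdiv.diversity import Assemblage
from tpdiv.errors import ConfigurationError, InputError
from tpdiv.scenarios import (
    SCENARIO_ORDER,
    ScenarioSpec,
    scenario_loss,
    scenario_null,
    scenario_species,
    shift_map,
)
from tpdiv.tpd import GridSpec, QuantileField


@pytest.fixture
def statuses():
    return {"s1": "CR", "s2": "EN", "s3": "VU", "s4": "NT", "s5": "LC", "s6": "DD"}


@pytest.fixture
def assemblage(statuses):
    return Assemblage(realm="r", species_ids=frozenset(statuses), statuses=statuses)


class TestScenarioAlgebra:
    def test_vu_scenario_removes_cr_en_vu(self, assemblage):
        removed = scenario_species(assemblage, ScenarioSpec.named("-VU"))
        assert removed == {"s1", "s2", "s3"}

    def test_dd_scenario_keeps_only_lc(self, assemblage):
        removed = scenario_species(assemblage, ScenarioSpec.named("-DD"))
        assert removed == {"s1", "s2", "s3", "s4", "s6"}

    def test_cr_scenario_with_no_cr_species(self):
        assemblage = Assemblage(
            realm="r", species_ids=frozenset({"a"}), statuses={"a": "LC"}
        )
        assert scenario_species(assemblage, ScenarioSpec.named("-CR")) == set()

    def test_removed_sets_nested_across_scenarios(self, assemblage):
        previous = set()
        for name in SCENARIO_ORDER:
            removed = scenario_species(assemblage, ScenarioSpec.named(name))
            assert previous <= removed
            previous = removed

    def test_ne_species_outside_the_baseline(self):
        assemblage = Assemblage(
            realm="r",
            species_ids=frozenset({"a", "b"}),
            statuses={"a": "CR", "b": "NE"},
        )
        assert scenario_species(assemblage, ScenarioSpec.named("-DD")) == {"a"}

    def test_custom_spec_matches_named(self, assemblage):
        named = scenario_species(assemblage, ScenarioSpec.named("-CR"))
        custom = scenario_species(assemblage, ScenarioSpec.custom({"CR"}))
        assert named == custom

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec.named("-EX")


class TestShiftMap:
    def _field(self, quantile, grid=None):
        quantile = np.asarray(quantile, float)
        grid = grid or GridSpec((0.0,), (float(len(quantile)),), (len(quantile),))
        occupied = ~np.isnan(quantile)
        return QuantileField(grid=grid, quantile=quantile, occupied=occupied)

    def test_sign_convention(self):
        # a cell at quantile 0.3 before and 0.5 after became relatively
        # less frequent: delta = 0.3 - 0.5 = -0.2
        before = self._field([0.3, 0.7, 1.0])
        after = self._field([0.5, 0.6, 1.0])
        result = shift_map(before, after)
        assert result.delta[0] == pytest.approx(-0.2)

    def test_identical_fields_no_shift(self):
        f = self._field([0.4, 0.8, 1.0])
        result = shift_map(f, f)
        assert result.mean_abs_delta == pytest.approx(0.0)
        assert result.deltaF == pytest.approx(0.0)
        assert not result.lost_cells.any()

    def test_lost_fraction(self):
        before = self._field([0.2] * 85 + [0.9] * 15)
        after = self._field([0.25] * 85 + [np.nan] * 15)
        result = shift_map(before, after)
        assert result.deltaF == pytest.approx(0.15)
        assert result.lost_cells.sum() == 15

    def test_cells_empty_in_both_are_undefined(self):
        before = self._field([0.5, np.nan, 1.0])
        after = self._field([0.5, np.nan, 1.0])
        result = shift_map(before, after)
        assert np.isnan(result.delta[1])

    def test_grid_mismatch_rejected(self):
        a = self._field([1.0, 1.0])
        b = self._field([1.0, 1.0], grid=GridSpec((0.0,), (5.0,), (2,)))
        with pytest.raises(InputError):
            shift_map(a, b)


def _world(small_world, statuses_map):
    coords = small_world["coords"]
    ids = list(small_world["space"].coords.index)
    index = {sp: i for i, sp in enumerate(ids)}
    coords_by = {sp: coords[i] for sp, i in index.items()}
    return ids, index, coords_by


class TestScenarioLoss:
    def test_nothing_removed_no_loss(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: "LC" for sp in ids}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        result = scenario_loss(
            assemblage,
            ScenarioSpec.named("-NT"),
            coords_by,
            kernel=small_world["kernel"],
            grid=small_world["grid"],
            masses=small_world["masses"],
            mass_index=index,
        )
        assert result.loss_pct == pytest.approx(0.0)
        assert result.shift.mean_abs_delta == pytest.approx(0.0)
        assert result.shift.deltaF == pytest.approx(0.0)

    def test_everything_removed_total_loss(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: "CR" for sp in ids}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        result = scenario_loss(
            assemblage,
            ScenarioSpec.named("-CR"),
            coords_by,
            kernel=small_world["kernel"],
            grid=small_world["grid"],
            masses=small_world["masses"],
            mass_index=index,
        )
        assert result.loss_pct == pytest.approx(100.0)
        assert result.shift is None
        assert result.n_removed == result.n_assessed

    def test_delta_t_exact(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: ("CR" if i < 17 else "LC") for i, sp in enumerate(ids)}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        result = scenario_loss(
            assemblage,
            ScenarioSpec.named("-CR"),
            coords_by,
            kernel=small_world["kernel"],
            grid=small_world["grid"],
            masses=small_world["masses"],
            mass_index=index,
        )
        assert result.shift.deltaT == pytest.approx(17 / len(ids))
        assert result.n_removed == 17

    def test_isolated_cluster_loss_matches_occupancy(self, unit_kernel):
        # CR species form an isolated cluster; lost cells are exactly the
        # cells occupied only by the removed cluster
        from tpdiv.tpd import species_cell_masses, threshold_tpd, tpd_from_masses

        grid = GridSpec((-12.0, -12.0), (12.0, 12.0), (120, 120))
        lc = np.random.default_rng(0).normal(-6, 0.5, size=(20, 2))
        cr = np.random.default_rng(1).normal(6, 0.5, size=(8, 2))
        coords = np.vstack([lc, cr])
        ids = [f"s{i}" for i in range(len(coords))]
        statuses = {sp: ("LC" if i < 20 else "CR") for i, sp in enumerate(ids)}
        coords_by = {sp: coords[i] for i, sp in enumerate(ids)}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        result = scenario_loss(
            assemblage, ScenarioSpec.named("-CR"), coords_by,
            kernel=unit_kernel, grid=grid, q=0.99,
        )
        assert result.loss_pct > 0
        masses = species_cell_masses(coords, unit_kernel, grid)
        before = threshold_tpd(tpd_from_masses(masses, None, grid), 0.99)
        after = threshold_tpd(tpd_from_masses(masses, np.arange(20), grid), 0.99)
        expected_lost = (before.mass > 0) & (after.mass == 0)
        assert np.array_equal(result.shift.lost_cells, expected_lost)


class TestScenarioNull:
    def test_zero_removed_degenerate(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: "LC" for sp in ids}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        null, ci95, ses = scenario_null(
            assemblage,
            0,
            coords_by_species=coords_by,
            kernel=small_world["kernel"],
            grid=small_world["grid"],
            reps=19,
            seed=0,
            masses=small_world["masses"],
            mass_index=index,
        )
        assert np.allclose(null.values, 0.0)
        assert null.degenerate
        assert ci95 == (0.0, 0.0)

    def test_null_reproducible_and_ci_ordered(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: ("EN" if i < 25 else "LC") for i, sp in enumerate(ids)}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        kwargs = dict(
            coords_by_species=coords_by,
            kernel=small_world["kernel"],
            grid=small_world["grid"],
            reps=49,
            seed=11,
            masses=small_world["masses"],
            mass_index=index,
        )
        null_a, ci_a, _ = scenario_null(assemblage, 25, **kwargs)
        null_b, ci_b, _ = scenario_null(assemblage, 25, **kwargs)
        assert np.array_equal(null_a.values, null_b.values)
        assert ci_a == ci_b
        assert ci_a[0] <= np.median(null_a.values) <= ci_a[1]

    def test_observed_random_loss_inside_ci(self, small_world):
        # when "threatened" species are themselves a random subset, the
        # observed loss is generally not significant
        ids, index, coords_by = _world(small_world, None)
        rng = np.random.default_rng(2)
        inside = 0
        for rep in range(20):
            threatened = set(rng.choice(ids, size=30, replace=False))
            statuses = {sp: ("VU" if sp in threatened else "LC") for sp in ids}
            assemblage = Assemblage("r", frozenset(ids), statuses)
            result = scenario_loss(
                assemblage, ScenarioSpec.named("-VU"), coords_by,
                kernel=small_world["kernel"], grid=small_world["grid"],
                masses=small_world["masses"], mass_index=index,
            )
            null, ci95, ses = scenario_null(
                assemblage, 30, coords_by_species=coords_by,
                kernel=small_world["kernel"], grid=small_world["grid"],
                reps=99, seed=100 + rep, observed_loss=result.loss_pct,
                masses=small_world["masses"], mass_index=index,
            )
            inside += ci95[0] <= result.loss_pct <= ci95[1]
        assert inside >= 17  # ~95% coverage, allow Monte Carlo slack

    def test_removing_whole_pool_rejected(self, small_world):
        ids, index, coords_by = _world(small_world, None)
        statuses = {sp: "CR" for sp in ids}
        assemblage = Assemblage("r", frozenset(ids), statuses)
        with pytest.raises(InputError):
            scenario_null(
                assemblage,
                len(ids),
                coords_by_species=coords_by,
                kernel=small_world["kernel"],
                grid=small_world["grid"],
                reps=9,
                seed=0,
                masses=small_world["masses"],
                mass_index=index,
            )
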