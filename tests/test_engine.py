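import math
from dataclasses import replace

import numpy as np
import pytest

from nanotx.cells import OxygenResponse
from nanotx.dosing import Schedule
from nanotx.engine import (CellPopulation, PhenotypeParams, SimConfig,
                           hex_disk_positions, initialize, run, step)
from nanotx.errors import ConfigurationError
from nanotx.microenv import Grid
from nanotx.nano import NPDesign
from nanotx.pharmacodynamics import PDParams


def small_config(**overrides):
    base = dict(
        grid=Grid(200.0, 200.0, dx=20.0),
        phenotype=PhenotypeParams(o2_uptake=0.0),
        design=NPDesign(),
        schedule=Schedule(injections=((0.0, 1.0),), clearance_rate=1e-3,
                          reference_dose=0.1),
        dt_diffusion=1.0, dt_mechanics=6.0, dt_phenotype=6.0,
        t_end=60.0, output_cadence=30.0, initial_tumor_radius=40.0, seed=3,
    )
    base.update(overrides)
    return SimConfig(**base)


class TestInitialize:
    def test_zero_radius_single_centered_cell(self):
        state = initialize(small_config(initial_tumor_radius=0.0))
        assert len(state.cells) == 1
        np.testing.assert_allclose(state.cells.pos[0], [100.0, 100.0])

    def test_hex_packing_count_matches_enumeration(self):
        """Cell count equals a direct enumeration of hex-lattice points in the disk."""
        config = small_config(initial_tumor_radius=60.0)
        state = initialize(config)
        R = config.initial_tumor_radius
        s = 2.0 * (3.0 * config.phenotype.cell_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
        count = 0
        dy = s * math.sqrt(3.0) / 2.0
        for k in range(-20, 21):
            y = k * dy
            off = s / 2.0 if k % 2 else 0.0
            for i in range(-20, 21):
                if math.hypot(i * s + off, y) <= R:
                    count += 1
        assert len(state.cells) == count > 1

    def test_same_seed_bit_identical(self):
        a = initialize(small_config())
        b = initialize(small_config())
        assert np.array_equal(a.cells.pos, b.cells.pos)
        assert np.array_equal(a.oxygen.values, b.oxygen.values)

    def test_oversized_tumor_rejected(self):
        with pytest.raises(ConfigurationError, match="does not fit"):
            small_config(initial_tumor_radius=150.0)

    def test_initial_fields(self):
        state = initialize(small_config())
        assert state.np_field.total_number() == 0.0
        assert state.oxygen.values.max() <= 38.0 + 1e-9


class TestStep:
    def test_no_cells_fields_still_evolve(self):
        config = small_config(initial_tumor_radius=0.0)
        state = initialize(config)
        state.cells.keep(np.zeros(1, dtype=bool))
        step(state, config)
        assert state.time == config.dt_phenotype
        assert state.np_field.total_number() > 0.0  # boundary injection diffused in

    def test_equal_seeds_identical_trajectories(self):
        cfg = small_config(t_end=720.0)
        s1 = run(cfg).series
        s2 = run(cfg).series
        assert s1.equals(s2)

    def test_different_seeds_diverge(self):
        cfg = small_config(t_end=2880.0)
        a = run(cfg).series
        b = run(replace(cfg, seed=99)).series
        assert not a["viable"].equals(b["viable"])

    def test_uptake_conservation_exact(self):
        """Extracellular NP mass removed by uptake equals the influx credited
        to the cells (same numbers by construction), and the global ledger
        closes."""
        config = small_config(t_end=360.0)
        state = initialize(config)
        for _ in range(30):
            step(state, config)
        led = state.ledger
        assert led["internalized"] > 0
        audit = state.audit()
        assert abs(audit["relative_ext"]) < 1e-6
        assert abs(audit["relative_int"]) < 1e-6

    def test_boundary_tracks_schedule(self):
        config = small_config()
        state = initialize(config)
        step(state, config)
        expected = 0.1 * math.exp(-1e-3 * state.time)
        assert state.np_field.dirichlet_value == pytest.approx(expected)

    def test_dead_cells_do_not_take_up_nps(self):
        config = small_config()
        state = initialize(config)
        state.cells.state[:] = 2  # all necrotic
        state.cells.timer[:] = 1e9
        nI0 = state.cells.n.sum()
        for _ in range(5):
            step(state, config)
        assert state.cells.n.sum() == nI0 == 0.0
        assert state.ledger["internalized"] == 0.0


class TestRun:
    def test_zero_horizon_initial_state_only(self):
        traj = run(small_config(t_end=0.0))
        assert len(traj.rows) == 1
        assert traj.rows[0]["time"] == 0.0

    def test_ledger_audit_passes_at_every_output_time(self):
        traj = run(small_config(t_end=720.0, output_cadence=60.0))
        s = traj.series
        assert (s["audit_relative_ext"].abs() < 1e-6).all()
        assert (s["audit_relative_int"].abs() < 1e-6).all()

    def test_counts_are_nonnegative_integers(self):
        s = run(small_config(t_end=720.0)).series
        for col in ("viable", "apoptotic", "necrotic"):
            assert (s[col] >= 0).all()
            assert (s[col] == s[col].astype(int)).all()

    def test_inheritance_moves_nps_to_daughters(self):
        """With x=0.5 and ample NPs, dividing cells pass their load on; the
        division-loss ledger stays zero."""
        cfg = small_config(t_end=2880.0, inheritance_fraction=0.5,
                           schedule=Schedule(injections=((0.0, 1.0),),
                                             clearance_rate=0.0, reference_dose=0.2))
        traj = run(cfg)
        assert traj.final_state.ledger["lost_division"] == 0.0
        cfg0 = replace(cfg, inheritance_fraction=0.0)
        traj0 = run(cfg0)
        assert traj0.final_state.ledger["lost_division"] >= 0.0


class TestConfigValidation:
    def test_time_step_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            small_config(dt_diffusion=6.0, dt_mechanics=1.0)

    def test_uneven_nesting_rejected(self):
        with pytest.raises(ConfigurationError):
            small_config(dt_diffusion=4.0, dt_mechanics=6.0)

    def test_inheritance_bounds(self):
        with pytest.raises(ConfigurationError):
            small_config(inheritance_fraction=0.7)


class TestHexPacking:
    def test_zero_radius_one_point(self):
        pts = hex_disk_positions(0.0, 8.4, (50.0, 50.0))
        assert pts.shape == (1, 2)

    def test_points_within_disk(self):
        pts = hex_disk_positions(75.0, 8.4, (0.0, 0.0))
        assert (np.hypot(pts[:, 0], pts[:, 1]) <= 75.0 + 1e-9).all()

    def test_minimum_spacing_is_cell_diameter(self):
        pts = hex_disk_positions(60.0, 8.0, (0.0, 0.0))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert d.min() == pytest.approx(16.0, rel=1e-9)


class TestPopulationContainer:
    def test_snapshot_schema(self):
        state = initialize(small_config())
        snap = state.cells.snapshot()
        m = state.cells.m
        assert snap.index.name == "id"
        assert len(snap.columns) == 9 + m
        assert list(snap.columns[:9]) == ["x", "y", "volume", "state", "b_current",
                                          "apoptosis_current", "n_total", "C", "E"]

    def test_to_cells_round_trip_values(self):
        state = initialize(small_config())
        state.cells.n[0, 0] = 2.5
        cells = state.cells.to_cells()
        assert cells[0].np_comp.n[0] == 2.5
        assert cells[0].state == "viable"
        assert cells[0].radius == pytest.approx(
            (3 * cells[0].volume / (4 * math.pi)) ** (1 / 3))

    def test_append_assigns_fresh_ids(self):
        pop = CellPopulation(m=3)
        ids1 = pop.append(np.zeros((2, 2)), np.ones(2), np.zeros((2, 3)),
                          np.zeros(2), np.zeros(2), np.ones(2), np.ones(2))
        ids2 = pop.append(np.zeros((1, 2)), np.ones(1), np.zeros((1, 3)),
                          np.zeros(1), np.zeros(1), np.ones(1), np.ones(1))
        assert set(ids1) == {0, 1} and set(ids2) == {2}
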