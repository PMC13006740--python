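"""Multi-rate simulation engine.

A phenotype step (default 6 min) nests faster diffusion substeps (field
update + dosing boundary + per-cell uptake) and mechanics substeps
(pairwise forces + explicit position update), then performs the per-cell
biology: intracellular NP/drug kinetics, pharmacodynamic effect, phenotype
interpolation, stochastic cycle/death events, and division/death
bookkeeping. A single seeded random generator per run is consumed in a
fixed order (per phenotype step: one (N, 3) block of event uniforms, then
one division angle per dividing cell), so equal seeds give identical
trajectories.

Cells are stored as a structure of arrays (:class:`CellPopulation`) so the
inner loops vectorize; :meth:`CellPopulation.to_cells` materializes the
per-cell :class:`~nanotx.cells.Cell` records used by the module-level API
and snapshots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import pharmacodynamics as pd_mod
from .cells import (APOPTOTIC, NECROTIC, VIABLE, Cell, DeathParams, MechanicsParams,
                    OxygenResponse, necrosis_rate, pairwise_velocities,
                    proliferation_rate, radius_from_volume)
from .dosing import Schedule, boundary_concentration
from .errors import ConfigurationError
from .microenv import (Field, Grid, apply_cell_uptake, create_field,
                       diffuse_decay_step, steady_state_field)
from .nano import NPCompartment, NPDesign, cascade_step_arrays, uptake_coefficient
from .pharmacodynamics import CYTOSTATIC, PDParams, hill_effect, interpolate_phenotype

STATE_CODES = {VIABLE: 0, APOPTOTIC: 1, NECROTIC: 2}
STATE_NAMES = {v: k for k, v in STATE_CODES.items()}


@dataclass(frozen=True)
class SubstrateParams:
    """Diffusion/decay/boundary parameters of one substrate field."""

    diffusion: float          # um^2/min
    decay: float = 0.0        # 1/min
    boundary_value: float = 0.0
    initial_value: float | None = None  # None -> boundary value


@dataclass(frozen=True)
class PhenotypeParams:
    """Cell phenotype block: sizes, base rates, death timing, mechanics."""

    cell_volume: float = 2494.0      # um^3
    oxygen: OxygenResponse = dc_field(default_factory=OxygenResponse)
    apoptosis_rate: float = 5.3167e-05  # base apoptosis rate, 1/min
    o2_uptake: float = 10.0          # per-cell oxygen uptake rate, 1/min
    death: DeathParams = dc_field(default_factory=DeathParams)
    mechanics: MechanicsParams = dc_field(default_factory=MechanicsParams)

    def __post_init__(self):
        errs = []
        if self.cell_volume <= 0:
            errs.append(f"cell volume must be > 0, got {self.cell_volume}")
        if self.apoptosis_rate < 0 or self.o2_uptake < 0:
            errs.append("phenotype rates must be >= 0")
        if errs:
            raise ConfigurationError("invalid phenotype parameters", errs)


@dataclass(frozen=True)
class SimConfig:
    """Complete, validated description of one simulation run."""

    grid: Grid = dc_field(default_factory=lambda: Grid(400.0, 400.0))
    oxygen: SubstrateParams = dc_field(
        default_factory=lambda: SubstrateParams(diffusion=1.0e5, decay=0.1, boundary_value=38.0))
    np_field: SubstrateParams = dc_field(
        default_factory=lambda: SubstrateParams(diffusion=6.0, decay=0.0,
                                                boundary_value=0.0, initial_value=0.0))
    phenotype: PhenotypeParams = dc_field(default_factory=PhenotypeParams)
    design: NPDesign = dc_field(default_factory=NPDesign)
    pd: PDParams = dc_field(default_factory=PDParams)
    schedule: Schedule = dc_field(default_factory=Schedule)
    inheritance_fraction: float = 0.0
    dt_diffusion: float = 0.01   # min
    dt_mechanics: float = 0.1    # min
    dt_phenotype: float = 6.0    # min
    t_end: float = 43200.0       # min (30 days)
    output_cadence: float = 720.0  # min
    initial_tumor_radius: float = 100.0  # um
    seed: int = 0
    save_snapshots: bool = False
    # Oxygen relaxes across the domain in well under a minute (D ~ 1e5
    # um^2/min), so by default it is solved quasi-steady once per phenotype
    # step instead of transiently substepped.
    oxygen_quasi_steady: bool = True

    def __post_init__(self):
        errs = []
        if not (0.0 < self.dt_diffusion <= self.dt_mechanics <= self.dt_phenotype):
            errs.append(
                f"time steps must satisfy 0 < dt_diffusion <= dt_mechanics <= dt_phenotype, "
                f"got {self.dt_diffusion}, {self.dt_mechanics}, {self.dt_phenotype}")
        else:
            for a, b, na, nb in ((self.dt_diffusion, self.dt_mechanics, "dt_diffusion", "dt_mechanics"),
                                 (self.dt_mechanics, self.dt_phenotype, "dt_mechanics", "dt_phenotype")):
                k = b / a
                if abs(k - round(k)) > 1e-9:
                    errs.append(f"{na}={a} must divide {nb}={b} evenly")
        if self.t_end < 0:
            errs.append(f"t_end must be >= 0, got {self.t_end}")
        if self.output_cadence <= 0:
            errs.append(f"output cadence must be > 0, got {self.output_cadence}")
        if not (0.0 <= self.inheritance_fraction <= 0.5):
            errs.append(
                f"inheritance_fraction must be in [0, 0.5], got {self.inheritance_fraction}")
        margin = radius_from_volume(self.phenotype.cell_volume) + self.grid.dx
        if self.initial_tumor_radius < 0:
            errs.append("initial tumor radius must be >= 0")
        elif self.initial_tumor_radius + margin > min(self.grid.width, self.grid.height) / 2:
            errs.append(
                f"initial tumor radius {self.initial_tumor_radius} um does not fit the "
                f"{self.grid.width}x{self.grid.height} um domain")
        if errs:
            raise ConfigurationError("invalid simulation configuration", errs)


class CellPopulation:
    """Structure-of-arrays container for the cell agents of one run."""

    def __init__(self, m: int):
        self.m = int(m)
        self.ids = np.zeros(0, dtype=np.int64)
        self.pos = np.zeros((0, 2))
        self.volume = np.zeros(0)
        self.state = np.zeros(0, dtype=np.int8)
        self.timer = np.zeros(0)
        self.n = np.zeros((0, self.m))
        self.C = np.zeros(0)
        self.auc = np.zeros(0)
        self.effect = np.zeros(0)
        self.b_current = np.zeros(0)
        self.a_current = np.zeros(0)
        self.next_id = 0

    def __len__(self) -> int:
        return self.ids.size

    @property
    def radius(self) -> np.ndarray:
        return radius_from_volume(self.volume)

    @property
    def viable(self) -> np.ndarray:
        return self.state == STATE_CODES[VIABLE]

    def counts(self) -> dict:
        return {name: int((self.state == code).sum()) for name, code in STATE_CODES.items()}

    def append(self, pos, volume, n, C, auc, b_current, a_current) -> np.ndarray:
        """Add new (viable) cells; returns their ids."""
        k = len(pos)
        new_ids = np.arange(self.next_id, self.next_id + k, dtype=np.int64)
        self.next_id += k
        self.ids = np.concatenate([self.ids, new_ids])
        self.pos = np.vstack([self.pos, np.asarray(pos, dtype=float)])
        self.volume = np.concatenate([self.volume, np.asarray(volume, dtype=float)])
        self.state = np.concatenate([self.state, np.zeros(k, dtype=np.int8)])
        self.timer = np.concatenate([self.timer, np.zeros(k)])
        self.n = np.vstack([self.n, np.asarray(n, dtype=float).reshape(k, self.m)])
        self.C = np.concatenate([self.C, np.asarray(C, dtype=float)])
        self.auc = np.concatenate([self.auc, np.asarray(auc, dtype=float)])
        self.effect = np.concatenate([self.effect, np.zeros(k)])
        self.b_current = np.concatenate([self.b_current, np.asarray(b_current, dtype=float)])
        self.a_current = np.concatenate([self.a_current, np.asarray(a_current, dtype=float)])
        return new_ids

    def keep(self, mask: np.ndarray) -> None:
        for name in ("ids", "pos", "volume", "state", "timer", "n", "C",
                     "auc", "effect", "b_current", "a_current"):
            setattr(self, name, getattr(self, name)[mask])

    def to_cells(self, design_m: int | None = None) -> list[Cell]:
        out = []
        for i in range(len(self)):
            out.append(Cell(
                id=int(self.ids[i]),
                position=self.pos[i].copy(),
                volume=float(self.volume[i]),
                state=STATE_NAMES[int(self.state[i])],
                state_timer=float(self.timer[i]),
                b_current=float(self.b_current[i]),
                a_current=float(self.a_current[i]),
                np_comp=NPCompartment(n=self.n[i].copy(), C=float(self.C[i]),
                                      auc=float(self.auc[i])),
                effect=float(self.effect[i]),
            ))
        return out

    def snapshot(self) -> pd.DataFrame:
        """Per-cell table: id (index), x, y, volume, state, rates, nI, C, E, n0..n{m-1}."""
        data = {
            "x": self.pos[:, 0], "y": self.pos[:, 1], "volume": self.volume,
            "state": [STATE_NAMES[int(s)] for s in self.state],
            "b_current": self.b_current, "apoptosis_current": self.a_current,
            "n_total": self.n.sum(axis=1), "C": self.C, "E": self.effect,
        }
        for j in range(self.m):
            data[f"n{j}"] = self.n[:, j]
        return pd.DataFrame(data, index=pd.Index(self.ids, name="id"))


def _empty_ledger() -> dict:
    return {k: 0.0 for k in ("boundary_net", "decayed_ext", "internalized",
                             "decayed_int", "spent", "cleared_death", "lost_division")}


@dataclass
class SimState:
    """Mutable run state: time, fields, cells, mass ledger, rng stream."""

    time: float
    oxygen: Field
    np_field: Field
    cells: CellPopulation
    ledger: dict
    rng: np.random.Generator
    nE0: float

    def audit(self) -> dict:
        """Nanoparticle mass-balance residuals (relative to the largest flow).

        Extracellular: nE - nE0 = boundary_net - decayed_ext - internalized.
        Intracellular: resident NP total = internalized - decayed_int -
        spent - cleared_death - lost_division.
        """
        led = self.ledger
        nE = self.np_field.total_number()
        res_ext = nE - self.nE0 - (led["boundary_net"] - led["decayed_ext"] - led["internalized"])
        resident = float(self.cells.n.sum())
        res_int = resident - (led["internalized"] - led["decayed_int"] - led["spent"]
                              - led["cleared_death"] - led["lost_division"])
        scale = max(1.0e-12, nE, self.nE0, abs(led["boundary_net"]), led["internalized"])
        return {"residual_ext": res_ext, "residual_int": res_int, "scale": scale,
                "relative_ext": res_ext / scale, "relative_int": res_int / scale}


def hex_disk_positions(tumor_radius: float, cell_radius: float,
                       center: tuple[float, float]) -> np.ndarray:
    """Centers of a hexagonally packed disk of cells (spacing = 2 cell radii)."""
    s = 2.0 * cell_radius
    if tumor_radius < 0:
        raise ConfigurationError(f"tumor radius must be >= 0, got {tumor_radius}")
    pts = [(0.0, 0.0)]
    if tumor_radius > 0:
        pts = []
        dy = s * math.sqrt(3.0) / 2.0
        kmax = int(math.floor(tumor_radius / dy)) + 1
        for k in range(-kmax, kmax + 1):
            y = k * dy
            x_off = (s / 2.0) if (k % 2) else 0.0
            imax = int(math.floor((tumor_radius + s) / s)) + 1
            for i in range(-imax, imax + 1):
                x = i * s + x_off
                if math.hypot(x, y) <= tumor_radius:
                    pts.append((x, y))
        if not pts:
            pts = [(0.0, 0.0)]
    out = np.array(pts, dtype=float)
    out[:, 0] += center[0]
    out[:, 1] += center[1]
    return out


def initialize(config: SimConfig) -> SimState:
    """Seeded tumor disk at the domain center, oxygen equilibrated, no NPs."""
    grid = config.grid
    oxygen = create_field(grid, "oxygen", config.oxygen.diffusion, config.oxygen.decay,
                          config.oxygen.boundary_value, config.oxygen.initial_value)
    npf = create_field(grid, "nanoparticle", config.np_field.diffusion,
                       config.design.lambda_extra, config.np_field.boundary_value,
                       0.0 if config.np_field.initial_value is None
                       else config.np_field.initial_value)
    pop = CellPopulation(config.design.m)
    center = (grid.width / 2.0, grid.height / 2.0)
    cell_r = float(radius_from_volume(config.phenotype.cell_volume))
    pos = hex_disk_positions(config.initial_tumor_radius, cell_r, center)
    k = len(pos)
    b0 = proliferation_rate(config.oxygen.boundary_value, config.phenotype.oxygen)
    pop.append(pos, np.full(k, config.phenotype.cell_volume), np.zeros((k, config.design.m)),
               np.zeros(k), np.zeros(k), np.full(k, float(b0)),
               np.full(k, config.phenotype.apoptosis_rate))
    rng = np.random.default_rng(config.seed)
    state = SimState(time=0.0, oxygen=oxygen, np_field=npf, cells=pop,
                     ledger=_empty_ledger(), rng=rng, nE0=npf.total_number())
    if config.oxygen_quasi_steady:
        _solve_oxygen(state, config, np.nonzero(pop.viable)[0])
    return state


def _solve_oxygen(state: SimState, config: SimConfig, v_idx: np.ndarray) -> None:
    """Quasi-steady oxygen solve with viable-cell uptake as per-voxel sinks."""
    pop = state.cells
    q = np.zeros_like(state.oxygen.values)
    if v_idx.size and config.phenotype.o2_uptake > 0:
        ix, iy = config.grid.voxel_of(pop.pos[v_idx], pop.ids[v_idx])
        np.add.at(q, (ix, iy),
                  config.phenotype.o2_uptake * pop.volume[v_idx] / config.grid.voxel_volume)
    steady_state_field(state.oxygen, q)


def step(state: SimState, config: SimConfig) -> SimState:
    """Advance one phenotype time step (see module docstring for the order)."""
    pop = state.cells
    dt_p = config.dt_phenotype
    n_diff = int(round(dt_p / config.dt_diffusion))
    n_mech = int(round(dt_p / config.dt_mechanics))
    dt_d = dt_p / n_diff
    dt_m = dt_p / n_mech
    phen = config.phenotype

    # --- oxygen: quasi-steady profile given current viable-cell sinks ---
    viable = pop.viable
    v_idx = np.nonzero(viable)[0]
    if config.oxygen_quasi_steady:
        _solve_oxygen(state, config, v_idx)

    # --- NP diffusion substeps with dosing boundary and cell uptake ---
    influx = np.zeros(len(pop))
    nI_running = pop.n.sum(axis=1)
    for k in range(n_diff):
        t_sub = state.time + (k + 1) * dt_d
        state.np_field.dirichlet_value = boundary_concentration(t_sub, config.schedule)
        if not config.oxygen_quasi_steady:
            diffuse_decay_step(state.oxygen, dt_d)
        diffuse_decay_step(state.np_field, dt_d, state.ledger)
        if v_idx.size:
            if not config.oxygen_quasi_steady and phen.o2_uptake > 0:
                apply_cell_uptake(state.oxygen, pop.pos[v_idx],
                                  np.full(v_idx.size, phen.o2_uptake),
                                  pop.volume[v_idx], dt_d, ids=pop.ids[v_idx])
            U = uptake_coefficient(nI_running[v_idx], config.design)
            if np.any(U > 0):
                up = apply_cell_uptake(state.np_field, pop.pos[v_idx], U,
                                       pop.volume[v_idx], dt_d, ids=pop.ids[v_idx])
                influx[v_idx] += up
                nI_running[v_idx] += up
                state.ledger["internalized"] += float(up.sum())

    # --- mechanics substeps ---
    if len(pop) > 1:
        radii = pop.radius
        cap = phen.mechanics.max_step_fraction * np.maximum(radii, 1e-6)
        for _ in range(n_mech):
            vel = pairwise_velocities(pop.pos, radii, phen.mechanics, state.rng)
            disp = vel * dt_m
            norm = np.sqrt((disp * disp).sum(axis=1))
            over = norm > cap
            if np.any(over):
                disp[over] *= (cap[over] / norm[over])[:, None]
            pop.pos += disp
        margin = config.grid.dx / 2.0
        np.clip(pop.pos[:, 0], margin, config.grid.width - margin, out=pop.pos[:, 0])
        np.clip(pop.pos[:, 1], margin, config.grid.height - margin, out=pop.pos[:, 1])

    if len(pop) == 0:
        state.time += dt_p
        return state

    # --- per-cell biology at the phenotype cadence ---
    ix, iy = config.grid.voxel_of(pop.pos, pop.ids)
    sigma = state.oxygen.values[ix, iy]

    if v_idx.size:
        n_v, C_v, auc_v, led = cascade_step_arrays(
            pop.n[v_idx], pop.C[v_idx], pop.auc[v_idx], influx[v_idx],
            pop.volume[v_idx], dt_p, config.design)
        pop.n[v_idx] = n_v
        pop.C[v_idx] = C_v
        pop.auc[v_idx] = auc_v
        state.ledger["decayed_int"] += led["decayed_int"]
        state.ledger["spent"] += led["spent"]

        if config.pd.model == pd_mod.AUC:
            E = hill_effect(pop.auc[v_idx], config.pd)
        else:
            E = hill_effect(pop.C[v_idx] / pop.volume[v_idx], config.pd)
        pop.effect[v_idx] = E
        b_ox = proliferation_rate(sigma[v_idx], phen.oxygen)
        if config.pd.mode == CYTOSTATIC:
            pop.b_current[v_idx] = interpolate_phenotype(E, config.pd, b0=b_ox)
            pop.a_current[v_idx] = phen.apoptosis_rate
        else:
            pop.b_current[v_idx] = b_ox
            pop.a_current[v_idx] = interpolate_phenotype(E, config.pd,
                                                         b0=phen.apoptosis_rate)
        nec_rate = necrosis_rate(sigma[v_idx], phen.oxygen)

        # stochastic events: fixed draw order, precedence necrose > apoptose > divide
        draws = state.rng.random((v_idx.size, 3))
        p_nec = -np.expm1(-nec_rate * dt_p)
        p_apo = -np.expm1(-pop.a_current[v_idx] * dt_p)
        p_div = -np.expm1(-pop.b_current[v_idx] * dt_p)
        necrose = draws[:, 0] < p_nec
        apoptose = ~necrose & (draws[:, 1] < p_apo)
        divide = ~necrose & ~apoptose & (draws[:, 2] < p_div)

        for local in np.nonzero(necrose | apoptose)[0]:
            i = v_idx[local]
            state.ledger["cleared_death"] += float(pop.n[i].sum())
            pop.n[i] = 0.0
            pop.C[i] = 0.0
            if necrose[local]:
                pop.state[i] = STATE_CODES[NECROTIC]
                pop.timer[i] = phen.death.necrosis_lysis_time
            else:
                pop.state[i] = STATE_CODES[APOPTOTIC]
                pop.timer[i] = phen.death.apoptosis_duration

        dividers = v_idx[np.nonzero(divide)[0]]
        removed_parent = np.zeros(len(pop), dtype=bool)
        if dividers.size:
            x = config.inheritance_fraction
            new_pos, new_vol, new_n, new_C, new_auc, new_b, new_a = [], [], [], [], [], [], []
            for i in dividers:
                theta = state.rng.uniform(0.0, 2.0 * math.pi)
                u = np.array([math.cos(theta), math.sin(theta)])
                off = 0.5 * float(radius_from_volume(pop.volume[i])) * u
                state.ledger["lost_division"] += (1.0 - 2.0 * x) * float(pop.n[i].sum())
                for sign in (1.0, -1.0):
                    new_pos.append(pop.pos[i] + sign * off)
                    new_vol.append(pop.volume[i] / 2.0)
                    new_n.append(x * pop.n[i])
                    new_C.append(pop.C[i] / 2.0)
                    new_auc.append(pop.auc[i] / 2.0)
                    new_b.append(pop.b_current[i])
                    new_a.append(pop.a_current[i])
                removed_parent[i] = True
            pop.keep(~removed_parent)
            pop.append(np.array(new_pos), np.array(new_vol), np.array(new_n),
                       np.array(new_C), np.array(new_auc), np.array(new_b),
                       np.array(new_a))

    # --- dead-cell progression and removal ---
    dead = ~pop.viable
    if np.any(dead):
        apo = pop.state == STATE_CODES[APOPTOTIC]
        shrinkable = apo & (pop.timer > 0)
        frac = np.minimum(1.0, dt_p / np.where(shrinkable, pop.timer, np.inf))
        pop.volume[shrinkable] *= np.maximum(0.0, 1.0 - frac[shrinkable])
        pop.timer[dead] -= dt_p
        remove = dead & (pop.timer <= 0)
        if np.any(remove):
            pop.keep(~remove)

    state.time += dt_p
    return state


@dataclass
class Trajectory:
    """Time series (and optional snapshots) emitted by :func:`run`."""

    config: SimConfig
    rows: list = dc_field(default_factory=list)
    snapshots: dict = dc_field(default_factory=dict)
    final_state: SimState | None = None

    @property
    def series(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def endpoint(self, column: str = "viable") -> float:
        return float(self.rows[-1][column])


def _record(traj: Trajectory, state: SimState, config: SimConfig) -> None:
    counts = state.cells.counts()
    audit = state.audit()
    row = {
        "time": state.time,
        "viable": counts[VIABLE],
        "apoptotic": counts[APOPTOTIC],
        "necrotic": counts[NECROTIC],
        "nE": state.np_field.total_number(),
        "nI_total": float(state.cells.n.sum()),
        "C_total": float(state.cells.C.sum()),
        "boundary_value": state.np_field.dirichlet_value,
        "audit_relative_ext": audit["relative_ext"],
        "audit_relative_int": audit["relative_int"],
    }
    for key, val in state.ledger.items():
        row[f"ledger_{key}"] = val
    traj.rows.append(row)
    if config.save_snapshots:
        traj.snapshots[state.time] = state.cells.snapshot()


def run(config: SimConfig) -> Trajectory:
    """Execute a full simulation, recording the time series at the output cadence."""
    state = initialize(config)
    traj = Trajectory(config=config)
    _record(traj, state, config)
    n_steps = int(round(config.t_end / config.dt_phenotype))
    record_every = max(1, int(round(config.output_cadence / config.dt_phenotype)))
    for k in range(n_steps):
        step(state, config)
        if (k + 1) % record_every == 0 or k == n_steps - 1:
            _record(traj, state, config)
    traj.final_state = state
    return traj
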