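"""Deterministic micro-scenarios for testing and exploration.

Every fixture is pure: the arguments (plus seed) fully determine the output,
and nothing is read from disk. These provide the substrate for closed-form
and oracle checks — a micro-tumor, a single cell in a constant NP bath
(where the saturable-uptake ODE has an exact solution), and a cohort of NPs
planted in one release state (where the cascade reduces to scalar
exponentials).
"""

from __future__ import annotations

import numpy as np

from .cells import OxygenResponse
from .dosing import Schedule
from .engine import (PhenotypeParams, SimConfig, SimState, SubstrateParams,
                     initialize)
from .errors import ConfigurationError
from .microenv import Grid, create_field
from .nano import NPCompartment, NPDesign
from .pharmacodynamics import CYTOTOXIC, PDParams

#: drug response with no phenotype action, for pure-kinetics fixtures
INERT_PD = PDParams(mode=CYTOTOXIC, b0=0.0, bmax=0.0)


def _quiet_phenotype(**kw) -> PhenotypeParams:
    """Phenotype with no division, death, or oxygen consumption."""
    base = dict(
        oxygen=OxygenResponse(b_bar=0.0),
        apoptosis_rate=0.0,
        o2_uptake=0.0,
    )
    base.update(kw)
    return PhenotypeParams(**base)


def toy_tumor(n_cells: int, seed: int = 0) -> tuple[SimState, SimConfig]:
    """A hex-packed micro-tumor of exactly ``n_cells`` viable cells.

    Small 200x200 um domain, abundant oxygen (no consumption), no NPs.
    Cells are kept in order of distance from the domain center.
    """
    if n_cells < 1:
        raise ConfigurationError(f"n_cells must be >= 1, got {n_cells}")
    config = SimConfig(
        grid=Grid(200.0, 200.0, dx=20.0),
        phenotype=PhenotypeParams(o2_uptake=0.0),
        schedule=Schedule(injections=(), reference_dose=0.0),
        dt_diffusion=0.5, dt_mechanics=3.0, dt_phenotype=6.0,
        t_end=0.0, initial_tumor_radius=70.0, seed=seed,
    )
    state = initialize(config)
    if len(state.cells) < n_cells:
        raise ConfigurationError(
            f"cannot fit {n_cells} cells in the toy domain "
            f"(max {len(state.cells)})")
    center = np.array([config.grid.width / 2.0, config.grid.height / 2.0])
    d2 = ((state.cells.pos - center) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")[:n_cells]
    mask = np.zeros(len(state.cells), dtype=bool)
    mask[order] = True
    state.cells.keep(mask)
    state.nE0 = state.np_field.total_number()
    return state, config


def single_cell_bath(
    rho: float,
    design: NPDesign,
    dt_phenotype: float = 0.5,
) -> tuple[SimState, SimConfig]:
    """One cell in a uniform, constantly replenished NP bath.

    Diffusion is disabled (D = 0) and every voxel is held at concentration
    ``rho`` by a full Dirichlet mask refreshed each step, so the local
    concentration a cell sees is constant and the saturable internalization
    ODE has the closed form nI(t) = n* (1 - exp(-rI V rho t / n*)).
    """
    if rho < 0:
        raise ConfigurationError(f"bath concentration must be >= 0, got {rho}")
    config = SimConfig(
        grid=Grid(100.0, 100.0, dx=20.0),
        np_field=SubstrateParams(diffusion=0.0, boundary_value=rho, initial_value=rho),
        phenotype=_quiet_phenotype(),
        design=design,
        pd=INERT_PD,
        schedule=Schedule(injections=((0.0, 1.0),), clearance_rate=0.0,
                          reference_dose=rho),
        dt_diffusion=dt_phenotype, dt_mechanics=dt_phenotype,
        dt_phenotype=dt_phenotype, t_end=0.0, initial_tumor_radius=0.0,
    )
    state = initialize(config)
    # hold the whole bath, not just the edges, at the ambient concentration
    state.np_field = create_field(config.grid, "nanoparticle", 0.0,
                                  design.lambda_extra, rho, rho, dirichlet_all=True)
    state.nE0 = state.np_field.total_number()
    return state, config


def cohort_release(N: float, state_j: int, design: NPDesign) -> NPCompartment:
    """A compartment with N NPs planted in release state ``state_j``, no drug."""
    if not (0 <= state_j < design.m):
        raise ConfigurationError(
            f"state index {state_j} outside [0, {design.m - 1}]")
    comp = NPCompartment.empty(design.m)
    comp.n[state_j] = float(N)
    return comp
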