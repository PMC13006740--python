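"""Finite-volume reaction-diffusion microenvironment.

Scalar substrate fields (oxygen, extracellular nanoparticles) live on a
regular 2D voxel grid and evolve by diffusion, first-order bulk decay,
per-cell uptake sinks, and Dirichlet boundary conditions representing a
vascularized far field. Diffusion/decay use an unconditionally stable
dimension-split backward-Euler scheme (LOD): one implicit tridiagonal solve
per grid line and direction, followed by a pointwise implicit decay update.
Cell uptake is applied after diffusion within each step (sequential
splitting), with an implicit per-voxel update so concentrations stay
non-negative for any step size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .errors import CellOutsideDomainError, ConfigurationError, NumericalError


@dataclass(frozen=True)
class Grid:
    """Regular 2D voxel grid.

    The 2D domain carries a slab thickness (one voxel deep by default) so
    that voxel volumes — and therefore particle numbers — are well defined.
    """

    width: float  # um
    height: float  # um
    dx: float = 20.0  # um, voxel edge length
    slab_thickness: float = 20.0  # um

    def __post_init__(self):
        errs = []
        for name in ("width", "height", "dx", "slab_thickness"):
            if getattr(self, name) <= 0:
                errs.append(f"grid.{name} must be positive, got {getattr(self, name)}")
        if not errs:
            for name, ext in (("width", self.width), ("height", self.height)):
                n = ext / self.dx
                if abs(n - round(n)) > 1e-9:
                    errs.append(f"grid.{name}={ext} is not a multiple of dx={self.dx}")
        if errs:
            raise ConfigurationError("invalid grid", errs)

    @property
    def nx(self) -> int:
        return int(round(self.width / self.dx))

    @property
    def ny(self) -> int:
        return int(round(self.height / self.dx))

    @property
    def voxel_volume(self) -> float:
        """um^3 per voxel (dx^2 x slab thickness)."""
        return self.dx * self.dx * self.slab_thickness

    def voxel_of(self, positions: np.ndarray, ids=None) -> tuple[np.ndarray, np.ndarray]:
        """Map cell centers (N, 2) to voxel indices (ix, iy).

        Raises :class:`CellOutsideDomainError` naming the offending cell.
        """
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        ix = np.floor(pos[:, 0] / self.dx).astype(np.intp)
        iy = np.floor(pos[:, 1] / self.dx).astype(np.intp)
        bad = (ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)
        if np.any(bad):
            k = int(np.argmax(bad))
            cid = ids[k] if ids is not None else k
            raise CellOutsideDomainError(
                f"cell {cid} at position {tuple(pos[k])} is outside the "
                f"{self.width}x{self.height} um domain"
            )
        return ix, iy


@dataclass
class Field:
    """A diffusible substrate on a :class:`Grid`.

    ``values`` is indexed ``[ix, iy]`` and holds concentrations (oxygen in
    mmHg treated as a concentration-like quantity; NPs in NPs/um^3).
    """

    name: str
    grid: Grid
    values: np.ndarray
    D: float  # um^2/min
    decay_rate: float  # 1/min
    dirichlet_mask: np.ndarray
    dirichlet_value: float

    @property
    def dx(self) -> float:
        return self.grid.dx

    @property
    def voxel_volume(self) -> float:
        return self.grid.voxel_volume

    def total_number(self) -> float:
        """Total substrate amount, sum(values) * voxel volume.

        For the NP field this is nE, the total extracellular NP number.
        """
        return float(self.values.sum()) * self.voxel_volume

    def pin_dirichlet(self) -> float:
        """Re-impose the Dirichlet value; returns the amount added (number units)."""
        before = float(self.values[self.dirichlet_mask].sum())
        self.values[self.dirichlet_mask] = self.dirichlet_value
        after = float(self.values[self.dirichlet_mask].sum())
        return (after - before) * self.voxel_volume


def create_field(
    grid: Grid,
    name: str,
    D: float,
    decay_rate: float,
    dirichlet_value: float,
    initial_value: float | None = None,
    dirichlet_all: bool = False,
) -> Field:
    """Create a substrate field with all four domain edges held at a Dirichlet value.

    ``initial_value`` defaults to the Dirichlet value (appropriate for oxygen,
    which is assumed pre-equilibrated); pass 0 for substrates introduced at
    t=0, such as injected NPs. ``dirichlet_all`` pins every voxel — used by
    the uniform-bath fixture to hold a constant ambient concentration.
    """
    errs = []
    if D < 0:
        errs.append(f"diffusion coefficient must be >= 0, got {D}")
    if decay_rate < 0:
        errs.append(f"decay rate must be >= 0, got {decay_rate}")
    if dirichlet_value < 0:
        errs.append(f"dirichlet value must be >= 0, got {dirichlet_value}")
    if errs:
        raise ConfigurationError(f"invalid field '{name}'", errs)

    init = dirichlet_value if initial_value is None else initial_value
    values = np.full((grid.nx, grid.ny), float(init))
    mask = np.zeros((grid.nx, grid.ny), dtype=bool)
    if dirichlet_all:
        mask[:, :] = True
    else:
        mask[0, :] = mask[-1, :] = True
        mask[:, 0] = mask[:, -1] = True
    values[mask] = dirichlet_value
    return Field(name=name, grid=grid, values=values, D=D,
                 decay_rate=decay_rate, dirichlet_mask=mask,
                 dirichlet_value=dirichlet_value)


def _implicit_sweep(values: np.ndarray, mask: np.ndarray, r: float, axis: int) -> None:
    """In-place backward-Euler 1D diffusion solve along ``axis``.

    Each grid line yields a tridiagonal system (Thomas algorithm via
    scipy's banded solver). Dirichlet voxels become identity rows so they
    stay pinned while still exchanging flux with interior neighbors. Lines
    sharing the same mask pattern are solved together as a multi-RHS system.
    """
    v = values if axis == 0 else values.T
    mk = mask if axis == 0 else mask.T
    n = v.shape[0]
    if n == 1:
        return
    # group lines (columns of v) by mask pattern
    patterns, inverse = np.unique(mk.T, axis=0, return_inverse=True)
    for p_idx in range(patterns.shape[0]):
        pat = patterns[p_idx]
        cols = np.nonzero(inverse == p_idx)[0]
        if pat.all():
            continue  # fully pinned line: identity
        ab = np.zeros((3, n))
        n_neighbors = (np.arange(n) > 0).astype(float) + (np.arange(n) < n - 1)
        diag = np.where(pat, 1.0, 1.0 + r * n_neighbors)
        upper = np.where(pat, 0.0, -r)  # coefficient of u[i+1] in row i
        lower = np.where(pat, 0.0, -r)  # coefficient of u[i-1] in row i
        ab[0, 1:] = upper[:-1]
        ab[1, :] = diag
        ab[2, :-1] = lower[1:]
        rhs = v[:, cols]
        v[:, cols] = solve_banded((1, 1), ab, rhs)


def diffuse_decay_step(field: Field, dt: float, ledger: dict | None = None) -> Field:
    """Advance diffusion + bulk decay by one implicit time step (in place).

    Order: re-pin Dirichlet voxels, dimension-split implicit diffusion,
    pointwise implicit decay of non-pinned voxels. If ``ledger`` is given,
    its ``boundary_net`` (net number entering through Dirichlet voxels) and
    ``decayed_ext`` (number destroyed by bulk decay) entries are accumulated.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be positive, got {dt}")
    vol = field.voxel_volume
    pin_delta = field.pin_dirichlet()

    mass0 = field.total_number()
    r = field.D * dt / (field.dx * field.dx)
    if r > 0:
        _implicit_sweep(field.values, field.dirichlet_mask, r, axis=0)
        _implicit_sweep(field.values, field.dirichlet_mask, r, axis=1)
    diff_delta = field.total_number() - mass0

    decayed = 0.0
    if field.decay_rate > 0:
        free = ~field.dirichlet_mask
        before = float(field.values[free].sum())
        field.values[free] /= 1.0 + field.decay_rate * dt
        decayed = (before - float(field.values[free].sum())) * vol

    if not np.all(np.isfinite(field.values)) or np.any(field.values < 0):
        raise NumericalError(
            f"field '{field.name}' produced NaN/negative values in a "
            f"diffusion-decay step (dt={dt}, D={field.D}, decay={field.decay_rate})"
        )

    if ledger is not None:
        ledger["boundary_net"] = ledger.get("boundary_net", 0.0) + pin_delta + diff_delta
        ledger["decayed_ext"] = ledger.get("decayed_ext", 0.0) + decayed
    return field


def steady_state_field(field: Field, sink_rate: np.ndarray | None = None) -> Field:
    """Replace ``field.values`` with the steady reaction-diffusion solution.

    Solves ``D lap(sigma) = (decay + q(x)) sigma`` with the field's Dirichlet
    boundary, where ``q`` is an optional per-voxel sink rate (1/min), e.g.
    summed cell uptake ``U_i V_i / voxel_volume``. Appropriate for substrates
    whose diffusive relaxation is much faster than the simulation step
    (oxygen: D ~ 1e5 um^2/min relaxes across the domain in well under a
    minute), where a transient split scheme at a coarse step would be
    biased. Five-point Laplacian, sparse direct solve.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.linalg import spsolve

    nx, ny = field.values.shape
    N = nx * ny
    q = np.zeros((nx, ny)) if sink_rate is None else np.asarray(sink_rate, dtype=float)
    idx = np.arange(N).reshape(nx, ny)
    k = field.D / (field.dx * field.dx)
    rows, cols, data = [], [], []
    rhs = np.zeros(N)
    mask = field.dirichlet_mask
    for i in range(nx):
        for j in range(ny):
            p = idx[i, j]
            if mask[i, j]:
                rows.append(p); cols.append(p); data.append(1.0)
                rhs[p] = field.dirichlet_value
                continue
            neighbors = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            diag = field.decay_rate + q[i, j]
            for (a, b) in neighbors:
                if 0 <= a < nx and 0 <= b < ny:
                    diag += k
                    rows.append(p); cols.append(idx[a, b]); data.append(-k)
            rows.append(p); cols.append(p); data.append(diag)
    A = csr_matrix((data, (rows, cols)), shape=(N, N))
    sol = spsolve(A, rhs).reshape(nx, ny)
    if not np.all(np.isfinite(sol)) or np.any(sol < -1e-12):
        raise NumericalError(f"steady-state solve failed for field '{field.name}'")
    field.values = np.maximum(sol, 0.0)
    return field


def apply_cell_uptake(
    field: Field,
    positions: np.ndarray,
    uptake_rates: np.ndarray,
    volumes: np.ndarray,
    dt: float,
    ids: np.ndarray | None = None,
) -> np.ndarray:
    """Remove substrate taken up by cells; return per-cell uptaken numbers.

    Each cell i sinks the substrate in the voxel containing its center at
    rate ``U_i V_i`` (um^3/min). The voxel update is implicit,
    ``rho' = rho / (1 + dt * sum_i U_i V_i / voxel_volume)``, and each cell's
    uptaken number is its share ``U_i V_i rho' dt``, so the total removed
    mass equals the total uptaken number by construction.
    """
    U = np.asarray(uptake_rates, dtype=float)
    V = np.asarray(volumes, dtype=float)
    if U.size == 0:
        return np.zeros(0)
    ix, iy = field.grid.voxel_of(positions, ids)
    sink = np.zeros_like(field.values)
    np.add.at(sink, (ix, iy), U * V)
    factor = 1.0 / (1.0 + dt * sink / field.voxel_volume)
    field.values *= factor
    uptaken = U * V * field.values[ix, iy] * dt
    return uptaken
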