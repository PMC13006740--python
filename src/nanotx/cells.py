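"""Off-lattice center-based cell agents.

Cells follow a Live cycle: a viable cell divides with an oxygen-dependent
birth rate (linear ramp between a hypoxic threshold and a saturation
value), dies by apoptosis at a drug-modulated rate, or necroses when
oxygen drops below the necrotic threshold. Mechanics use the standard
center-based polynomial adhesion/repulsion potential in an inertialess
regime (velocity proportional to net force). Death is a simplified
two-phase process: apoptotic cells shrink linearly and are removed after a
fixed duration; necrotic cells persist unchanged until lysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import nano
from .errors import ConfigurationError
from .nano import NPCompartment

VIABLE, APOPTOTIC, NECROTIC = "viable", "apoptotic", "necrotic"


@dataclass(frozen=True)
class OxygenResponse:
    """Oxygen-dependent proliferation and necrosis parameters.

    Defaults follow common multicellular-framework conventions (birth rate
    0.00072 1/min ~ one division per day at full oxygen; proliferation ramp
    5-38 mmHg; necrosis ramp 5 down to 2.5 mmHg). The source study's exact
    values live in an unreproduced supplementary table, so these are
    documented assumptions.
    """

    b_bar: float = 0.00072       # reference proliferation rate, 1/min
    sigma1: float = 5.0          # proliferation threshold, mmHg
    sigma2: float = 38.0         # proliferation saturation, mmHg
    rnec_bar: float = 1.0 / 360.0  # maximum necrosis rate, 1/min
    sigma3: float = 5.0          # necrosis threshold, mmHg
    sigma4: float = 2.5          # necrosis maximum, mmHg

    def __post_init__(self):
        errs = []
        if self.sigma1 >= self.sigma2:
            errs.append(f"sigma1 ({self.sigma1}) must be < sigma2 ({self.sigma2})")
        if self.sigma4 >= self.sigma3:
            errs.append(f"sigma4 ({self.sigma4}) must be < sigma3 ({self.sigma3})")
        if self.b_bar < 0 or self.rnec_bar < 0:
            errs.append("rates must be >= 0")
        if errs:
            raise ConfigurationError("invalid oxygen response", errs)


def proliferation_rate(sigma, p: OxygenResponse):
    """b(sigma) = b_bar * clamp((sigma - sigma1)/(sigma2 - sigma1), 0, 1)."""
    ramp = (np.asarray(sigma, dtype=float) - p.sigma1) / (p.sigma2 - p.sigma1)
    return p.b_bar * np.clip(ramp, 0.0, 1.0)


def necrosis_rate(sigma, p: OxygenResponse):
    """rnec(sigma) = rnec_bar * clamp((sigma3 - sigma)/(sigma3 - sigma4), 0, 1)."""
    ramp = (p.sigma3 - np.asarray(sigma, dtype=float)) / (p.sigma3 - p.sigma4)
    return p.rnec_bar * np.clip(ramp, 0.0, 1.0)


@dataclass(frozen=True)
class MechanicsParams:
    adhesion: float = 0.4        # adhesive force scale
    repulsion: float = 10.0      # repulsive force scale
    adhesion_distance_multiple: float = 1.25  # x (R_i + R_j)
    drag: float = 1.0            # force*min/um; velocity = force/drag
    max_step_fraction: float = 0.25  # displacement cap per mechanics step, x radius

    def __post_init__(self):
        if min(self.adhesion, self.repulsion, self.adhesion_distance_multiple,
               self.drag) < 0 or self.drag == 0:
            raise ConfigurationError("mechanics parameters must be >= 0 with drag > 0")


def radius_from_volume(volume):
    """Sphere-equivalent radius (um) of a cell volume (um^3)."""
    return np.cbrt(3.0 * np.asarray(volume, dtype=float) / (4.0 * math.pi))


@dataclass
class Cell:
    """A single off-lattice cell agent."""

    id: int
    position: np.ndarray          # (2,), um
    volume: float                 # um^3
    state: str = VIABLE
    state_timer: float = 0.0      # minutes remaining in the death process
    b0: float = 0.00072           # base cycle-entry rate, 1/min
    a0: float = 5.3167e-05        # base apoptosis rate, 1/min
    b_current: float = 0.00072    # drug/oxygen-modulated cycle rate
    a_current: float = 5.3167e-05  # drug-modulated apoptosis rate
    necrosis_current: float = 0.0
    np_comp: NPCompartment = dc_field(default_factory=lambda: NPCompartment.empty(10))
    effect: float = 0.0           # pharmacodynamic effect E

    @property
    def radius(self) -> float:
        return float(radius_from_volume(self.volume))

    @property
    def viable(self) -> bool:
        return self.state == VIABLE


def pairwise_velocities(
    positions: np.ndarray,
    radii: np.ndarray,
    mech: MechanicsParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Velocities (um/min) from pairwise adhesion/repulsion forces.

    For a pair at center distance d with combined radius R = R_i + R_j the
    force magnitude along the center line is ``repulsion * (1 - d/R)^2`` for
    d < R (pushing apart) minus ``adhesion * (1 - d/R_A)^2`` for d < R_A =
    adhesion_distance_multiple * R (pulling together), zero beyond; forces
    are pairwise antisymmetric so total momentum vanishes. Coincident
    centers repel along a random unit direction (deterministic under the
    run's seeded generator).
    """
    pos = np.asarray(positions, dtype=float)
    rad = np.asarray(radii, dtype=float)
    n = pos.shape[0]
    if n < 2:
        return np.zeros_like(pos)
    if n > 400:  # sparse neighbor-list path; identical force law
        return _pairwise_velocities_tree(pos, rad, mech, rng)
    diff = pos[:, None, :] - pos[None, :, :]          # (n, n, 2), points from j to i
    dist = np.sqrt((diff * diff).sum(axis=-1))
    R = rad[:, None] + rad[None, :]
    RA = mech.adhesion_distance_multiple * R

    coincident = (dist == 0.0)
    np.fill_diagonal(coincident, False)
    if coincident.any():
        gen = rng if rng is not None else np.random.default_rng(0)
        ii, jj = np.nonzero(np.triu(coincident, 1))
        for a, b in zip(ii, jj):
            theta = gen.uniform(0.0, 2.0 * math.pi)
            u = np.array([math.cos(theta), math.sin(theta)])
            diff[a, b] = 1e-6 * u
            diff[b, a] = -1e-6 * u
        dist = np.sqrt((diff * diff).sum(axis=-1))

    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(dist[..., None] > 0, diff / np.where(dist == 0, 1.0, dist)[..., None], 0.0)
    rep = mech.repulsion * np.clip(1.0 - dist / R, 0.0, None) ** 2
    adh = mech.adhesion * np.clip(1.0 - dist / RA, 0.0, None) ** 2
    mag = np.where(dist < R, rep, 0.0) - np.where(dist < RA, adh, 0.0)
    np.fill_diagonal(mag, 0.0)
    force = (mag[..., None] * unit).sum(axis=1)
    return force / mech.drag


def _pairwise_velocities_tree(pos, rad, mech: MechanicsParams,
                              rng: np.random.Generator | None) -> np.ndarray:
    """Neighbor-list evaluation of the same pairwise force law.

    Interactions have compact support (max adhesion distance), so for large
    populations only pairs within the largest possible interaction radius
    are enumerated (KD-tree); forces are accumulated pairwise
    antisymmetrically.
    """
    from scipy.spatial import cKDTree

    n = pos.shape[0]
    rmax = 2.0 * float(rad.max()) * mech.adhesion_distance_multiple
    pairs = cKDTree(pos).query_pairs(rmax, output_type="ndarray")
    force = np.zeros_like(pos)
    if pairs.size == 0:
        return force
    i, j = pairs[:, 0], pairs[:, 1]
    diff = pos[i] - pos[j]
    dist = np.sqrt((diff * diff).sum(axis=1))
    zero = dist == 0.0
    if zero.any():
        gen = rng if rng is not None else np.random.default_rng(0)
        for k in np.nonzero(zero)[0]:
            theta = gen.uniform(0.0, 2.0 * math.pi)
            diff[k] = 1e-6 * np.array([math.cos(theta), math.sin(theta)])
        dist = np.sqrt((diff * diff).sum(axis=1))
    R = rad[i] + rad[j]
    RA = mech.adhesion_distance_multiple * R
    unit = diff / dist[:, None]
    mag = (mech.repulsion * np.where(dist < R, np.clip(1.0 - dist / R, 0.0, None) ** 2, 0.0)
           - mech.adhesion * np.where(dist < RA, np.clip(1.0 - dist / RA, 0.0, None) ** 2, 0.0))
    fpair = mag[:, None] * unit
    np.add.at(force, i, fpair)
    np.add.at(force, j, -fpair)
    return force / mech.drag


def sample_cell_events(cell: Cell, dt: float, rng: np.random.Generator) -> str:
    """Draw this step's event for a viable cell.

    Independent exponential clocks per step: each of necrosis, apoptosis and
    division fires with probability 1 - exp(-rate*dt), drawn in that fixed
    order with precedence necrose > apoptose > divide.
    """
    rates = (cell.necrosis_current, cell.a_current, cell.b_current)
    if any(r < 0 for r in rates):
        raise ConfigurationError(f"negative event rate for cell {cell.id}: {rates}")
    draws = rng.random(3)
    fired = draws < -np.expm1(-dt * np.asarray(rates))
    if fired[0]:
        return "necrose"
    if fired[1]:
        return "apoptose"
    if fired[2]:
        return "divide"
    return "none"


def divide_cell(
    cell: Cell,
    inheritance_fraction: float,
    rng: np.random.Generator,
    next_id: int,
) -> tuple[Cell, Cell]:
    """Split a viable cell into two daughters of half the volume.

    Daughters are placed at the parent center +/- radius/2 along a uniformly
    random direction; each receives fraction ``inheritance_fraction`` of the
    parent's per-state NP counts via :func:`nano.split_on_division`.
    Returns (daughter1, daughter2); daughter ids are next_id, next_id + 1.
    """
    if not (0.0 <= inheritance_fraction <= 0.5):
        raise ConfigurationError(
            f"inheritance fraction must be in [0, 0.5], got {inheritance_fraction}"
        )
    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])
    offset = 0.5 * cell.radius * u
    comp1, comp2, _lost = nano.split_on_division(cell.np_comp, inheritance_fraction)
    half = cell.volume / 2.0
    kids = []
    for k, (sign, comp) in enumerate(((1.0, comp1), (-1.0, comp2))):
        kids.append(Cell(
            id=next_id + k,
            position=cell.position + sign * offset,
            volume=half,
            b0=cell.b0,
            a0=cell.a0,
            b_current=cell.b_current,
            a_current=cell.a_current,
            np_comp=comp,
        ))
    return kids[0], kids[1]


@dataclass(frozen=True)
class DeathParams:
    apoptosis_duration: float = 516.0   # min (~8.6 h shrink-and-remove)
    necrosis_lysis_time: float = 1440.0  # min (necrotic corpse persists 24 h)


def progress_death(cell: Cell, dt: float, death: DeathParams = DeathParams()) -> bool:
    """Advance a dead cell's timer; returns True when it should be removed.

    Apoptotic cells shrink linearly to zero volume over the remaining timer;
    necrotic cells keep the volume they had at necrosis onset.
    """
    if cell.viable:
        return False
    if cell.state == APOPTOTIC and cell.state_timer > 0:
        shrink = min(1.0, dt / cell.state_timer)
        cell.volume *= max(0.0, 1.0 - shrink)
    cell.state_timer -= dt
    return cell.state_timer <= 0
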