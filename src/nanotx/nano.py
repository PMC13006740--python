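"""Per-cell nanoparticle kinetics.

Internalized NPs form a continuous population distributed over m discrete
drug-release states. State j holds NPs with roughly ``f_j = 1 - j/m`` of
their initial drug load ``C*`` remaining; releasing ``C*/m`` of drug moves a
NP to the next state. Release feeds an intracellular free-drug pool C that
decays at ``lambda_drug``; internalized NPs themselves may decay at
``lambda_NP``. Uptake from the extracellular field is saturable: the uptake
coefficient falls linearly to zero as the cell's NP count approaches the
per-cell saturation count ``n*``, which makes the cell-level ODE and the
tissue-level sink term remove/gain identical NP numbers.

Two long-horizon behaviors are provided for the final release state. In the
default (literal) mode, state m-1 keeps releasing drug at rate ``r_{m-1}``
with no exit, so a cohort's cumulative release grows without bound; with
``exhausted_removal`` enabled, spent NPs exit state m-1 at the same
drained-in-time rate, capping per-NP release at ``C*``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, NumericalError


@dataclass(frozen=True)
class NPDesign:
    """Pharmacokinetic design parameters of the nanoparticle.

    gamma1 may be ``math.inf`` to model instantaneous release: arriving NPs
    deposit their full load C* into the free-drug pool immediately and sit
    in the final (spent) state thereafter.
    """

    r_I: float = 0.0058          # base internalization rate, 1/min
    n_star: float = 800.0        # per-cell saturation NP count
    lambda_NP: float = 9.6270e-05  # intracellular NP decay rate, 1/min
    lambda_extra: float = 0.0    # extracellular NP decay rate, 1/min (applied on the field)
    m: int = 10                  # number of release states
    C_star: float = 100.0        # drug load per NP, umol
    gamma1: float = 0.1          # characteristic release rate, umol/min (inf = immediate)
    lambda_drug: float = 1.4441e-03  # released-drug decay rate, 1/min (8 h half-life)
    exhausted_removal: bool = False  # spent NPs exit the final state
    midpoint_load: bool = False  # use midpoint approximation for per-state load

    def __post_init__(self):
        errs = []
        for name in ("r_I", "lambda_NP", "lambda_extra", "lambda_drug"):
            if getattr(self, name) < 0:
                errs.append(f"np_design.{name} must be >= 0, got {getattr(self, name)}")
        if self.gamma1 < 0:
            errs.append(f"np_design.gamma1 must be >= 0, got {self.gamma1}")
        if self.m < 1:
            errs.append(f"np_design.m must be >= 1, got {self.m}")
        if self.n_star <= 0:
            errs.append(f"np_design.n_star must be > 0, got {self.n_star}")
        if self.C_star <= 0:
            errs.append(f"np_design.C_star must be > 0, got {self.C_star}")
        if errs:
            raise ConfigurationError("invalid NP design", errs)

    @property
    def immediate_release(self) -> bool:
        return math.isinf(self.gamma1)


@dataclass
class NPCompartment:
    """Per-cell NP release-state populations, released drug, and AUC."""

    n: np.ndarray          # (m,) NP population per release state
    C: float = 0.0         # released intracellular drug, umol
    auc: float = 0.0       # accumulated exposure, umol*min/um^3

    @classmethod
    def empty(cls, m: int) -> "NPCompartment":
        return cls(n=np.zeros(int(m)))

    @property
    def total(self) -> float:
        """nI, the total internalized NP count (sum over release states)."""
        return float(self.n.sum())


def uptake_coefficient(nI, d: NPDesign):
    """Saturable uptake coefficient U = rI * (1 - nI/n*), clamped at 0.

    Accepts scalars or arrays.
    """
    return d.r_I * np.clip(1.0 - np.asarray(nI, dtype=float) / d.n_star, 0.0, None)


def release_rate_table(d: NPDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state remaining fractions f, release rates r, transition rates alpha.

    f_j = 1 - j/m; r_j = gamma1 * f_j (with the per-state load C_j ~ f_j C*);
    alpha_j = m r_j / C* for j <= m-2, since moving one state requires
    releasing C*/m of drug at rate r_j. The final state has no exit unless
    ``exhausted_removal`` is set, in which case alpha_{m-1} = m r_{m-1} / C*.
    ``midpoint_load`` switches C_j to the midpoint approximation
    (f_j + f_{j+1})/2 * C*.

    Returns arrays of length m (alpha[m-1] is 0 in the literal mode).
    """
    m = d.m
    j = np.arange(m, dtype=float)
    f = 1.0 - j / m
    if d.immediate_release:
        return f, np.zeros(m), np.zeros(m)
    load_frac = (f + (1.0 - (j + 1.0) / m)) / 2.0 if d.midpoint_load else f
    r = d.gamma1 * load_frac
    alpha = m * r / d.C_star
    if not d.exhausted_removal:
        alpha = alpha.copy()
        alpha[m - 1] = 0.0
    return f, r, alpha


def internalization_exchange(comp: NPCompartment, uptaken: float, d: NPDesign) -> float:
    """Credit NPs removed from the cell's voxel to the compartment.

    ``uptaken`` is the number returned by ``microenv.apply_cell_uptake`` for
    this cell; it is added in full to release state 0 (arrivals carry a full
    load C*), which enforces exact extracellular/intracellular conservation.
    For immediate-release designs the full load goes straight to the
    free-drug pool and the NPs land in the final (spent) state.
    """
    if uptaken < 0 or not np.isfinite(uptaken):
        raise NumericalError(f"invalid uptaken NP number {uptaken}")
    if d.immediate_release:
        comp.n[-1] += uptaken
        comp.C += uptaken * d.C_star
    else:
        comp.n[0] += uptaken
    return uptaken


def cascade_step_arrays(
    n: np.ndarray,
    C: np.ndarray,
    auc: np.ndarray,
    influx: np.ndarray,
    volumes: np.ndarray,
    dt: float,
    d: NPDesign,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """One forward-Euler step of the release cascade for many cells at once.

    ``n`` is (N, m); ``C``, ``auc``, ``influx``, ``volumes`` are (N,).
    Returns updated (n, C, auc) plus a dict of per-step totals for the mass
    ledger: NPs lost to intracellular decay and, with exhausted-removal on,
    NPs exiting the final state.

    The influx gathered over the step is deposited into state 0 at the end
    of the step (or, for immediate-release designs, converted straight into
    free drug), so uptake numbers are conserved exactly.
    """
    _, r, alpha = release_rate_table(d)
    exit_rate = alpha + d.lambda_NP
    if dt * float(exit_rate.max(initial=0.0)) >= 1.0:
        raise NumericalError(
            f"release-cascade stability guard violated: dt*max(alpha_j + lambda_NP) = "
            f"{dt * float(exit_rate.max()):.3g} >= 1; use a smaller phenotype time step"
        )
    outflow = alpha * n  # (N, m), NPs/min moving to the next state (or out, last col)
    dn = -outflow - d.lambda_NP * n
    dn[:, 1:] += outflow[:, :-1]
    n_new = n + dt * dn

    decayed = dt * d.lambda_NP * float(n.sum())
    spent = dt * float(outflow[:, -1].sum()) if d.exhausted_removal else 0.0

    if d.immediate_release:
        C_new = C + influx * d.C_star - dt * d.lambda_drug * C
        n_new[:, -1] += influx
    else:
        C_new = C + dt * (n @ r - d.lambda_drug * C)
        n_new[:, 0] += influx

    auc_new = auc + dt * C_new / volumes
    return n_new, C_new, auc_new, {"decayed_int": decayed, "spent": spent}


def advance_intracellular(
    comp: NPCompartment, influx: float, dt: float, d: NPDesign, volume: float = 2494.0
) -> NPCompartment:
    """One forward-Euler step of a single cell's intracellular kinetics.

    Scalar wrapper over :func:`cascade_step_arrays`; updates ``comp`` in place
    and returns it. ``volume`` (um^3) converts drug amount to the
    concentration accumulated into the AUC.
    """
    n = comp.n[None, :].astype(float)
    C = np.array([comp.C], dtype=float)
    auc = np.array([comp.auc], dtype=float)
    n2, C2, auc2, _ = cascade_step_arrays(
        n, C, auc, np.array([float(influx)]), np.array([float(volume)]), dt, d
    )
    comp.n = n2[0]
    comp.C = float(C2[0])
    comp.auc = float(auc2[0])
    return comp


def split_on_division(comp: NPCompartment, x: float) -> tuple[NPCompartment, NPCompartment, float]:
    """Partition a parent compartment between two daughters at division.

    Each daughter receives fraction ``x`` (0 <= x <= 0.5) of every release
    state — inheritance is independent of release state — and the
    uninherited remainder ``(1 - 2x) * nI`` leaves the system (degraded).
    The released free drug C and the AUC accumulator are split 50/50
    regardless of x, conserving drug mass.
    """
    if not (0.0 <= x <= 0.5):
        raise ConfigurationError(f"inheritance fraction must be in [0, 0.5], got {x}")
    d1 = NPCompartment(n=x * comp.n, C=comp.C / 2.0, auc=comp.auc / 2.0)
    d2 = NPCompartment(n=x * comp.n.copy(), C=comp.C / 2.0, auc=comp.auc / 2.0)
    lost = (1.0 - 2.0 * x) * comp.total
    return d1, d2, lost


def clear_on_death(comp: NPCompartment) -> float:
    """Remove all internalized NPs when a cell dies; returns the cleared count.

    The caller logs the returned number to the mass ledger ("removed by
    death"). The free-drug pool and AUC are discarded with the cell.
    """
    cleared = comp.total
    comp.n[:] = 0.0
    comp.C = 0.0
    return cleared
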