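"""Replicate ensembles, parameter sweeps, and the scaled study protocols.

The source study's simulations (tens of thousands of cells, 30-day
horizons) are summarized here by desk-scale protocols that preserve the
ratio of each process time scale to the simulation horizon: a ~30-50 cell
tumor seed, a 4-day horizon, boundary clearance with a 1-day half-life,
"slow" release chosen so a NP empties over roughly the horizon, and a
second injection at half the horizon. Ensembles follow the replicate
protocol of the study: k seeds (default 10), summaries as mean +/- one
standard deviation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .dosing import Schedule
from .engine import CellPopulation, SimConfig, run
from .errors import ConfigurationError
from .microenv import Grid
from .nano import NPDesign
from .pharmacodynamics import CYTOSTATIC, CYTOTOXIC, PDParams
from .units import days, rate_from_half_life_days

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# replicate ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Mean and +/- 1 SD of each time-series column over replicate seeds."""

    seeds: list
    mean: pd.DataFrame
    sd: pd.DataFrame
    endpoints: np.ndarray          # viable cells at the horizon, per seed
    failures: dict = dc_field(default_factory=dict)

    @property
    def endpoint_mean(self) -> float:
        return float(self.endpoints.mean())

    @property
    def endpoint_sd(self) -> float:
        return float(self.endpoints.std(ddof=0))


def run_replicates(config: SimConfig, n: int, seed0: int = 0) -> EnsembleSummary:
    """Run seeds seed0..seed0+n-1 and summarize as mean +/- 1 SD per time point.

    A failing replicate is recorded (seed -> message) and the ensemble
    continues with the survivors, with a logged warning.
    """
    if n < 1:
        raise ConfigurationError(f"replicate count must be >= 1, got {n}")
    series, endpoints, seeds, failures = [], [], [], {}
    for k in range(n):
        seed = seed0 + k
        try:
            traj = run(replace(config, seed=seed))
        except Exception as exc:  # noqa: BLE001 - per-seed isolation is the contract
            failures[seed] = str(exc)
            logger.warning("replicate seed %d failed: %s", seed, exc)
            continue
        s = traj.series.set_index("time")
        series.append(s)
        endpoints.append(traj.endpoint("viable"))
        seeds.append(seed)
    if not series:
        raise ConfigurationError(f"all {n} replicates failed: {failures}")
    stacked = pd.concat(series, keys=seeds)
    mean = stacked.groupby(level=1).mean()
    sd = stacked.groupby(level=1).std(ddof=0).fillna(0.0)
    return EnsembleSummary(seeds=seeds, mean=mean, sd=sd,
                           endpoints=np.array(endpoints, dtype=float),
                           failures=failures)


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSpec:
    """Cartesian sweep: named dotted-path axes over a base configuration."""

    base: SimConfig
    axes: dict            # e.g. {"design.gamma1": [0.02, 0.1], ...}
    replicates: int = 10
    seed0: int = 0

    def __post_init__(self):
        errs = []
        if self.replicates < 1:
            errs.append(f"replicates must be >= 1, got {self.replicates}")
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            errs.append("axes must be non-empty lists of values")
        if errs:
            raise ConfigurationError("invalid sweep spec", errs)


def with_param(config: SimConfig, path: str, value) -> SimConfig:
    """Return a copy of ``config`` with the dotted-path field replaced."""
    parts = path.split(".")
    def _set(obj, idx):
        if idx == len(parts) - 1:
            return replace(obj, **{parts[idx]: value})
        child = getattr(obj, parts[idx])
        return replace(obj, **{parts[idx]: _set(child, idx + 1)})
    try:
        return _set(config, 0)
    except (AttributeError, TypeError) as exc:
        raise ConfigurationError(f"unknown sweep axis {path!r}: {exc}") from exc


def sweep_grid(spec: SweepSpec) -> pd.DataFrame:
    """Run the full Cartesian grid x replicates; one summary row per grid point.

    The endpoint metric is the viable cell count at the horizon (mean and SD
    over replicates), the quantity the study's heatmaps report.
    """
    names = list(spec.axes)
    rows = []
    for combo in itertools.product(*(spec.axes[k] for k in names)):
        config = spec.base
        for name, value in zip(names, combo):
            config = with_param(config, name, value)
        summary = run_replicates(config, spec.replicates, spec.seed0)
        row = dict(zip(names, combo))
        row.update(viable_mean=summary.endpoint_mean, viable_sd=summary.endpoint_sd,
                   n_replicates=len(summary.seeds))
        rows.append(row)
    return pd.DataFrame(rows)


def release_state_histogram(cells, region: tuple[float, float, float, float]) -> pd.DataFrame:
    """Per-cell release-state matrix for cells inside a rectangular region.

    ``region`` is (x0, x1, y0, y1) in um. Rows are cells (indexed by id),
    columns the m release-state populations n0..n(m-1) — the data behind
    release-state heatmaps. An empty region yields a 0-row frame.
    """
    x0, x1, y0, y1 = region
    if isinstance(cells, CellPopulation):
        ids, pos, n = cells.ids, cells.pos, cells.n
        m = cells.m
    else:
        cell_list = list(cells)
        m = cell_list[0].np_comp.n.size if cell_list else 0
        ids = np.array([c.id for c in cell_list], dtype=np.int64)
        pos = np.array([c.position for c in cell_list], dtype=float).reshape(-1, 2)
        n = np.array([c.np_comp.n for c in cell_list], dtype=float).reshape(-1, m)
    if ids.size:
        inside = (pos[:, 0] >= x0) & (pos[:, 0] <= x1) & (pos[:, 1] >= y0) & (pos[:, 1] <= y1)
    else:
        inside = np.zeros(0, dtype=bool)
    cols = [f"n{j}" for j in range(m)]
    return pd.DataFrame(n[inside], index=pd.Index(ids[inside], name="id"), columns=cols)


# ---------------------------------------------------------------------------
# scaled study protocols
# ---------------------------------------------------------------------------

SCALED_HORIZON_DAYS = 7.0
SCALED_SECOND_INJECTION_DAYS = 3.5   # half the horizon, as in the study (15 of 30 days)
SCALED_CLEARANCE_HALF_LIFE_DAYS = 1.0
SCALED_SLOW_GAMMA1 = 0.03            # umol/min: one NP empties over ~ the horizon
SCALED_RAPID_EXTRACELLULAR_DECAY = rate_from_half_life_days(1.0)


def scaled_config(**overrides) -> SimConfig:
    """Base desk-scale configuration for the qualitative study reproductions."""
    base = dict(
        grid=Grid(280.0, 280.0, dx=20.0),
        design=NPDesign(),
        pd=PDParams(mode=CYTOTOXIC),
        schedule=Schedule(
            injections=((0.0, 1.0),),
            clearance_rate=rate_from_half_life_days(SCALED_CLEARANCE_HALF_LIFE_DAYS),
            reference_dose=0.2),
        inheritance_fraction=0.0,
        dt_diffusion=2.0, dt_mechanics=12.0, dt_phenotype=12.0,
        t_end=days(SCALED_HORIZON_DAYS), output_cadence=720.0,
        initial_tumor_radius=80.0,
    )
    base.update(overrides)
    return SimConfig(**base)


def compare_release_rates(replicates: int = 10, seed0: int = 0) -> dict:
    """Slow release (gamma1 scaled so one NP empties over ~the horizon) vs
    instantaneous release, single dose C at t=0.

    Run with a cytostatic drug over a 5-day horizon: the endpoint then
    integrates drug coverage (time the intracellular concentration holds the
    cycle arrested) without the survivor-dose-concentration feedback that a
    killing drug induces in a desk-scale tumor.
    """
    slow = scaled_config(design=NPDesign(gamma1=SCALED_SLOW_GAMMA1),
                         pd=pd_for_mode(CYTOSTATIC), t_end=days(7.0))
    instant = scaled_config(design=NPDesign(gamma1=math.inf),
                            pd=pd_for_mode(CYTOSTATIC), t_end=days(7.0))
    return {
        "slow_release": run_replicates(slow, replicates, seed0),
        "instant_release": run_replicates(instant, replicates, seed0),
    }


def compare_extracellular_decay(replicates: int = 10, seed0: int = 0) -> dict:
    """No vs rapid extracellular NP decay, with immediate drug release.

    Cytostatic drug, 4-day horizon: extracellular decay cuts delivery, so
    the decaying arm escapes arrest earlier and grows more.
    """
    stable = scaled_config(design=NPDesign(gamma1=math.inf, lambda_extra=0.0),
                           pd=pd_for_mode(CYTOSTATIC), t_end=days(6.0))
    decaying = scaled_config(
        design=NPDesign(gamma1=math.inf,
                        lambda_extra=SCALED_RAPID_EXTRACELLULAR_DECAY),
        pd=pd_for_mode(CYTOSTATIC), t_end=days(6.0))
    return {
        "no_extracellular_decay": run_replicates(stable, replicates, seed0),
        "rapid_extracellular_decay": run_replicates(decaying, replicates, seed0),
    }


def compare_schedules(replicates: int = 10, seed0: int = 0) -> dict:
    """One full dose at t=0 vs two half doses (t=0 and half the horizon).

    Cytostatic drug, immediate release, 5-day horizon with the second half
    dose at 2.5 days: splitting extends boundary supply past the clearance
    of the first bolus, lengthening arrest coverage.
    """
    single = scaled_config(design=NPDesign(gamma1=math.inf),
                           pd=pd_for_mode(CYTOSTATIC), t_end=days(5.0))
    split = replace(single, schedule=replace(
        single.schedule, injections=((0.0, 0.5), (days(2.5), 0.5))))
    return {
        "single_full_dose": run_replicates(single, replicates, seed0),
        "two_half_doses": run_replicates(split, replicates, seed0),
    }


def pd_for_mode(mode: str) -> PDParams:
    """Default pharmacodynamics for a drug class.

    Cytotoxic drugs raise the apoptosis rate toward a maximally induced
    value; cytostatic drugs interpolate the cycle-entry rate down to full
    arrest (bmax = 0).
    """
    if mode == CYTOTOXIC:
        return PDParams(mode=CYTOTOXIC)
    return PDParams(mode=CYTOSTATIC, b0=0.00072, bmax=0.0)


def inheritance_response(mode: str = CYTOTOXIC,
                         fractions=(0.0, 0.25, 0.5),
                         replicates: int = 10, seed0: int = 0) -> dict:
    """Endpoint response to the NP inheritance fraction (single dose C)."""
    out = {}
    for x in fractions:
        cfg = scaled_config(pd=pd_for_mode(mode), inheritance_fraction=x)
        cfg = replace(cfg, inheritance_fraction=x)
        out[x] = run_replicates(cfg, replicates, seed0)
    return out
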