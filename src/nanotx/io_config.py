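"""Configuration documents and run outputs.

Configurations are human-readable YAML with nested blocks (grid,
substrates, cell_phenotype, mechanics, np_design, pd, schedule, engine,
experiment). Every key has a default; unknown keys are rejected and
validation reports every violation at once. Defaults standing in for
values the source study did not print are marked "assumed" in the schema
table below.

Outputs are a time-series CSV, per-time cell snapshot CSVs, dense field
matrices (CSV and an HDF5 container), and a JSON run manifest carrying the
full configuration, its hash, the seed, and package versions — enough to
regenerate every artifact.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cells import DeathParams, MechanicsParams, OxygenResponse
from .dosing import Schedule
from .engine import (PhenotypeParams, SimConfig, SubstrateParams, Trajectory)
from .errors import ConfigurationError
from .microenv import Field, Grid
from .nano import NPDesign
from .pharmacodynamics import CYTOSTATIC, PDParams
from .units import days, rate_from_half_life_days

# schema: block -> key -> (default, "assumed"/"study"/"framework" provenance note)
_SCHEMA = {
    "grid": {
        "width_um": (400.0, "assumed: domain size not printed"),
        "height_um": (400.0, "assumed"),
        "dx_um": (20.0, "framework convention, cell-sized voxels"),
        "slab_thickness_um": (20.0, "assumed: one voxel deep"),
    },
    "substrates": {
        "oxygen": {
            "diffusion_um2_per_min": (1.0e5, "study"),
            "decay_per_min": (0.1, "framework convention"),
            "boundary_mmHg": (38.0, "assumed: framework far-field value"),
            "initial_mmHg": (None, "defaults to boundary value"),
            "cell_uptake_per_min": (10.0, "framework convention"),
        },
        "nanoparticle": {
            "diffusion_um2_per_min": (6.0, "study"),
            "initial_per_um3": (0.0, "no NPs before the first injection"),
        },
    },
    "cell_phenotype": {
        "volume_um3": (2494.0, "framework convention"),
        "birth_rate_per_min": (0.00072, "framework convention; assumed"),
        "o2_proliferation_threshold_mmHg": (5.0, "assumed"),
        "o2_proliferation_saturation_mmHg": (38.0, "assumed"),
        "necrosis_rate_max_per_min": (1.0 / 360.0, "assumed"),
        "o2_necrosis_threshold_mmHg": (5.0, "assumed"),
        "o2_necrosis_max_mmHg": (2.5, "assumed"),
        "apoptosis_rate_per_min": (5.3167e-05, "framework convention; assumed"),
        "apoptosis_duration_min": (516.0, "assumed"),
        "necrosis_lysis_min": (1440.0, "assumed"),
    },
    "mechanics": {
        "adhesion": (0.4, "framework convention"),
        "repulsion": (10.0, "framework convention"),
        "adhesion_distance_multiple": (1.25, "framework convention"),
        "drag": (1.0, "framework convention"),
        "max_step_fraction": (0.25, "package stability choice"),
    },
    "np_design": {
        "internalization_rate_per_min": (0.0058, "study (medium)"),
        "saturation_count": (800.0, "assumed"),
        "intracellular_decay_per_min": (9.6270e-05, "study (5-day half-life)"),
        "extracellular_decay_per_min": (0.0, "study (baseline)"),
        "n_states": (10, "assumed"),
        "drug_load_umol": (100.0, "assumed"),
        "release_rate_umol_per_min": (0.1, "study; 'immediate' or .inf for instant release"),
        "released_drug_decay_per_min": (1.4441e-03, "assumed: 8 h half-life"),
        "exhausted_removal": (False, "package option"),
        "midpoint_load": (False, "package option"),
    },
    "pd": {
        "model": ("hill", "study default"),
        "mode": ("cytotoxic", "study scenario"),
        "emax": (1.0, "assumed"),
        "ec50": (1.2, "assumed"),
        "hill_power": (4.0, "assumed"),
        "max_rate_per_min": (1.0e-03, "assumed: cytotoxic max apoptosis rate"),
    },
    "inheritance_fraction": (0.0, "study baseline; 0..0.5"),
    "schedule": {
        "reference_dose_per_um3": (0.2, "assumed"),
        "clearance_half_life_days": (4.0, "assumed"),
        "injections": ([{"time_days": 0.0, "dose_multiple": 1.0}], "study baseline"),
    },
    "engine": {
        "dt_diffusion_min": (0.01, "framework convention"),
        "dt_mechanics_min": (0.1, "framework convention"),
        "dt_phenotype_min": (6.0, "framework convention"),
        "t_end_min": (43200.0, "study horizon: 30 days"),
        "output_cadence_min": (720.0, "package choice"),
        "initial_tumor_radius_um": (100.0, "assumed"),
        "seed": (0, "replicate protocol"),
        "save_snapshots": (False, "package choice"),
    },
    "experiment": {
        "replicates": (10, "study replicate protocol"),
        "seed0": (0, "package choice"),
    },
}


def _defaults(node):
    if isinstance(node, dict):
        return {k: _defaults(v) for k, v in node.items()}
    return node[0]


def default_document() -> dict:
    """The fully defaulted configuration document."""
    return _defaults(_SCHEMA)


def _merge(schema_node, doc_node, path, errors, out):
    for key, value in doc_node.items():
        if key not in schema_node:
            errors.append(f"unknown key '{path}{key}'")
            continue
        sub = schema_node[key]
        if isinstance(sub, dict) and not isinstance(sub, tuple):
            if not isinstance(value, dict):
                errors.append(f"'{path}{key}' must be a mapping")
                continue
            _merge(sub, value, f"{path}{key}.", errors, out[key])
        else:
            out[key] = value


def document_to_config(doc: dict) -> SimConfig:
    """Validate a configuration document and build a :class:`SimConfig`.

    All violations are collected and reported together.
    """
    errors: list[str] = []
    merged = default_document()
    if doc:
        if not isinstance(doc, dict):
            raise ConfigurationError("configuration document must be a mapping")
        _merge(_SCHEMA, doc, "", errors, merged)
    if errors:
        raise ConfigurationError("invalid configuration", errors)

    def build(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except ConfigurationError as exc:
            errors.extend(exc.errors)
            return None

    g = merged["grid"]
    grid = build(Grid, g["width_um"], g["height_um"], g["dx_um"], g["slab_thickness_um"])

    ox = merged["substrates"]["oxygen"]
    oxygen = SubstrateParams(diffusion=ox["diffusion_um2_per_min"],
                             decay=ox["decay_per_min"],
                             boundary_value=ox["boundary_mmHg"],
                             initial_value=ox["initial_mmHg"])
    npc = merged["substrates"]["nanoparticle"]
    np_field = SubstrateParams(diffusion=npc["diffusion_um2_per_min"],
                               decay=0.0, boundary_value=0.0,
                               initial_value=npc["initial_per_um3"])

    ph = merged["cell_phenotype"]
    mech = merged["mechanics"]
    oxy_resp = build(OxygenResponse,
                     b_bar=ph["birth_rate_per_min"],
                     sigma1=ph["o2_proliferation_threshold_mmHg"],
                     sigma2=ph["o2_proliferation_saturation_mmHg"],
                     rnec_bar=ph["necrosis_rate_max_per_min"],
                     sigma3=ph["o2_necrosis_threshold_mmHg"],
                     sigma4=ph["o2_necrosis_max_mmHg"])
    mechanics = build(MechanicsParams,
                      adhesion=mech["adhesion"], repulsion=mech["repulsion"],
                      adhesion_distance_multiple=mech["adhesion_distance_multiple"],
                      drag=mech["drag"], max_step_fraction=mech["max_step_fraction"])
    phenotype = None
    if oxy_resp is not None and mechanics is not None:
        phenotype = build(PhenotypeParams,
                          cell_volume=ph["volume_um3"], oxygen=oxy_resp,
                          apoptosis_rate=ph["apoptosis_rate_per_min"],
                          o2_uptake=ox["cell_uptake_per_min"],
                          death=DeathParams(ph["apoptosis_duration_min"],
                                            ph["necrosis_lysis_min"]),
                          mechanics=mechanics)

    nd = merged["np_design"]
    gamma1 = nd["release_rate_umol_per_min"]
    if isinstance(gamma1, str):
        if gamma1.lower() in ("immediate", "inf", "infinity"):
            gamma1 = math.inf
        else:
            errors.append(f"np_design.release_rate_umol_per_min: unrecognized value {gamma1!r}")
            gamma1 = math.inf
    design = build(NPDesign,
                   r_I=nd["internalization_rate_per_min"],
                   n_star=nd["saturation_count"],
                   lambda_NP=nd["intracellular_decay_per_min"],
                   lambda_extra=nd["extracellular_decay_per_min"],
                   m=nd["n_states"], C_star=nd["drug_load_umol"],
                   gamma1=gamma1,
                   lambda_drug=nd["released_drug_decay_per_min"],
                   exhausted_removal=nd["exhausted_removal"],
                   midpoint_load=nd["midpoint_load"])

    pdm = merged["pd"]
    mode = pdm["mode"]
    b0 = (ph["birth_rate_per_min"] if mode == CYTOSTATIC
          else ph["apoptosis_rate_per_min"])
    bmax = pdm["max_rate_per_min"]
    if mode == CYTOSTATIC and bmax == _SCHEMA["pd"]["max_rate_per_min"][0]:
        bmax = 0.0  # cytostatic default: full cycle arrest at maximal effect
    pd_params = build(PDParams, model=pdm["model"], mode=mode, Emax=pdm["emax"],
                      EC50=pdm["ec50"], hill_n=pdm["hill_power"], b0=b0, bmax=bmax)

    sc = merged["schedule"]
    injections = []
    for inj in sc["injections"]:
        if not isinstance(inj, dict) or set(inj) - {"time_days", "dose_multiple"}:
            errors.append(f"schedule.injections entries need time_days/dose_multiple, got {inj}")
            continue
        injections.append((days(inj.get("time_days", 0.0)), inj.get("dose_multiple", 1.0)))
    schedule = build(Schedule, injections=tuple(injections),
                     clearance_rate=rate_from_half_life_days(sc["clearance_half_life_days"])
                     if sc["clearance_half_life_days"] > 0 else 0.0,
                     reference_dose=sc["reference_dose_per_um3"])

    eng = merged["engine"]
    config = None
    if all(x is not None for x in (grid, phenotype, design, pd_params, schedule)):
        config = build(SimConfig, grid=grid, oxygen=oxygen, np_field=np_field,
                       phenotype=phenotype, design=design, pd=pd_params,
                       schedule=schedule,
                       inheritance_fraction=merged["inheritance_fraction"],
                       dt_diffusion=eng["dt_diffusion_min"],
                       dt_mechanics=eng["dt_mechanics_min"],
                       dt_phenotype=eng["dt_phenotype_min"],
                       t_end=eng["t_end_min"],
                       output_cadence=eng["output_cadence_min"],
                       initial_tumor_radius=eng["initial_tumor_radius_um"],
                       seed=eng["seed"], save_snapshots=eng["save_snapshots"])
    if errors:
        raise ConfigurationError("invalid configuration", errors)
    return config


def config_to_document(config: SimConfig, experiment: dict | None = None) -> dict:
    """Serialize a :class:`SimConfig` back into a configuration document."""
    inj = [{"time_days": t / days(1.0), "dose_multiple": d}
           for t, d in config.schedule.injections]
    hl = (math.log(2.0) / config.schedule.clearance_rate / days(1.0)
          if config.schedule.clearance_rate > 0 else 0.0)
    doc = {
        "grid": {"width_um": config.grid.width, "height_um": config.grid.height,
                 "dx_um": config.grid.dx, "slab_thickness_um": config.grid.slab_thickness},
        "substrates": {
            "oxygen": {"diffusion_um2_per_min": config.oxygen.diffusion,
                       "decay_per_min": config.oxygen.decay,
                       "boundary_mmHg": config.oxygen.boundary_value,
                       "initial_mmHg": config.oxygen.initial_value,
                       "cell_uptake_per_min": config.phenotype.o2_uptake},
            "nanoparticle": {"diffusion_um2_per_min": config.np_field.diffusion,
                             "initial_per_um3": config.np_field.initial_value or 0.0},
        },
        "cell_phenotype": {
            "volume_um3": config.phenotype.cell_volume,
            "birth_rate_per_min": config.phenotype.oxygen.b_bar,
            "o2_proliferation_threshold_mmHg": config.phenotype.oxygen.sigma1,
            "o2_proliferation_saturation_mmHg": config.phenotype.oxygen.sigma2,
            "necrosis_rate_max_per_min": config.phenotype.oxygen.rnec_bar,
            "o2_necrosis_threshold_mmHg": config.phenotype.oxygen.sigma3,
            "o2_necrosis_max_mmHg": config.phenotype.oxygen.sigma4,
            "apoptosis_rate_per_min": config.phenotype.apoptosis_rate,
            "apoptosis_duration_min": config.phenotype.death.apoptosis_duration,
            "necrosis_lysis_min": config.phenotype.death.necrosis_lysis_time,
        },
        "mechanics": {
            "adhesion": config.phenotype.mechanics.adhesion,
            "repulsion": config.phenotype.mechanics.repulsion,
            "adhesion_distance_multiple": config.phenotype.mechanics.adhesion_distance_multiple,
            "drag": config.phenotype.mechanics.drag,
            "max_step_fraction": config.phenotype.mechanics.max_step_fraction,
        },
        "np_design": {
            "internalization_rate_per_min": config.design.r_I,
            "saturation_count": config.design.n_star,
            "intracellular_decay_per_min": config.design.lambda_NP,
            "extracellular_decay_per_min": config.design.lambda_extra,
            "n_states": config.design.m,
            "drug_load_umol": config.design.C_star,
            "release_rate_umol_per_min": ("immediate" if config.design.immediate_release
                                          else config.design.gamma1),
            "released_drug_decay_per_min": config.design.lambda_drug,
            "exhausted_removal": config.design.exhausted_removal,
            "midpoint_load": config.design.midpoint_load,
        },
        "pd": {"model": config.pd.model, "mode": config.pd.mode,
               "emax": config.pd.Emax, "ec50": config.pd.EC50,
               "hill_power": config.pd.hill_n,
               "max_rate_per_min": config.pd.bmax},
        "inheritance_fraction": config.inheritance_fraction,
        "schedule": {"reference_dose_per_um3": config.schedule.reference_dose,
                     "clearance_half_life_days": hl,
                     "injections": inj},
        "engine": {"dt_diffusion_min": config.dt_diffusion,
                   "dt_mechanics_min": config.dt_mechanics,
                   "dt_phenotype_min": config.dt_phenotype,
                   "t_end_min": config.t_end,
                   "output_cadence_min": config.output_cadence,
                   "initial_tumor_radius_um": config.initial_tumor_radius,
                   "seed": config.seed,
                   "save_snapshots": config.save_snapshots},
        "experiment": experiment or _defaults(_SCHEMA["experiment"]),
    }
    return doc


def load_config(path) -> SimConfig:
    """Load and validate a YAML configuration file."""
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"configuration file not found: {p}")
    with open(p) as fh:
        doc = yaml.safe_load(fh) or {}
    return document_to_config(doc)


def write_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_document(config), fh, sort_keys=True)


def config_hash(config: SimConfig) -> str:
    """SHA-256 of the canonical (sorted-key) serialized configuration."""
    doc = config_to_document(config)
    canon = json.dumps(doc, sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()


def write_field_matrix(field: Field, path) -> None:
    """Dense field matrix as CSV (rows = x index, columns = y index)."""
    np.savetxt(path, field.values, delimiter=",")


def write_outputs(trajectory: Trajectory, out_dir) -> list[Path]:
    """Write the run artifacts; returns the list of files created.

    time_series.csv, cells_t<minutes>.csv snapshot tables, final field
    matrices (CSV + fields.h5), and manifest.json. An empty trajectory
    yields the manifest only.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    config = trajectory.config
    manifest = {
        "config": config_to_document(config),
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "package": {"name": "nanotx", "version": __version__},
        "versions": {"numpy": np.__version__},
        "n_time_points": len(trajectory.rows),
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    written.append(mpath)

    if trajectory.rows:
        spath = out / "time_series.csv"
        trajectory.series.to_csv(spath, index=False)
        written.append(spath)

    for t, snap in trajectory.snapshots.items():
        cpath = out / f"cells_t{int(round(t)):07d}.csv"
        snap.to_csv(cpath)
        written.append(cpath)

    if trajectory.final_state is not None:
        import h5py

        state = trajectory.final_state
        for f in (state.oxygen, state.np_field):
            fpath = out / f"field_{f.name}_final.csv"
            write_field_matrix(f, fpath)
            written.append(fpath)
        hpath = out / "fields.h5"
        with h5py.File(hpath, "w") as h5:
            for f in (state.oxygen, state.np_field):
                grp = h5.create_group(f.name)
                grp.create_dataset("values", data=f.values)
                grp.attrs.update({"dx_um": f.dx, "time_min": state.time,
                                  "diffusion_um2_per_min": f.D,
                                  "decay_per_min": f.decay_rate,
                                  "dirichlet_value": f.dirichlet_value})
        written.append(hpath)
    return written
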