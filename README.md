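# nanotx

Agent-based simulation of anticancer therapy with drug-loaded
nanoparticles (NPs), for computational oncology and nanomedicine design
studies. A 2D tumor of off-lattice cell agents sits in a diffusive
microenvironment; NPs enter from a vascularized boundary, are endocytosed
by a saturable law, release their drug through an age-structured state
cascade inside each cell, and can be inherited by daughter cells at
division. Intracellular drug feeds back on the cell phenotype — slowing
cycling (cytostatic) or driving apoptosis (cytotoxic) — so NP design
parameters and dosing schedules can be screened against tumor growth.

## Model core

Extracellular transport (per substrate, Dirichlet far-field boundary):

    ∂ρ/∂t = D ∇²ρ − λρ − Σᵢ Uᵢ Vᵢ δ(x − xᵢ) ρ

Saturable internalization for cell *i*, matched exactly to the tissue
sink (so NP number is conserved between books):

    dnI/dt = rI (1 − nI/n*) Vᵢ ρ(xᵢ),   Uᵢ = rI (1 − nI/n*)

Drug release: internalized NPs occupy m states with remaining load
fraction f_j = 1 − j/m, release at r_j = γ₁ f_j, and advance at
α_j = m r_j / C*; released drug C obeys dC/dt = Σ r_j n_j − λ_drug C.
At division each daughter inherits x ∈ [0, 0.5] of every state's
population. Effect is a Hill response E = Emax cⁿ/(EC50ⁿ + cⁿ) on
c = C/V (or on AUC), and the targeted rate is b₀ + (b_max − b₀) E/Emax.
Oxygen-dependent proliferation and necrosis use clamped linear ramps.

See `docs/methods.md` for the full model description, parameter
provenance (published values vs. documented assumptions), numerics, and
the design of the desk-scale experiments.

## Worked example

Run a one-week treated tumor and an untreated control from Python:

```python
from dataclasses import replace
from nanotx import experiments as ex
from nanotx.engine import run

treated = run(replace(ex.scaled_config(), seed=2))          # cytotoxic, 1 dose
print(treated.series[["time", "viable", "apoptotic", "nI_total"]].tail(3))
```

which prints (seed 2):

```
       time  viable  apoptotic  nI_total
12   8640.0      31          7  4.558860
13   9360.0      31          8  1.123855
14  10080.0      48          4  0.875272
```

An ~85-cell tumor treated with one NP dose is held to 48 viable cells at
day 7 (`time` is in minutes); `nI_total` is the internalized NP pool,
which has almost emptied by then — released, decayed, and no longer
replenished once the boundary supply cleared — so the late rise in viable
cells is regrowth after drug coverage ends. The same run from the shell:

```bash
nanotx run --config my_config.yaml --seed 2 --out out/
nanotx replicates --config my_config.yaml --n 10 --out out_ens/
nanotx sweep --spec sweep.yaml --out out_sweep/
```

`nanotx run` writes `time_series.csv`, per-time cell snapshots, final
field matrices (CSV + HDF5), and a `manifest.json` (config, hash, seed,
versions) from which every artifact can be regenerated. Configuration is
YAML with full validation; every default that stands in for an unpublished
value is marked "assumed" in the schema (`nanotx.io_config._SCHEMA`).

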