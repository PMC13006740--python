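# Methods

`nanotx` simulates anticancer therapy with drug-loaded nanoparticles (NPs)
in a 2D tumor, coupling four scales: a diffusive microenvironment, cell
agents, per-cell NP populations, and pharmacodynamic phenotype control.
This note records the model equations as implemented, the parameters that
matter, the numerical choices, and what the desk-scale experiments do and
do not demonstrate.

## Model

### Microenvironment

Oxygen (mmHg) and extracellular NPs (NPs/µm³) are scalar fields on a
regular voxel grid (default dx = 20 µm, one cell-sized voxel per site; a
slab thickness of 20 µm converts areal voxels to volumes so NP numbers are
well defined). Each field obeys

    ∂ρ/∂t = D ∇²ρ − λ ρ − Σ_i U_i V_i δ(x − x_i) ρ,

with Dirichlet values on all four domain edges representing a vascular
far field. Oxygen: D = 1e5 µm²/min, bulk decay 0.1/min, boundary 38 mmHg.
NPs: D = 6 µm²/min, bulk decay = the extracellular NP decay rate (0 by
default), boundary set by the dosing schedule. No bulk source/secretion
terms are used.

The transient solver is dimension-split backward Euler (locally
one-dimensional): one implicit tridiagonal solve per grid line and
direction, then pointwise implicit decay, then per-voxel implicit cell
uptake, all unconditionally stable and positivity-preserving. Because the
oxygen field relaxes across the whole domain in well under a minute while
the engine's scaled runs use multi-minute steps, the engine by default
solves oxygen **quasi-steadily**: each phenotype step solves
D∇²σ = (λ + q(x))σ with q the per-voxel summed cell uptake, by a sparse
direct solve. A transient sequential-splitting update at coarse steps
systematically underestimates σ (the split consumption step can empty a
voxel regardless of how much diffusion would resupply it); the
quasi-steady solve removes that bias. The transient path remains available
(`oxygen_quasi_steady=False`) and is the one exercised by the solver
tests; NPs, which diffuse slowly and are depleted weakly per step, always
use the transient path.

### Cells

Cells are off-lattice circles with volume 2494 µm³ (radius ≈ 8.4 µm),
following a Live cycle: a viable cell divides with rate

    b(σ) = b̄ · clamp((σ − σ1)/(σ2 − σ1), 0, 1),

dies by apoptosis with a drug-modulated rate, and necroses with rate

    r_nec(σ) = r̄_nec · clamp((σ3 − σ)/(σ3 − σ4), 0, 1).

Defaults: b̄ = 7.2e-4/min (one division per day at full oxygen), σ1 = 5,
σ2 = 38, r̄_nec = 1/360 per min, σ3 = 5, σ4 = 2.5 mmHg, base apoptosis
5.3167e-5/min. Events are drawn per phenotype step with probability
1 − exp(−rate·dt) from independent per-step clocks, with precedence
necrosis > apoptosis > division. Death is a simplified two-phase process:
apoptotic cells shrink linearly and are removed after 8.6 h; necrotic
corpses persist unchanged for 24 h, then lyse and are removed.

Mechanics are the standard center-based polynomial potential: repulsion
∝ (1 − d/R)² inside the combined radius R, adhesion ∝ (1 − d/R_A)² out to
R_A = 1.25·R, inertialess (velocity = net force / drag). Forces are
pairwise antisymmetric, so momentum is conserved exactly. Two
implementation details: for populations above 400 cells the same force law
is evaluated over a KD-tree neighbor list instead of the dense pair
matrix, and each mechanics substep caps a cell's displacement at 25% of
its radius so the coarser mechanics steps used in scaled runs cannot
overshoot through a neighbor.

### Nanoparticle kinetics

Uptake is saturable: a cell holding nI NPs takes up at coefficient
U = rI (1 − nI/n*), clamped at zero. The tissue sink and the cell gain are
matched number-for-number — the NP amount removed from a cell's voxel in a
step is credited in full to its release-state-0 population — so
extracellular and intracellular books balance exactly.

Internalized NPs occupy m release states (default m = 10). State j holds
fraction f_j = 1 − j/m of the initial per-NP load C*, releases drug at
r_j = γ1·f_j (γ1 = βC* the characteristic release rate), and advances to
state j+1 at α_j = m·r_j/C* (the rate at which C*/m of drug is drained at
r_j). The final state has no exit in the default (literal) mode, so it
keeps releasing at r_{m−1} indefinitely; an optional `exhausted_removal`
mode gives it the analogous exit rate, removing spent NPs and capping
per-NP release at C*. The per-state load uses C_j ≈ f_j·C*; a midpoint
variant ((f_j + f_{j+1})/2 · C*) is available but off by default.
Released drug accumulates in a well-mixed cytoplasmic pool C (µmol) that
decays at λ_drug; internalized NPs decay at λ_NP. All populations are
continuous (deterministic rate equations), advanced by forward Euler at
the phenotype step with a stability guard dt·max(α_j + λ_NP) < 1. The
"immediate release" design (γ1 = ∞) short-circuits the cascade: arriving
NPs deposit C* directly into the pool and sit in the final state.

At division each daughter receives fraction x ∈ [0, 0.5] of every release
state (inheritance is independent of release state); the uninherited
remainder (1 − 2x)·nI leaves the system and is ledgered. The released pool
C and the AUC accumulator split 50/50 regardless of x, conserving drug.
When a cell dies its NPs are cleared and ledgered. The engine maintains a
global NP ledger (boundary flux, extracellular and intracellular decay,
internalization, death clearance, division loss, spent removal) whose
extracellular and intracellular identities close to ≲1e-12 relative in
tests; the acceptance suite enforces 1e-6.

### Pharmacodynamics

Drug effect is E = Emax·cⁿ/(EC50ⁿ + cⁿ) on the intracellular
concentration c = C/V (model "hill") or on AUC = ∫c dt accumulated by
rectangle rule at the phenotype step (model "auc"). The targeted rate
interpolates linearly: b_phen = b0 + (bmax − b0)·E/Emax. Cytostatic drugs
target cycle entry with bmax = 0 (full arrest at maximal effect); the
oxygen-modulated birth rate is used as the base so hypoxia and drug
compose. Cytotoxic drugs target apoptosis with bmax = 1e-3/min by default.

### Dosing

An injection at time t_k with dose multiple d_k raises the NP boundary
value by d_k·ρ_ref·exp(−k_cl(t − t_k)); contributions superpose. Systemic
clearance is therefore implicit in the time-varying Dirichlet boundary.
Default clearance half-life 4 days (so the large majority of circulating
NPs are gone by day 12 of a 30-day run); reference dose ρ_ref = 0.2
NPs/µm³.

### Engine

Multi-rate stepping: diffusion substeps (default 0.01 min) nest inside
mechanics substeps (0.1 min) inside phenotype steps (6 min); each dt must
divide the next. One seeded generator per run is consumed in a fixed
order (per phenotype step: an (N, 3) block of event uniforms, then one
angle per division), so a seed fully determines a trajectory. Replicate
ensembles run seeds seed0..seed0+n−1 and report mean ± 1 SD.

## Parameter provenance

Values printed in the source study and used directly: the NP and oxygen
diffusion coefficients; the internalization-rate levels 0.0029 / 0.0058 /
0.0116 per min; the intracellular decay levels 3.2090e-5 / 9.6270e-5 /
4.8135e-4 per min (15/5/1-day half-lives); the extracellular decay level
1.6045e-5 per min (30 days); the release-rate levels γ1 = 0.02 and 0.1
µmol/min plus "immediate"; the inheritance range 0–50%; the 10-replicate
mean ± SD protocol. Everything else (domain size, C*, n*, EC50, Emax,
Hill power, λ_drug, oxygen thresholds, dose magnitude, clearance rate) is
an assumption chosen once as a self-consistent set and marked "assumed" in
the configuration schema. In these units a cell saturated at n* = 800 NPs
of load C* = 100 µmol reaches c ≈ 8–30 µmol/µm³ of released drug against
EC50 = 1.2, i.e. the dose–response is exercised across its full range.

## Desk-scale experiment design

The study-scale simulations (tens of thousands of cells, 30-day horizon)
are summarized by desk-scale protocols on a 280×280 µm domain seeded with
an ~85-cell tumor disk (radius 80 µm), time steps 2/12/12 min, chosen to
preserve the *ratios* of process time scales to the horizon rather than
absolute durations: boundary clearance half-life 1 day against 6–7-day
horizons (supply window ≪ horizon, as with clearance-by-day-12 against 30
days); "slow" release γ1 = 0.03 µmol/min so one NP drains over
approximately the horizon; "rapid" extracellular decay with a 1-day
half-life (≈ horizon-scale, as the 30-day half-life is to the 30-day
study); a second injection at half the horizon (as day 15 is to 30).

The release-rate, extracellular-decay and dose-fractionation comparisons
use the **cytostatic** drug class, and the inheritance comparison uses the
**cytotoxic** class. This split is deliberate. At desk scale a strongly
killing drug introduces an artifact absent at study scale: as cells die,
the surviving few share the whole extracellular NP reservoir, their
per-cell dose rises, and the arm spirals to extinction — erasing exactly
the regrowth-after-coverage dynamics that the orderings probe. With a
cytostatic drug the population is not culled, per-cell delivery stays
comparable across arms, and the endpoint (viable cells at the horizon)
cleanly integrates how long each arm held the cycle arrested. The
inheritance experiment is inherently about killing while dividing, so it
stays cytotoxic with a moderate maximal apoptosis rate (1e-3/min, ≈1.4× 
the maximal birth rate) that kills without flash-extinction.

Calibration of the assumed pharmacodynamic numbers (EC50 = 1.2, Hill
power 4) was done against *delivery measurements*: drug-inert static-tumor
runs recorded the per-cell concentration trajectory of each arm
(instantaneous release peaks near 10 and falls below ~1 by day 4; slow
release sustains 1.2–3.8 through day 6), and EC50 was placed between the
arms' mid-horizon levels with a slope steep enough to convert the
crossover into a coverage difference. The ordering outcomes themselves
were not used to fit parameters.

What the desk-scale results do show: the model reproduces, with the
correct sign and clear margins under the 10-seed protocol, the study's
qualitative findings — slower release contains at least as well as
instantaneous release at matched dose; rapid extracellular decay degrades
treatment; two half doses beat one full dose; cytotoxic efficacy improves
monotonically with NP inheritance. What they do not show: the study's
absolute cell counts (its figure heatmaps), behavior of
tens-of-thousands-cell tumors where penetration depth and interior
hypoxia are far stronger, or any claim about real tumors — every
biological parameter here is either a published model constant or a
documented assumption.

## Numerical choices and degenerate inputs

- Diffusion: LOD backward Euler, first-order splitting accepted; Dirichlet
  voxels are identity rows so pinned values exchange flux with the
  interior; uniform fields with matching boundary values are exact steady
  states. NaN or negative concentrations raise immediately with step
  context.
- Uptake: per-voxel implicit update ρ′ = ρ/(1 + dt·ΣU_iV_i/V_voxel);
  per-cell shares sum exactly to the removed mass.
- Cascade: forward Euler; influx is deposited at the end of the step so
  uptake numbers are conserved exactly; guarded by
  dt·max(α_j + λ_NP) < 1 with an error message recommending a smaller
  phenotype step.
- Events: at most one event per cell per phenotype step, precedence
  necrosis > apoptosis > division; the O(rate·dt) bias this induces is
  well below Monte-Carlo noise at the default steps.
- Degenerate inputs: a zero-radius tumor seeds exactly one centered cell;
  m = 1 gives a single release state with no transitions; empty regions
  yield empty (not error) histograms; t_end = 0 emits only the initial
  state; coincident cell centers repel along a seeded random direction.

## Known limitations

- NPs in transit release no drug; arrivals always carry the full load C*.
- The literal final-state behavior releases unboundedly over long
  horizons; use `exhausted_removal` when cumulative-release accounting
  matters.
- Spent NPs (immediate-release mode) and aged NPs still count against the
  saturation limit n*, throttling further uptake — a real consequence of
  counting NPs rather than drug.
- No contact inhibition of growth: dense tumors overlap rather than stall,
  as in the underlying Live-cycle model.
- 2D only; no vasculature, receptor binding, endosomal trafficking,
  immune compartment, or motility.
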