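# Model and methods

## The hybrid automaton

`scaffoldsim` simulates a population of cells cultured inside a porous
polymeric scaffold as a hybrid discrete/continuous cellular automaton. The
scaffold is a cube of `n_layers`³ voxels (default 10 layers of 1 mm for a
1 cm side). The discrete layer is an integer lattice holding at most one
*virtual cell* per voxel; the continuous layer consists of three per-voxel
real fields — glucose (g/L), oxygen (g/L) and the Young's modulus of the
extracellular matrix (kPa) — plus a well-mixed external medium reservoir.

Each iteration (default 1 h) advances four phases in fixed order:

1. **Transport.** Glucose and oxygen obey Fick's second law,
   ∂C/∂t = D ΔC, integrated by explicit central differences (FTCS). The
   protocol step is internally divided into sub-steps at *half* the 3D
   stability bound h²/(6D); running exactly at the bound leaves the odd-even
   lattice mode undamped and visibly distorts sharply peaked fields.
   Glucose exchanges with a finite well-mixed reservoir (the culture medium)
   whose solute mass is debited by the net boundary influx; oxygen sees a
   Dirichlet boundary at the incubator saturation value, since gas exchange
   keeps the medium oxygenated. Diffusivities are free-solution values
   (glucose 2.412 mm²/h, oxygen 10.8 mm²/h — a 4.5-fold ratio) because the
   scaffold material does not measurably hinder small-solute transport.
2. **Media change.** Every 24 h the glucose field is reset to the fresh-media
   concentration at every voxel and the reservoir is refilled. Oxygen is
   untouched.
3. **Environmental rules.** Every cell executes all environmental rules for
   its type: it consumes glucose and oxygen from its voxel (floored at zero)
   and, if proliferant, stiffens the matrix in its neighbourhood (below).
4. **Behavioural rules.** Every cell, visited in a freshly shuffled order,
   evaluates the probabilities of all behavioural rules matching its type
   and draws at most one (residual probability = no change). Duplication
   places a daughter on a uniformly drawn empty face-neighbour (no-op when
   the neighbourhood is full); migration relocates the cell the same way;
   state changes are in place; degradation frees a dead cell's voxel.

Runs are bitwise reproducible from (configuration, seed): a single
`numpy` generator drives seeding, visit order and rule draws, and replicate
seeds derive deterministically from `(base_seed, k)` via `SeedSequence`.

## The population scale factor

Bench experiments seed millions of cells; the lattice holds ~10³. The
occupancy scale factor preserves the initially occupied volume fraction:
with the average eukaryotic cell volume 4.2×10⁻⁶ mm³,

    occupied_fraction = n_vitro · v_cell / V_scaffold
    n_virtual = round(occupied_fraction · capacity),  min 1
    aggregation_ratio = n_vitro / n_virtual

For 5 M cells in a 1 cm³ scaffold: fraction 0.021, 21 virtual cells, each
aggregating ≈2.38×10⁵ biological cells. Per-cell uptakes (glucose
16.7×10⁻¹² g/cell/h, oxygen 2.93×10⁻¹⁵ g/cell/h) are multiplied by the
aggregation ratio, so the virtual population consumes what the real one
would. One consequence drives a numerical choice documented below: a virtual
cell's aggregated biological cells fill roughly one voxel, so its hourly
uptake is of the same order as its voxel's entire glucose content.

**Sensed concentrations.** Behavioural probabilities read the nutrient
fields *after* diffusion and media change but *before* the current
iteration's uptake impulses. The post-uptake value reflects the operator
splitting (a voxel transiently emptied by its own occupant's hourly
impulse), not the concentration the cells grew in; sensing it made every
cell — rich region or poor — see near-zero glucose, erasing all spatial
structure. The sensed field carries the persistent, regional depletion
signal instead.

**Stiffening geometry.** A proliferant cell exerts its full cross-linking
effect every hour: one share `lox·U_YM·dt` to each in-bounds face-neighbour
and the remaining shares to its own voxel (at a scaffold face the enzyme
output acts on the matrix that exists). Under uniform occupancy every voxel
then expects the same deposit; the naive "one share per in-bounds
neighbour" rule systematically under-stiffens corners purely by geometry,
which contradicts the observed edge-stiffened phenotype.

## The rule grammar

Rules are single statements `id: A -> B [+ C], D`. `A`, `B`, `C` are
declared cell-type names (or `empty`); `D` is either an environment tag
(`environment(Glc|O2|YM)`, amount `U` = the reference uptake) or an
arithmetic probability expression (`+ - * /`, parentheses, `min`, `max`,
`exp`) over the normalized context variables

| variable | meaning |
| --- | --- |
| `TIME` | iteration / total iterations |
| `TD`   | death iteration / total (0 while alive) |
| `Glc`  | local glucose / fresh-media concentration |
| `O2`   | local oxygen / incubator concentration |
| `C_<type>` | count of that type / lattice capacity |
| `AGE`  | iterations since birth / current iteration (0 at iteration 0) |
| `TLD`  | iterations since last division / current iteration (0 at iteration 0) |
| `YM`   | local stiffness / initial scaffold stiffness |

plus the configuration's named parameters (`a`…`e`, `s`, …). Values are
clamped to [0, 1] after evaluation so calibration sweeps cannot crash; when
the probabilities of one cell's candidate rules sum above 1 they are
renormalized and a warning is logged, since that signals a mis-calibrated
rule set.

## The shipped cell-line models

Three cell states are declared: proliferant (P), quiescent (Q), dead (D).
The default rules are

    dup:     P -> P + P,  a * min(Glc, O2) / 24
    rest:    P -> Q,      d * (1 - min(Glc, O2))
    wake:    Q -> P,      b * Glc
    die:     Q -> D,      c * (1 - min(Glc, O2))
    move:    P -> empty + P,  e
    clear:   D -> empty,  a / 24
    + reference uptake rules for P and Q (glucose, oxygen; quiescent cells
      consume a fraction s of the proliferant amounts) and the stiffening
      rule for P.

The `/24` converts the daily-scale multiplicative coefficients of the two
cell lines to hourly probabilities. Death is reached through quiescence
(proliferant cells first arrest, arrested cells starve), matching the state
structure of the biology: scarcity of whichever resource is locally
limiting drives arrest and death, abundance drives proliferation and
re-awakening.

Line-specific coefficients (dimensionless):

| parameter | MCF7 | MDA-MB-231 | origin |
| --- | --- | --- | --- |
| a (duplication/degradation) | 0.38 | 0.44 | bench-derived |
| b (quiescent→proliferant)   | 0.005 | 0.02 | optimized |
| c (death)                   | 0.8  | 0.1  | calibrated here |
| d (proliferant→quiescent)   | 0.8  | 0.185 | calibrated here |
| e (migration)               | 0.008 | 0.01 | bench-derived |
| lox (matrix cross-linking)  | 3×10⁻⁶ | 3×10⁻³ | bench-derived (1000× LOX expression difference) |

Shared environmental parameters: U_Glu = 16.7×10⁻¹² g/cell/h,
U_O2 = 2.93×10⁻¹⁵ g/cell/h (reference uptakes), s = 0.5 (quiescent
consumption scale), U_YM = 32.2 kPa/h per virtual cell (stiffening
increment). The protocol is 10 days of hourly iterations with daily media
changes in high-glucose DMEM (4.5 g/L), medium volume 17 mL, incubator
oxygen 7.2×10⁻³ g/L, initial scaffold stiffness 47 kPa.

### Calibration of the free parameters

c, d, U_YM, s and the medium volume have no published values; they were
calibrated once, jointly, against the bench-characterized stiffness
phenotype of the MDA-MB-231 cultures — final mean stiffness ≈57.9 kPa
(from 46.9±5.3 kPa), an external shell ≈10% stiffer than the core, a ≈15-fold
gap between pooled-voxel and per-scaffold stiffness dispersion, and ≤5%
intrascaffold spread when seeding ≤1.25 M cells — and, for MCF7, against the
flat stiffness and declining density of that line. The calibrated regime is
one of sustained nutrient limitation: the population grows to the carrying
capacity set by the daily glucose budget, the core starves between media
changes and depopulates, and the shells next to the medium keep
proliferating and stiffening. The medium volume acts as the supply knob
(it pins the boundary concentration through the day), d sets how much of the
population idles in quiescence, and c how quickly the starving core is
cleared. MCF7's much larger c, d reproduce its arrested phenotype (early
growth followed by decline toward the initial density — the calibration
does not reach the full decline to half seen on the bench) and its
inability to remodel the matrix follows from the 1000-fold lower `lox`
without further tuning.

## Analysis layer

* **Cell density**: living (P+Q) count over the initial population; the
  validation error against bench series is the per-point absolute
  percentage error |silico − vitro| / vitro at matched days.
* **Radial profiles**: voxels are binned by the Manhattan distance of their
  centers from the scaffold center (1 mm left-closed bins) — the natural
  radial coordinate of a cubic lattice, which is not radially symmetric.
  Fields are normalized to their initial average, per-voxel cell densities
  to the bin's share of the initial population. The *core* is the region
  within 6 mm of the center and the *external shell* the outer third of the
  Manhattan radius (≥9.5 mm, the five outermost 1 mm shells): single 1 mm
  shells at the lattice extremes hold as few as 8 voxels and are
  sampling-noise dominated even across 50 replicates. The edge-core
  contrast is 100·(outer − core)/core on the replicate-mean day-10 field,
  and the intrascaffold spread is 100·(max − min)/min over the coarse
  core / middle / external band means.
* **Stiffness statistics**: `pooled` mode treats every voxel of every
  replicate as an observation (the dispersion of the full Young's-modulus
  distribution); `per_scaffold` summarizes one mean per replicate, the way
  bench compression testing summarizes one modulus per scaffold. Their
  dispersion ratio measures how much intra-scaffold heterogeneity
  per-scaffold averaging hides. 95% CIs are normal-approximation
  (mean ± 1.96·SE) by default, percentile bootstrap on request; group
  comparisons use the Kruskal–Wallis test since the voxel distributions are
  far from normal.
* **Sensitivity**: parameters vary uniformly within ±40% of their reference
  values, behavioural (a–e) and environmental (U_Glu, U_O2, U_YM, s) groups
  separately. First-order and total Sobol indices come from a Saltelli
  design (A/B from one scrambled Sobol' sequence, estimators of Saltelli
  2010 and Jansen 1999, bootstrap CIs); a zero-variance output reports
  undefined (NaN) indices. Per-row model outputs average a small number of
  replicate seeds (default 3) derived from the row, taming run-to-run noise
  while staying reproducible.

## What the simulation does and does not emulate

The virtual population reproduces the *mechanistic skeleton* of a 3D
culture: nutrient-limited growth, the diurnal glucose sawtooth between
media changes, spatial differentiation between a starving core and a
well-fed rim, matrix stiffening by proliferant cells, and the dominance of
intra- over inter-scaffold variability. It does not emulate seeding
inefficiency, cell–cell signalling, matrix degradation, sub-voxel cell
positions, or the late global density decline seen in bench time courses
(the calibrated population plateaus at its carrying capacity instead);
absolute cell densities are therefore indicative only, and passing tests
constrain the stiffness phenotype much more tightly than the density one.

## Numerical choices and degenerate inputs

* Probabilities clamp to [0, 1]; uptake floors fields at 0; Σp > 1
  renormalizes with a warning.
* AGE and TLD are defined as 0 at iteration 0; TD is 0 for living cells.
* `n_virtual` rounds half-away-from-zero with a floor of 1; seeding a full
  lattice is allowed, overfull requests raise.
* Blocked duplication/migration is a silent no-op (the cell neither dies
  nor queues).
* A zero-hour protocol returns only the initial state; an empty scaffold at
  media concentration is a fixed point of the iteration.
* Problem sizes in the test suite and the acceptance script follow the
  default study design (10³ lattice, 240 iterations, 50 replicates per
  condition; 30 paired seeds for the cell-line comparison; Sobol oracles at
  n_base = 1024).

## Known limitations

* The exact functional forms of the transition probabilities are a design
  choice of this package; only the multiplicative coefficients of the two
  cell lines and the reference uptakes are bench-anchored. The forms were
  chosen for mechanistic plausibility and calibrated as a set.
* FTCS is first order in time; halving the sub-step changes fields at the
  2×10⁻³ level, so byte-level cross-implementation parity of field values
  should not be expected (seeded cell dynamics are exactly reproducible).
* One virtual cell per voxel caps the population at the lattice capacity;
  crowding effects near that cap are lattice artifacts.
* The Manhattan shells are coarse (the innermost holds 8 voxels), so
  shell-resolved statistics on single runs are noisy; replicate averaging
  is essential.
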