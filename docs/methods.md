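# Model and methods

`melanosim` simulates vascularized melanoma growth as a hybrid
discrete–continuum system: melanoma cells and endothelial tip cells are
discrete agents on a 3D cubic lattice, while glucose, VEGF, and two drugs
(doxorubicin "Dox", sunitinib) are continuum fields on the same lattice.
This note records the model, its unit conventions, the deliberately open
design points and how we resolved them, and what the synthetic study
conditions do and do not show.

## Lattice and fields

The extracellular matrix is a cube of voxels (default 100×100×100) with
10 µm spacing — one voxel per melanoma-cell radius, so at most one agent
occupies a voxel (tumor and vessel occupancy are mutually exclusive).
Each field evolves synchronously once per 2 h step:

    f'(p) = [ f(p)·(1−λ) + (λ/6)·Σ_{q∈VN(p)} f(q) + sources − sinks ]·(1−decay)

over the six face neighbors (Von Neumann stencil), followed by a clamp at
zero, since the additive sinks (glucose uptake 0.28/step per live tumor
cell, VEGF consumption 1/3 per vessel voxel) can overdraw a voxel.
Boundaries are reflecting: a missing neighbor contributes the center's own
value, which conserves mass exactly when sources, sinks and decay are off
(verified to 1e−9 relative over 100 steps in the tests, alongside a bitwise
comparison against a naive triple-loop reference).

Per-field roles:

| field      | source                               | sink                         | decay |
|------------|--------------------------------------|------------------------------|-------|
| glucose    | vessel voxels, `Pe_g` per step       | live tumor voxels, `U_g`     | `D_g` = 0.2 |
| VEGF       | *starving* tumor voxels, `Se_v` = 0.6| vessel voxels, `Pe_v` = 1/3  | `D_v` = 0.2 |
| Dox / sunitinib | vessel voxels, `Pe_d`·dose while dosing | whole-field fraction `U_d` = 0.2 | — |

VEGF is secreted only by starving cells (local glucose below the survival
threshold), not by every tumor cell: secretion is the hypoxia signal that
recruits vasculature, and tying it to starvation closes the
demand–supply feedback loop that stabilizes the model (see below).

## Unit conventions (dimensionless transport)

The published constants mix units: diffusivities in cm²/s, permeabilities
in cm/s, uptake in mmol/h, while the update rule needs dimensionless
per-step quantities with λ ∈ [0, 1].  An explicit-scheme mapping of the
physical diffusivities at Δt = 2 h, Δx = 10 µm would exceed the stability
bound by ~10⁴, so we treat transport as *dimensionless mixing*:

* **λ (mixing fractions)** — proportional to the physical diffusivities,
  scaled so the largest (glucose, 6.7e−7 cm²/s) maps to 0.90:
  λ_g = 0.90, λ_d = 0.70, λ_v = 0.39.  A physical diffusivity supplied in a
  config is mapped by `0.90 / 6.7e−7` and capped at 1.  An optional
  `n_sub` repeats the pure mixing sub-step for users who want faster
  transport per step.
* **Pe (vessel source/sink magnitudes)** — physical permeabilities in cm/s
  map by `Pe / 3e−5`, so the base glucose and drug permeabilities
  (3e−5 cm/s) become 1.0 per vessel voxel per step and the VEGF
  permeability (1e−5 cm/s) becomes 1/3.  The scale is chosen so that one
  vessel voxel sustains a few adjacent tumor cells (uptake 0.28/step),
  which reproduces the intended biology: tumor cells survive only near
  vasculature once the initial nutrient load has decayed.
* **U_g, Se_v, decay rates, U_d** — already dimensionless per-step values
  and used as printed (0.28, 0.6, 0.2, 0.2).

A consequence worth stating plainly: with per-step decay 0.2 and mixing
≤ 0.9, the steady-state decay length of every field is about one voxel.
Fields are therefore *short-ranged*; no agent can sense a source more than
a few voxels away.  All long-range organization in the model is emergent
(vessels find the tumor by exploring while the initial VEGF load lasts,
then chemotax locally).

## Melanoma cell rules (per 2 h step)

Order per cell: starvation bookkeeping → apoptosis draw → cell-cycle
progression/entry → division or migration → quiescence.

* **Starvation** — local glucose (mean over site + VN neighbors) below the
  survival threshold (default 1.0 against an initial mean of 4) starts a
  starvation clock and switches VEGF secretion on.  The threshold is not a
  published constant; 1.0 makes cells initially fed and starving within
  ~30 h as the ambient load decays, producing a necrotic core by ~80 h.
* **Apoptosis** — probability `1 − exp(−(λ0 + λ1 [+ λs])·Δt)` with λ0 = 0,
  the cytotoxic term `λ1 = w1·A_Dox/(1 + w2·A_glu)` (glucose protects), and
  a starvation death rate λs = 0.05 h⁻¹ applied once the starvation clock
  exceeds 24 h.  The baseline death rate of zero plus visibly dying
  untreated tumors requires *some* starvation death channel; both knobs
  are config-exposed.
* **Proliferation** — cycle entry with probability `1 − exp(−λ2·Δt)`,
  λ2 = 1/32 h⁻¹; division completes after one cell-cycle length
  (32 h = 1/λ2) and places the daughter on a chosen free Moore site.
  A cell that completes its cycle with no free site waits, quiescent, and
  retries; cycling cells do not migrate.
* **Site choice** (shared by division and migration) — if some free Moore
  neighbor's glucose exceeds the 27-voxel box mean by more than three
  population standard deviations, one such "abnormally rich" site is taken
  uniformly at random.  Otherwise candidates are ranked
  `R = V·A_glu/(1 + w3·A_Dox)` with the crowding preference `V` (1 for 0–2
  occupied Moore neighbors, 1/4 for 3–4, 1/6 for 5–6, 1/n for 7–26;
  occupied counts include vessels and dead cells), normalized to
  proportions, and selected by a uniform die over the cumulative intervals
  (roulette wheel).  All-zero ranks mean "no viable candidate" and are
  treated as no space.
* **Quiescence** — reversible; the full decision tree is re-run every
  step, so a quiescent cell resumes activity as soon as a neighbor frees.
* **Death is absorbing** — apoptotic cells occupy their voxel permanently
  (the grey necrotic core), but neither consume, secrete, nor count as
  alive.

## Angiogenesis

Vasculature is a parent-linked forest: 16 root tip cells start on the
domain boundary (round-robin over the six faces at seeded-uniform
positions) and only tips act; the trail of stalk nodes they leave is
permanent, acts as the vessel source/sink in every field, and is inert
otherwise — sunitinib can prune growing tips but never removes
established vessel.

Per tip and step: (1) quiescence if the local VEGF average is at or below
a threshold; (2) an apoptosis draw with
`λ4 = w4·A_suni/(1 + w5·A_VEGF)` (VEGF protects; on death the parent
becomes the tip again); (3) extension toward a >3σ VEGF outlier direction
if one exists; (4) otherwise branching into two distinct roulette-selected
free Moore sites (ranked `R = V·A_VEGF/(1 + w6·A_suni)`) with probability
0.1 per step, else a single extension.  Two-site branching uses paired
dice redrawn while they land in the same interval (capped at 100 retries,
then the two heaviest candidates).

Two of these numbers are ours, and they matter:

* **VEGF quiescence threshold, 2e−3.**  A literal "no VEGF = exactly
  zero" test never fires under multiplicative decay (the field underflows
  only after thousands of steps), so every tip would wander and branch
  forever, filling the lattice with vessel.  A small positive threshold
  restores the intended feedback: tips rest once the tumor's demand
  signal fades.  The value sets how long the *initial* VEGF load keeps
  tips exploring (≈28 steps from a mean of 1 at decay 0.2) and how far
  the tumor's plume reaches (≈6 voxels); both must cover about half the
  domain width for the vasculature to find the tumor, which bounds the
  usable lattice size at roughly 50³ for boundary-seeded tips.
* **Branch probability, 0.1 per step.**  Mathematically the >3σ extension
  rule cannot fire on a full 7-sample neighborhood (max deviation from a
  sample mean is σ√(n−1) ≈ 2.45σ), so without a gate every tip would
  branch every step and the tip population would double per step.  A
  0.1/step gate yields sparse tree-like microvasculature whose node count
  grows steadily alongside the tumor.

With these two values the untreated system reproduces the expected
trajectory on a scaled lattice (28³): early growth on the initial nutrient
load, a deep growth dip at 50–150 h as the ambient glucose decays, vessel
ingrowth toward the starving (VEGF-secreting) core, and vascularized
regrowth to thousands of cells by 400 h, with the vessel count increasing
monotonically throughout.

## Scheduling and reproducibility

Each step: fields in fixed order (glucose, VEGF, Dox, sunitinib; all
reading the previous step's occupancy) → melanoma cells in uniformly
shuffled order → tips in uniformly shuffled order.  Agents created during
a step first act in the next one.  All randomness flows from one seeded
`numpy.random.Generator`; identical (config, seed) gives byte-identical
output files.  An occupancy audit (agent lists vs masks vs voxel
exclusivity) runs after every step and raises with step context.

## Drug-combination study

12 dose multipliers per drug from 0.1× to 10× in geometric progression
(ratio 100^(1/11) ≈ 1.52) plus a zero-dose control; constant infusion via
the vessel source term for the whole run (no pharmacokinetics — the
minimal reading of "dose").  Efficacy is the melanoma death rate relative
to control, `E = 1 − alive/alive_control`, on *living* (active +
quiescent) cells; E50 means fewer than half the initial 100 cells remain
alive and E100 means total elimination.  Isoboles are staircase contours
on the grid (the lowest sunitinib level attaining the effect per Dox
level).  Loewe classification compares contour points against the chord
`x/A + y/B = 1`; because the staircase and the endpoints A, B each
overshoot the true iso-effective dose by up to one grid cell, all
quantized doses are debiased by the geometric half cell √r and half a
cell is kept as the additivity tolerance.  When one single-agent endpoint
is never attained on the grid (in this model sunitinib alone cannot
eliminate the tumor, because established stalk vessel keeps delivering
glucose), the highest tested dose serves as a lower bound; a contour
below the *bounded* chord is then still conclusively synergistic, and
anything else is reported as not classifiable.

## Sensitivity screen

One-at-a-time: each transport/kinetic parameter takes 10 evenly spaced
values over its literature range (physical ranges mapped by the unit
conventions above; mixing fractions capped at 1), all other parameters at
base, both drugs dosed at 1× (the screen probes the treated system — the
drug-transport parameters are inert otherwise).  Several replicate
simulations per value use a *paired* seed set (the same replicate seeds
reused across values), replicates are pooled by their mean per value, and
Spearman's rank correlation (scipy, average ranks, t-approximation
p-value) is computed against the final total melanoma, active melanoma,
and endothelial counts.

## Problem sizes used by the shipped studies

The packaged acceptance script and the end-to-end tests run the model on
scaled-down domains chosen as the smallest sizes on which the vasculature
reliably reaches the tumor and the screen's correlations stabilize:
28³ voxels (280 µm)³ and the full 400 h horizon for the sensitivity
screen (10 values × 10 replicates per parameter), the growth dynamics,
and the dose matrix (6×6 levels × 5 replicates); 24³ for the determinism
checks.  The 16 boundary tips and 100 seed cells of the base model are
kept as-is.  On substantially larger domains the boundary-seeded
vasculature cannot reach the tumor before it starves (see the VEGF
threshold discussion above), so the lattice is a model scale, not a
free resolution knob.

## What the synthetic conditions do and do not show

All inputs are generated by the initialization rules; there is no external
data.  Passing tests therefore demonstrate internal consistency of the
model — the rule set, the feedbacks, and the analyses built on them — not
agreement with any particular tumor.  Known limitations: no vessel
regression beyond tip pruning (established vasculature is immortal, which
caps what an anti-angiogenic can achieve alone), no anastomosis, blood
flow, oxygen, or pressure; short-ranged fields make results
lattice-size-dependent (boundary-seeded vasculature cannot find a tumor
more than ~25 voxels away); the cell cycle is a fixed-length timer; drug
action is a memoryless rate with no pharmacokinetics; and the 2 h step
ties the agent and field clocks together.
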