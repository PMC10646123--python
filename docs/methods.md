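# Methods

## Model and assumptions

The simulator couples six reaction–diffusion equations for fungal mycelium
(F), fungal self-inhibitor (I), phytotoxins (T), phytostimulants (S), plant
biomass (P) and soil nutrients (N), all as areal densities in g dm⁻². The
governing assumptions:

- **Self-inhibition drives ring formation.** A fraction `c_I` of the fungal
  mortality flux (quadratic self-thinning plus inhibitor-induced death)
  accumulates as a soil-borne inhibitor that both caps fungal growth
  (factor `1 − s_I·I`) and adds mortality (`s_F·F·I`). This, and nothing
  else in the model, converts a growing disk into an expanding annulus:
  with `s_I = s_F = 0` the colony fills in behind the front.
- **Hydrophobicity.** The mat excludes water from the soil below it: the
  fraction available to plants and to leaching is
  `W̄ = 1 − b^(a·F − W)` (zero once `a·F ≥ W`), so `W̄ ∈ [0, 1)` whenever
  `b > 1` (enforced at construction). Fungal growth itself uses the raw
  input `W` — mycelium forages water at the mat border — through a
  Michaelis–Menten factor `W/(W + k_W)`.
- **Phytotoxicity.** Toxins are produced in proportion to fungal density
  and kill plants at rate `s_T·T·P`.
- **Stimulation.** Phytostimulants (produced at `c_S·F`, decaying at `k_S`)
  and nutrients mineralized from plant mortality both raise the plant
  carrying capacity `W̄·(q_P + S + N)`.
- **Only F and P move.** The dissolved compounds are treated as laterally
  immobile on the dm scale; fungus and plants spread with equal, small
  diffusivities (0.01 dm² d⁻¹).

The two suppression hypotheses are toggled purely through `a` and `s_T`:
hydrophobicity-only (`a = 2`, `s_T = 0`), phytotoxicity-only (`a = 0`,
`s_T ∈ [0.9, 1.3]`, default 1.1) and combined (`a = 2`, `s_T ∈ [0.1, 0.5]`,
default 0.3). All other defaults are the published table values. For the
two ranged parameters we default to the reference-simulation values
`W = 1`, `g_F = 0.05` (the showcase parameter set) rather than interval
midpoints; every panel preset sweeps them across their full ranges anyway.

### Fungus-free baseline

Nutrient release is proportional to `g_P·P²·W̄`, which is positive at any
vegetated steady state, so undisturbed soil does **not** settle at the bare
logistic level `W̄₀·q_P` (`W̄₀ = 1 − b^(−W)`). The true far-field
equilibrium is the coupled root

    P* = W̄₀·(q_P + N(P*)),   N(P) = g_N·g_P·P² / (u_N·g_P·P + l_N),

solved by Brent bracketing (`fungus_free_equilibrium`); at defaults
P* ≈ 1.079, about 22% above W̄₀·q_P = 0.889, and the simulation converges
to it to 10⁻⁶ by day 2000. With `g_N = 0` the classical logistic level is
recovered exactly. The biometric baseline validates simulated far fields
against this closed form within 1%.

## Numerics

- **Grid.** `dx = 1` dm (one cell = the 0.1 m field resolution); zero-flux
  Neumann boundaries by ghost-cell mirroring, so diffusion conserves domain
  totals to round-off. 1D transect mode (400 cells, inoculum at one end) is
  the workhorse — far from the centre the annulus is locally a planar
  front; the Cartesian (not polar) 1D Laplacian neglects the curvature term
  ~D/r, which at r ≥ 10 dm is two orders below the reaction rates. The 2D
  mode (400 × 400, central inoculum) reproduces the full radial setup; a
  central inoculum stays exactly 90°-rotation symmetric.
- **Time stepping.** Explicit (forward Euler) updates with a one-day
  reporting step, each integrated in 5 sub-steps of 0.2 d
  (`SimConfig.substeps`). The sub-stepping matters: the plant logistic rate
  `g_P·P*` reaches ≈ 2.3 d⁻¹ in the wettest soils (W = 2), beyond the
  stability bound of a one-day explicit update, which produces a spurious
  patchy period-2 wake; at 0.2 d every reaction term is well inside the
  monotone regime across the published parameter ranges. The diffusion
  number `D·dt/dx²` = 0.002 is checked against the 2D bound 0.25 before
  every run. Fields are clipped at zero after each sub-step (explicit
  overshoot of mortality terms touches only values within one step of
  extinction). Evaluation is frozen-coefficient: W̄ and all six rates are
  computed from the same start-of-step snapshot, making the update
  order-independent.
- **Refinement behaviour.** Halving the sub-step or the grid spacing leaves
  the 2000-day transect unchanged within a few percent *after aligning for
  the sub-cell front displacement* (`aligned_profile_difference`: optimal
  cubic-spline shift). Raw pointwise comparison is dominated by the O(dt)
  dependence of the wave speed — 0.4% per halving of dt, i.e. a ~0.35 dm
  front offset after 2000 d — and is not a meaningful convergence measure
  for a travelling wave. Shape-constancy checks are run at dx = 0.5: at
  dx = 1 the 4-cell-wide mycelium band under-samples the profile and grid
  phase masks comparisons below ~8% even for a perfectly constant wave.
- **Front tracking.** Front position = outermost cell with
  `F ≥ 10⁻³ g dm⁻²` (10% of the inoculum; configurable). Front speed is the
  least-squares slope of position vs time over a post-transient window,
  with an error if the front is within 2 cells of the boundary.

## Biometrics and classification

From one radial transect (x increasing outward, front travelling toward
larger x) with far-field baseline P∞:

- FB = max F; PS = max(P − P∞); PI = max(P∞ − P); BZ = dx × number of cells
  with P < P∞(1 − ε); RW = distance between the F and P global maxima,
  undefined (NaN) when no stimulated band exists. Peak positions for RW are
  refined to sub-cell resolution by 3-point parabolic interpolation: on the
  1-dm grid the raw argmax quantizes RW (it can sit at exactly 2 dm across
  an entire ±50% sweep and mask a real monotone response). Ties in the
  global maxima break toward the front.
- Bands are maximal runs where P deviates from P∞ by more than ε·P∞,
  tagged ahead/behind by the position of their extremum relative to the F
  peak. The significance tolerance defaults to ε = 0.02 (2% of baseline)
  and is reported with every record; "dead" vegetation means
  P < P∞(1 − ε), not P = 0, since the model rarely reaches exact zero.
- Decision tree: no bands → type 3; stimulation only → 2; inhibition only
  → 1.2; inhibition with stimulation only behind the front → 1; stimulation
  also ahead → 1.1, upgraded to 1.3 when the ahead peak exceeds every
  behind peak (an ahead-only stimulated belt with inhibition is labelled
  1.1, the nearest class). The label is invariant to rescaling x and to
  appending undisturbed far field.
- The baseline is the mean P over the trailing 10% of the transect, which
  must lie wholly beyond the front — otherwise no clean far field exists
  and the record is refused rather than silently computed.

## Sensitivity analysis

One parameter at a time is scaled by {0.5, 0.75, 1, 1.25, 1.5} (five levels
across the ±50% envelope — enough points for a meaningful Pearson r while
keeping a full 24-parameter sweep at ~120 simulations); each level is a
full 1D run plus biometrics. Per (metric, parameter) pair the analysis
reports the Pearson sign (|r| < 0.1 reported as 0 — on five levels such an
r is numerical noise from an insensitive parameter) and the fold change
(max − min)/min over the defined levels, NaN-guarded when a level is
undefined or the minimum is zero. Failed runs are flagged, never dropped.
The heatmap matrix is the fold change normalized by each metric column's
maximum, so intensities compare only within a column.

Two published heatmap signs are not reproduced by this implementation, for
identifiable reasons rather than noise (both are monotone across all five
levels under every measurement variant tried):

- **PS vs k_S** comes out negative: faster phytostimulant degradation
  strictly lowers S (its only source is `c_S·F`, its only sink `k_S·S`) and
  with it the stimulated-band peak. A positive response is not derivable
  from the S and P equations.
- **BZ vs u_N** comes out (weakly) negative: nutrient uptake moves the
  far-field baseline strongly (P* from 1.27 to 1.02 across the sweep), and
  a bare zone measured relative to the run's own baseline is dominated by
  that shift rather than by the slower regrowth behind the front. A fixed,
  baseline-independent reference would flip the sign, but would make the
  bare zone of a wet run incomparable with a dry one.

## What the simulations do and do not show

All headline behaviours are generated, not fitted: ring (annulus) growth
requires `s_I > 0`; the front is a travelling wave (position linear in time
with R² > 0.999, shape constant in the co-moving frame); the combined panel
(s_T × W × g_F) produces exactly the five classical types {1, 1.1, 1.2, 2,
3}; the phytotoxicity-only panel never produces 1.1 or 1.3 (stimulation
ahead of the front needs the hydrophobic water-exclusion pathway); and the
type-1.3 showcase (`c_S = 0.8`, `k_S = 1`, `g_N = 0.2`, `W = 2`,
`g_F = 0.05`) yields a stronger flourishing belt ahead of the dead belt.
The type-1.3 preset uses the combined mode: at desk-scale resolution the
hydrophobicity-only variant needs dt ≤ 0.1 d for the ahead/behind peak
ordering to converge (both variants converge to 1.3 under refinement).

The hydrophobicity-only panel yields four types, not five: under the 2%
band tolerance, type 3 ("no evident effect") is empty anywhere in
W × g_F ∈ [0.1, 2] × [0.01, 0.05] — wherever hydrophobic suppression falls
below 2% of baseline, phytostimulant-driven stimulation still exceeds 2%
(closest approach: PS = 2.5%, PI = 1.9% at W = 1, g_F = 0.01, in 1D and
2D alike). A looser, field-realistic "evident effect" threshold (~5%) would
admit type 3 in a narrow window around W ≈ 1–1.2 at the lowest fungal
growth rates; the 2% default is kept because it is the documented
classifier tolerance used everywhere else.

These are simulations of an idealized homogeneous soil with constant water
input, no seasonality, no slope (hence rings, never arcs), and plants as a
single community variable. Passing tests therefore demonstrate internal
consistency of the mechanism — self-inhibition → annulus; mechanism mix →
band typology — not field prediction: real transects carry heterogeneity,
anisotropy and phenology that this generator deliberately omits.
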