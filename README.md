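# fairyring

Process-based simulation of fairy rings: the circular fungal colonies that
sweep through grassland soils for decades, visible above ground as belts of
dead and/or luxuriant vegetation. The package is for ecologists and
modellers who want to (i) reproduce the annular — rather than disk-like —
growth of the mycelium from a point inoculum, (ii) test which plant–fungus
interaction mechanisms generate which of the six classical ring types, and
(iii) relate model parameters to field-measurable ring biometrics.

## The model

Six densities (g dm⁻²) evolve on a 1D transect or 2D lattice: fungal
mycelium *F*, fungal self-inhibitor *I*, phytotoxins *T*, phytostimulants
*S*, plant biomass *P* and soil nutrients *N*. Only *F* and *P* diffuse
(D_F = D_P = 0.01 dm² d⁻¹); the dissolved compounds stay where they are
produced:

    ∂F/∂t = g_F·F·(1 − s_I·I)·W/(W + k_W) − d_F·F² − s_F·F·I + D_F∇²F
    ∂I/∂t = c_I·(d_F·F² + s_F·F·I) − k_I·I − l_I·I·W̄
    ∂T/∂t = c_T·F − k_T·T − l_T·T·W̄
    ∂S/∂t = c_S·F − k_S·S
    ∂P/∂t = g_P·P·[W̄·(q_P + S + N) − P] − s_T·T·P + D_P∇²P
    ∂N/∂t = g_N·(g_P·P² + s_T·P·T)·W̄ − u_N·g_P·W̄·P·N − l_N·N·W̄

with the hydrophobicity law for the water fraction available to plants,

    W̄ = 1 − b^(a·F − W)  if a·F < W,   else 0.

The fungus poisons its own past: a fraction c_I of dead mycelium
accumulates as a self-inhibitor (the putative agent is extracellular
self-DNA) that suppresses regrowth, which hollows the colony into an
expanding annulus — a travelling wave. Two suppression mechanisms act on
plants: *hydrophobicity* (the mycelial mat blocks water infiltration;
switch `a`) and *phytotoxicity* (toxin-induced mortality; switch `s_T`).
Two stimulation mechanisms act alongside: phytostimulants ("fairy
chemicals") and nutrients mineralized from dead plants.

From a simulated transect the package extracts five biometrics — fungal
biomass peak (FB), plant stimulation (PS), plant inhibition (PI), bare-zone
width (BZ) and ring width (RW) — and classifies the vegetation-band pattern
into ring types 1, 1.1, 1.2, 1.3, 2 or 3. A one-at-a-time ±50% sweep yields
the Pearson-sign / fold-change sensitivity heatmap of every biometric to
every parameter.

## Worked example

```python
from fairyring import SimConfig, Transect, run, compute_biometrics, classify
from fairyring.engine import front_speed

traj = run(SimConfig(hypothesis_mode="combined"))   # 400-cell transect, 2000 d
x, F, P = traj.final_transect()
rec = compute_biometrics(Transect(x, F, P))
print("type:", classify(rec).value)
for k, v in rec.as_dict().items():
    print(f"{k} = {v:.4g}")
fit = front_speed(traj, (1000, 1800))
print(f"front speed = {fit.speed:.4g} dm/d  (R^2 = {fit.r_squared:.4f})")
```

prints

```
type: 1
FB = 0.7623
PS = 0.1058
PI = 1.043
BZ = 4
RW = 2.352
baseline = 1.079
front speed = 0.04288 dm/d  (R^2 = 0.9992)
```

a type-1 ring: the mycelium front peaks at 0.76 g dm⁻², kills the grass
above it almost completely (PI ≈ the 1.08 g dm⁻² undisturbed baseline, a
4-dm bare belt), and drags a flourishing belt (+0.11 g dm⁻²) 2.4 dm behind
the fungal peak, the whole structure advancing as a travelling wave at
0.43 mm per day (front position almost perfectly linear in time).

The same things are available from the shell:

```sh
fairyring run --mode combined -o out/            # one run + biometrics + label
fairyring sweep fig6_combined -o out/            # a panel preset, one label per cell
fairyring biometrics my_transect.csv             # classify external x,F,P data
fairyring heatmap --mode combined -o out/        # sensitivity table + matrices
```

Presets: `fig4_hydrophobicity`, `fig5_phytotoxicity`, `fig6_combined`,
`type13_demo`, `ring_vs_disk`. Any parameter can be overridden with
`--set symbol=value` using the published symbols (`g_F`, `s_I`, `k_W`, …).

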