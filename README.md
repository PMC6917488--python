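# rbcpop

Unsteady-state population dynamics of single red-blood-cell volume and
hemoglobin, for researchers who want to read more out of a routine complete
blood count (CBC) than its averages.  Modern analyzers report the volume
`v` (fL) and hemoglobin mass `h` (pg) of ~50,000 individual RBCs per draw,
plus a reticulocyte flag for the youngest cells.  `rbcpop` models the
circulating population as a density `P(v, h, t)` obeying a drift–diffusion
master equation with birth and clearance,

    ∂P/∂t = −∇·(P f) + ∇·(D ∇P) + b(v,h) − d(v,h)·P

with, in coordinates normalized by the population means (x = v/v̄, y = h/h̄):

* drift `f = α (e^{β_v(x−y)}, e^{β_h(y−x)})`, applied as velocity `−f/LS`
  toward the origin — an early fast phase that pulls a young cell's
  hemoglobin concentration toward the population mean, then a slow
  coordinated reduction (cells lose ~30% volume and ~20% hemoglobin over a
  ~100-day lifespan, nominal `LS = 105 d`);
* constant diagonal diffusion `D = diag(D_v, D_h)` for cell-to-cell rate
  variability;
* a sigmoidal clearance field `d = 1/(1+e^Δ)`,
  `Δ = 100 cosθ (r − v_c·√2)/(v_c·√2)`, switching on as the cell's radial
  position `r = √(x²+y²)` falls inside a boundary at fraction `v_c` of the
  population-mean radius;
* a birth term `b(v,h)` measured directly from reticulocyte-flagged cells.

On top of the solver the package implements the piecewise estimation
protocol for serial CBCs (steady-state fit of the first draw, then
transient fits between successive draws), the single-cell statistics used
to read a blood-loss response (u-axis projection, old/new-cell tail
fractions, MCHC/CHDW deltas), the dimensionless production/clearance
balance `D_v·v_c/α`, and a fully synthetic blood-loss cohort generator with
ground truth (per-segment parameters and the mean-RBC-age trajectory
`M_RBC(t)`), so the entire pipeline is testable without any subject data.

## A worked example

```bash
python examples/steady_state_population.py
```

prints, with the packaged baseline fixture:

```
turnover at steady state : 1.67 %/day (healthy baseline is ~1%/day)
median lifespan          : 58 days
lifetime volume loss     : 33.8 %  (expected ~30%)
lifetime hemoglobin loss : 23.7 %  (expected ~20%)
mean circulating-RBC age : 32.1 days

sampled 50k-cell draw:
  MCV_fL        : 88.79
  MCHC_gdL      : 32.51
  RDW_pct       : 11.59
  CHDW_pct      : 6.01
  rFraction_pct : 2.02
  HGB_gdL       : 14.43
```

The first block is the model's physiology — cells are produced at ~1.7% of
the population per day, drift down the u axis losing a third of their
volume, and are cleared at the boundary — and the second block shows that a
sampled draw reproduces normal clinical CBC indices.  The other example
scripts fit a synthetic subject (`fit_synthetic_subject.py`), map where
density moves after a 10% blood loss (`blood_loss_density_shift.py`), and
run the cohort-level link between the fitted `D_v·v_c/α` and the change in
mean RBC age (`cohort_ratio_vs_age.py`).

A thin CLI wraps the same functions:

```bash
rbcpop synth --n 28 --seed 7 --out cohort/     # cells.csv, draws.csv, truth.json
rbcpop stats --cells cohort/cells.csv --out indices.csv
rbcpop fit --cells cohort/cells.csv --out fits/ --seed 1
rbcpop scenario --name fig3 --out scenario/
```

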