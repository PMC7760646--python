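# nimopk

Population pharmacokinetics of **nimotuzumab** — an anti-EGFR IgG1 antibody —
in patients with autosomal dominant polycystic kidney disease (ADPKD).

ADPKD kidneys overexpress EGFR on cyst epithelium, which makes an anti-EGFR
antibody a candidate therapy and, at the same time, makes its pharmacokinetics
nonlinear: the drug is consumed by the very target it is meant to block
(target-mediated drug disposition, TMDD), and its non-specific clearance
rises with dose.  This package implements the semi-mechanistic model that
captures both effects, together with everything needed to study it without
access to patient data: a virtual phase-I trial generator, a population
estimator, model diagnostics and the dose-selection simulation analysis.

It is aimed at pharmacometricians and methods researchers who want a fully
scriptable, reproducible QSS-TMDD analysis stack in Python.

## The model

Free drug amounts in a central (`A1`) and peripheral (`A2`) compartment and a
clearance-stimulating turnover mediator (`A3`):

```
dA1/dt = [ In(t) − (CL·A3/V1 + Q/V1)·A1 + (Q/V2)·A2 − kint·Rtot·A1/(Kss + C1) ]
         / [ 1 + Rtot·Kss/(Kss + C1)² ]
dA2/dt = [ (Q/V1)·A1 − (Q/V2)·A2 ] / [ 1 + Rtotp·Kss/(Kss + C2)² ]
dA3/dt = kin·( 1 + Smax·C1^γ/(S50^γ + C1^γ) ) − kout·A3
```

with `C1 = A1/V1`, `C2 = A2/V2`, `kin = kout·A3(0)`, `A3(0) = 1`, and the
observable `Ctot = C1 + Rtot·C1/(Kss + C1)` (the assay measures total drug).
Binding is collapsed into the quasi-steady-state constant
`Kss = (koff + kint)/kon`; the bracketed denominators (≥ 1) account for drug
buffered in the drug-target complex.  Inter-individual variability is
log-normal on `Rtotp` and `kout`; residual error is additive on log
concentration.  Population estimation maximizes a Laplace-approximated
marginal likelihood (per-subject Gauss–Newton mode search over the two
random effects).

## Worked example

```python
from nimopk import ModelParameters, dose_sweep, successive_increases

p = ModelParameters()                      # reference typical values
sweep = dose_sweep(p, doses=(50., 100., 200., 400.))
for d, m in sweep.items():
    print(f"{d:>5.0f} mg: Cmax_free {m.cmax_free:6.1f} mg/L   "
          f"AUC {m.auc_total:7.0f} mg·h/L   t>Kss {m.time_above_kss:6.1f} h")
print(successive_increases(sweep))
```

prints

```
   50 mg: Cmax_free   40.1 mg/L   AUC    2718 mg·h/L   t>Kss   62.6 h
  100 mg: Cmax_free   37.9 mg/L   AUC    4751 mg·h/L   t>Kss  108.9 h
  200 mg: Cmax_free   75.8 mg/L   AUC    8724 mg·h/L   t>Kss  167.8 h
  400 mg: Cmax_free  151.5 mg/L   AUC   16525 mg·h/L   t>Kss  218.6 h
{(50.0, 100.0): 73.87..., (100.0, 200.0): 54.05..., (200.0, 400.0): 30.23...}
```

Reading: the 50-mg arm uses a 53% smaller central volume (a dose-specific
covariate of the reference fit), so its free peak matches the 100-mg arm's —
but the higher concentration-per-litre drives the clearance mediator harder
and the profile crosses below `Kss` (15.5 mg/L, the in-vivo binding
constant) much sooner.  Doubling 50→100 mg extends the time above `Kss` by
~74%; each further doubling adds progressively less (54%, 30%, …), the
diminishing return that motivates capping the dose rather than escalating.

The same analysis end-to-end, from a config file:

```bash
nimopk generate --seed 20201147 --out trial.csv
nimopk fit --data trial.csv --out fit.json
nimopk vpc --data trial.csv --nsim 1000 --out vpc.csv
nimopk bootstrap --data trial.csv --n 500 --out boot.csv
nimopk sweep --out sweep.json
nimopk pipeline --seed 20201147 --out results/
```

Every artifact embeds the master seed and a configuration hash; re-running
with the same config reproduces all numeric outputs bit for bit.

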