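# kelpres

Resilience metrics and global sensitivity analysis for a
kelp–urchin–predator food chain with nonconsumptive feedbacks.

Northeast Pacific kelp forests and urchin barrens are alternative community
states: the same reef can hold either dense kelp with few active grazers or
bare rock carpeted with starving urchins.  `kelpres` implements a
Rosenzweig–MacArthur-type food chain — live kelp *A*, drift kelp *D*,
purple urchins *U*, and a sunflower-sea-star-like predator *S* — in which
four nonconsumptive effects modulate consumption: urchin preference for
drift kelp (`1/(1+κ_D D)`), fear of predators (`1/(1+κ_S S)`),
starvation-dependent predation susceptibility (`1/(1+κ_A(A+D))`), and
kelp-dependent urchin nutritional value (`1+β(A+D)`).  Drift kelp is
eliminated at its quasi-steady state `D*(A,U)`, leaving a reduced
three-variable system `(A, U, S)` on which everything runs.

For a parameter set the package computes three resilience metrics of the
kelp forest state, each probing a different feature of the ball-and-cup
picture:

| metric | meaning | computation |
| --- | --- | --- |
| recovery likelihood | width of the basin | fraction of an initial-condition grid whose 1000-week trajectory ends above 95% of the forest kelp density |
| recovery rate | steepness near the bottom | −max Re λ of the Jacobian at the forest equilibrium |
| resistance | depth of the cup | Freidlin–Wentzell quasipotential forest → barren via minimum-action paths |

and a global sensitivity analysis: parameters drawn from published
uncertainty distributions (with the NCE strengths zero-inflated at 10%),
metrics evaluated per draw, and drivers ranked by random-forest permutation
importance.

Intended users: theoretical ecologists and restoration modelers who want a
tested, scriptable implementation of multistability diagnostics
(basin-of-attraction estimation, linear return rates, quasipotentials via
minimum-action paths) on a concrete kelp-forest model, or who want to swap
in their own parameterizations.

## Worked example

```python
import numpy as np
from kelpres import baseline_parameters, simulate
from kelpres.equilibria import find_equilibria
from kelpres.resilience import compute_metrics

params = baseline_parameters()          # published bull-kelp baselines

for eq in find_equilibria(params):
    print(f"{eq.label:10s} A={eq.state[0]:10.3f} U={eq.state[1]:8.3g} "
          f"S={eq.state[2]:8.3f} stable={eq.stable}")

m = compute_metrics(params)
print("recovery likelihood:", m.recovery_likelihood)
print("recovery rate      :", m.recovery_rate)
print("resistance         :", m.resistance)
```

prints

```
extinction A=     0.000 U=       0 S=   0.000 stable=False
other      A=  2800.000 U=       0 S=   0.000 stable=False
barren     A=     0.097 U=    36.2 S=   0.000 stable=False
forest     A=  2800.000 U=4.16e-07 S=  44.216 stable=True
recovery likelihood: 0.825
recovery rate      : -4.7111452469669225e-05
resistance         : 1.4966496565848364e-07
```

Reading the numbers: the forest holds 2800 g of kelp with ~44 sea stars
keeping urchins functionally absent; the barren keeps 36 urchins on 0.1 g
of kelp with no predators.  82.5% of the default 320-point initial-density
grid recovers to the forest within 1000 weeks.  The recovery rate is a
hair *negative*: the forest is a very weakly divergent focus (timescale
~20,000 weeks, i.e. neutral on the study horizon), and the resistance of
~1.5e-7 in rescaled units means there is essentially no action barrier —
with predator mortality at 1e-4/week, suppressing the slow sea-star
population is nearly free, after which urchin release collapses the kelp
deterministically.

The sensitivity pipeline, from the shell:

```bash
kelpres gsa --n 2000 --seed 1 --out results/gsa          # samples + importance tables
kelpres sweep --metric recovery_likelihood --param r --range 0.5,4,15 --out results/sweep
kelpres quasipotential --out results/qp                  # forest->barren path CSV
kelpres metrics --params my_params.yaml --out results/m
```

Sweeping kelp growth `r` shows the characteristic step: recovery
likelihood is 0 for `r` below the drift-production rate `δ_A = 1.8` and
jumps to ~0.8 above it — kelp persists only when growth outpaces the loss
of biomass to drift.

## Layout

```
src/kelpres/
  params.py         17-parameter set, validation, serialization
  model_core.py     full + reduced dynamics, analytic Jacobian, LSODA simulate
  _fastsim.py       numba Rosenbrock(2,3) batch integrator
  equilibria.py     multistart equilibrium search, stability, labeling
  action_solver.py  geometric minimum-action paths (quasipotential)
  resilience.py     the three metrics
  gsa.py            parameter sampling, batch evaluation, RF importance, sweeps
  scenarios.py      baselines, IC grids, disturbances, double-well oracles
  io.py, cli.py     config/result round-trips, `kelpres` CLI
docs/methods.md     model, numerics, design choices, limitations
```
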