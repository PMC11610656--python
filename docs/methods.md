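# Methods

## The model

`kelpres` implements a tritrophic food-chain model of a temperate rocky
reef: live kelp *A* (g), drift kelp *D* (g), purple urchins *U*
(individuals), and an urchin predator *S* (sunflower-sea-star-like,
individuals).  The skeleton is a Rosenzweig–MacArthur chain — logistic
basal growth, Type I (linear) grazing of kelp by urchins, Type II
(saturating) predation on urchins — with the kelp resource split into a
live and a drift pool and four nonconsumptive-effect (NCE) feedbacks
multiplying the consumption terms:

* **drift preference** `1/(1 + kappa_D * D)`: the share of grazing time
  urchins spend actively grazing live kelp, the remainder spent passively
  consuming drift;
* **fear of predation** `1/(1 + kappa_S * S)`: predator cues suppress
  active grazing;
* **starvation-dependent predation susceptibility** `1/(1 + kappa_A * (A + D))`:
  starved urchins are easier prey;
* **kelp-dependent nutritional value** `1 + beta * (A + D)`: well-fed
  urchins yield more energy per predation event.

Live kelp sloughs into drift at rate `delta_A` (a fraction `eps_D`
retained), drift degrades at `delta_D`, and conversion efficiencies
`eps_U`, `eps_S` route energy up the chain.  All rates are per week; kelp
is in grams (the published parameter units are taken literally, including
`kappa_D = 1.95 (g kelp)^-1`, whose unit may well be a g-vs-kg slip but is
not corrected here, and `gamma_U`,
which multiplies urchin density in the saturation term although its
printed unit is per sea star).

Because drift turns over much faster than the other state variables, *D*
is eliminated at its quasi-steady state `D*(A, U)`, the unique nonnegative
root of

    kappa_D (alpha_D U + delta_D) D^2 + (delta_D - eps_D delta_A A kappa_D) D
        - eps_D delta_A A = 0,

evaluated with the cancellation-free quadratic formula; below
`kappa_D < 1e-12` the drift-consumption term (which carries the factor
`1 - 1/(1 + kappa_D D)`) vanishes identically and the root degenerates to
`eps_D delta_A A / delta_D`, the continuous limit of the quadratic root.
All analyses run on the reduced `(A, U, S)` system; a test-enforced
invariant keeps the reduced rates equal to the full-model rates at
`D = D*` to 1e-10 relative.

## Integration and the Jacobian

`simulate` uses LSODA (stiffness-switching, `rtol 1e-8` / `atol 1e-10`
defaults).  The batch engine behind the recovery-likelihood metric and the
sensitivity analysis is a numba-compiled, L-stable Rosenbrock(2,3) scheme
(`rtol 1e-6` / `atol 1e-9`) with the closed-form Jacobian; the system is
genuinely stiff whenever predators are abundant (urchin loss rates of
order 10^3/week against kelp relaxation of order 1/week), which rules out
explicit methods for 1000-week horizons.  Equivalence of the two
integrators is tested on trajectories spanning both basins.  Negative
solver undershoot is clamped to zero in RHS inputs and outputs; densities
are nonnegative by construction.

The Jacobian of the reduced system is analytic: partial derivatives of the
full-model rates combined with the implicit derivatives of `D*` from the
defining quadratic.  A central finite-difference Jacobian (one-sided at the
nonnegativity boundary) is retained purely as an independent oracle.

## Equilibria and state labels

Boundary reasoning removes most equilibrium classes (no kelp means urchins
starve; no urchins means predators starve), leaving extinction, the
urchin-free kelp state `K(1 - delta_A/r)`, sea-star-free coexistence, and
interior coexistence.  The latter two are found by multistart `hybr` root
searches on the per-capita rates in log coordinates — essential because
interior forest equilibria can hold urchin densities below 1e-6.  Residuals
are checked against `1e-8 * (1 + rK/4)` and duplicates merged at 1e-6
relative distance.

**Stability on the study horizon.**  All resilience metrics are defined
over a 1000-week horizon.  At the published baselines the interior forest
equilibrium (A = 2800 g, U = 4.2e-7, S = 44.2) carries a complex eigenvalue
pair with real part +4.7e-5/week: a Type II destabilization whose doubling
time (~2e4 weeks) is far beyond the horizon, while the barren equilibrium
is slowly invadable by sea stars (predator mortality `delta_S = 1e-4`/week
is far below the predation gain available there).
Strict sign-of-real-part classification would therefore declare the system
to have no relevant attractors at all, contradicting its plain 1000-week
behavior.  The package classifies an equilibrium as stable when every
eigenvalue real part is below `stab_tol = 1e-3`/week (the reciprocal of the
horizon); exact eigenvalues are always stored so callers can apply a
stricter reading.

Labels: *forest* is the stable equilibrium with the largest kelp density,
provided it reaches 10% of the urchin-free kelp equilibrium; *barren* is a
low-kelp (<5%) equilibrium with urchins present — a stable one when it
exists, otherwise the sea-star-free coexistence equilibrium, which is the
metastable barren community on the horizon (its `stable` flag remains
`False`).  The 10%/5% thresholds are scale-free package choices; the
states have no canonical numeric definition.

## The three metrics

* **Recovery likelihood**: fraction of an 8 x 8 x 5 grid of initial
  conditions (kelp on (0.02K, 1.2K], urchins on [0, 2x barren urchins],
  sea stars on [0, 2x forest sea stars]) whose 1000-week trajectory ends
  with mean kelp over the final 100 weeks above 95% of the forest kelp
  density.  The tail mean, not the endpoint, guards against oscillatory
  attractors.  Integration failures count as non-recovered and are logged.
* **Recovery rate**: minus the largest eigenvalue real part of the
  Jacobian at the forest equilibrium.  It can be legitimately negative
  (weakly divergent forests, as at baseline) and is reported as missing
  when no forest exists.
* **Resistance**: the Freidlin–Wentzell quasipotential barrier from forest
  to barren under additive isotropic noise, computed by minimum-action path
  optimization.

## Quasipotential computation

The geometric (time-free) action
`S = \int (||phi'|| ||f(phi)|| - phi' . f(phi)) ds` is discretized on 101
nodes with midpoint quadrature and minimized over interior nodes by
L-BFGS-B with the exact discrete gradient (field Jacobians analytic for
the kelp model, finite-differenced for generic fields).  Two details
matter:

* a spring penalty on non-uniform node spacing, re-scaled each cycle from
  the current action, prevents the optimizer from pushing the *discrete*
  action below the continuum value by clustering nodes where the
  quadrature under-resolves `||f||`; nodes are re-spaced to uniform arc
  length between cycles and the reported action is always that of the
  re-spaced path;
* for the kelp model the nodes are box-constrained to the nonnegative
  orthant, since the clamped vector field and its analytic Jacobian
  disagree outside it.

State coordinates are rescaled by the forest equilibrium values before
action computation, with per-component fallbacks (K, 1, 1) when a forest
component is essentially zero (e.g. urchin densities of 1e-7 would
otherwise distort the isotropic-noise geometry).  The rescaling vector is
recorded in every path result.  Absolute quasipotential values are
convention-dependent; only comparisons under a fixed convention are
meaningful.

Two transition strategies are evaluated and the smaller action is
reported, each being a valid upper bound on the quasipotential: a direct
forest-to-barren path optimization, and a *gate* decomposition — an
optimized leg from the forest to its sea-star-free projection
`(A*, U*, 0)` followed by the deterministic collapse flow (urchin
outbreak, kelp collapse, slow urchin starvation), which carries zero
action in the continuum and is traced by the stiff integrator with
adaptive node recording.  The gate route captures the typically cheapest
escape in this model: because predator mortality `delta_S` is tiny, the
costly part of a transition is suppressing the slow predator, after which
the barren is reached for free.  At the published baselines the forest is
marginally unstable on infinite horizons, so the true quasipotential is
essentially zero and the computed values (~1e-7 in rescaled units) sit at
the discretization floor; across the sensitivity ensemble the values span
many orders of magnitude.

## Synthetic scenarios and the sensitivity analysis

The scenario module ships the published baseline parameter table, builds
deterministic Cartesian initial-condition grids, applies pulse
disturbances (proportional kelp loss, additive urchin outbreaks,
proportional predator removal — the metrics themselves are
disturbance-agnostic), and provides 1D/2D double-well gradient systems
with known quasipotential 0.5 as analytic oracles.

The GSA draws each parameter independently from the published uncertainty
distributions (Normal truncated at zero by resampling, LogNormal, Uniform,
LogUniform; the printed table's notation is ambiguous for several entries
— the shipped readings bracket every baseline value and are fully
configurable as a JSON table).  The four NCE parameters are zero-inflated
with probability 0.1.  Default ensemble sizes are 10,000 draws for
likelihood/rate and a seeded 1,000-draw subsample for resistance (each
quasipotential solve costs a path optimization); the packaged acceptance
tests run a scaled 2,000/300 design that completes on a single CPU in
minutes.  Importance
uses a 500-tree random forest per metric (rows where the metric is
defined, 25% held out) scored by permutation importance, with impurity
importance stored as a secondary diagnostic; scores are comparable only
within a metric.  The regression target is the raw metric value — no
transform is applied — which makes the
resistance ranking sensitive to the handful of draws with extreme
barriers; this is a known limitation discussed below.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions of the analysis: baseline
parameters, the distribution table, the NCE zero-inflation, 1000-week
horizons and the 95% recovery threshold.  It does not emulate seasonal
(annual) kelp demography, space, additional grazers or predators, or
measurement noise — passing tests demonstrate internal correctness of the
pipeline under the model's assumptions, not field realism.

## Known limitations

* Recovery rate at a true three-species equilibrium always contains a
  predator mode with |Re| of order `delta_S`; with `delta_S` sampled down
  to 1e-9 the metric is pinned to the predator timescale for most
  ensemble draws.  Drivers of the urchin-growth mode (conversion
  efficiency, drift escape, fear) consequently do not dominate its
  sensitivity ranking here, although they would at a kelp-rich
  non-equilibrium reference state.
* Resistance values below ~1e-6 (rescaled) are at the path-discretization
  floor and should be read as "no effective barrier".
* The importance rankings at the scaled-down ensemble sizes are noisy for
  resistance (order 1e2 defined rows after bistability filtering).
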