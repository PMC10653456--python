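# Methods

## Model and conventions

The single-society model couples capacity *x*, resources *y* and wealth
*z* (see README for the equations).  All rates are per year; time is in
years throughout, and the Lyapunov exponent is reported per year so its
reciprocal is directly a horizon in years.

The regularization ε (default 0.01) only exists to keep the vector field
smooth as *z* → 0 during integration.  All structural analysis — fixed
points, Jacobians, both bifurcation thresholds — is done on the
unregularized field (ε → 0): the factor 1 − e^(−z/ε) is taken as 1 at
interior points and 0 on the invariant plane z = 0, and x + ε as x.
`exp(−z/ε)` is evaluated as 0 once z/ε > 700 (overflow guard).

### Equilibria and boundary stability

The interior equilibrium is

    y_eq = cd/(αb),   x_eq = √( (r/α)(1 − y_eq/K) ),   z_eq = (d/b) x_eq².

Every returned fixed point is verified by substitution: the unregularized
right-hand side at the returned coordinates must have norm < 10⁻⁸ (this
is an internal assertion, not merely a test).

The raw Jacobian is singular at the boundary equilibria O = (0,0,0) and
N = (0,K,0) (the term bz/x is 0/0 there), and the z = 0 limit of the
regularizing factor freezes *x* entirely, which would make N's stability
blind to α.  Instead, near the boundary the package linearizes the pair
(u, z) with u = x²: u̇ = 2bz − 2du, ż = αyu − cz (y frozen at its
equilibrium value), plus the independent resource relaxation rate (−r at
N, +r at O).  The determinant of the (u, z) block changes sign exactly at
α⋆ = cd/(Kb), so this chart expresses the transcritical exchange: N is
stable below α⋆ and unstable above; O is always unstable (resources
regrow).  The eigenvalues stored for O and N are those of this boundary
linearization and should be read as stability indicators, not as decay
rates of the regularized flow.

### Hopf threshold

The closed-form α_c (README) is cross-checked against bisection on the
real part of the interior Jacobian's complex eigenvalue pair (relative
tolerance 10⁻⁶).  At the default parameters the two agree to ~10⁻¹³
relative, and to 0.1% across random parameter sets within ±50% of the
defaults (tested).  Downstream scenario definitions ("k times α_c")
always resolve against the validated value, so they would survive any
correction to the closed form.

## Integration

Classical fixed-step RK4, compiled with numba.  Defaults: dt = 0.05 yr
for trajectory work (the collapse spikes pass close to the origin, where
the regularized field is stiffest), dt = 0.1 yr for the network regime
scans, where step-halving changes no classification (tested).  Components
that undershoot zero within −10⁻⁹ are clamped to zero — RK4 substeps can
undershoot at machine level — while anything lower raises an error: true
negativity means the step is too large, and silently clamping it would
change the model.  Fourth-order convergence is asserted in the tests
(fitted exponent 4 ± 0.5 against a fine-step reference).

Default horizons: 5 000 yr for single-system regime work, 20 000 yr
recorded after 10 000–14 000 yr burn-in for attractor statistics, longer
(see below) for Lyapunov estimation.  These are engineering choices,
config-exposed, validated by step-halving and burn-in doubling.

## Regime classification

An attractor is summarized by the max/min ratio of total population
Σx_i after burn-in: ratio < 1 + 10⁻³ means a fixed point; otherwise the
count of clustered local extrema separates limit cycles (two clusters)
from aperiodic attractors (more).  Extrema are parabolically refined
(removing the O(dt²) sampling bias on sharp peaks) and clustered at 10⁻³
relative tolerance.

Near the boundary of a stabilization window, transients decay *slowly*:
the excess ratio shrinks by a roughly constant factor every few thousand
years, and a 7 000-yr run can report a ratio of 1.25 for a state that is
genuinely converging to a fixed point.  The network classifier therefore
works in stages (5 000 yr burn + 2 000 yr measure per stage, up to
70 000 yr): it stops early when the ratio reaches 1 (fixed point), when
it exceeds 2 outright, or when the excess ratio stops shrinking between
stages (a sustained oscillation).  A consequence worth knowing: at long
horizons some scenarios that look oscillatory over a few thousand years
(e.g. the five-node chain with a black-node rate of 2.5α_c at moderate
σ) turn out to converge to a genuine fixed point.

## Largest Lyapunov exponent

Two estimators are provided.

**Two-trajectory fit** (the headline method): after burn-in onto the
attractor, the state is duplicated with +10⁻⁹ added to every component,
both copies are co-integrated, and the slope of ln‖difference‖ against
time is fitted.  On this attractor the separation grows in *bursts*: a
collapse spike amplifies any phase difference to the attractor diameter
within a single event, after which the distance falls back between
spikes.  The upper envelope of the log-distance therefore saturates long
before the bulk of the curve, and naive rules such as "fit until the
distance first reaches a fraction of the attractor diameter" latch onto
the first burst and overestimate the exponent by an order of magnitude.
The fit window is instead ended when the 250-yr *running median* of the
log-distance rises to within 2 ln-units of its saturation plateau, and
the procedure is repeated over several re-perturbation windows spaced
5 000 yr along the attractor (default 8 windows of 12 000 yr); the
estimate is the mean slope with its standard error over windows.
Individual windows scatter by a factor of ~2–3 around the mean — a
property of the intermittent dynamics, not of the estimator — which is
why a single-window fit of this quantity is unreliable.

**Benettin renormalization** (the cross-check): the companion trajectory
is rescaled back to separation 10⁻⁹ every τ = 20 yr and the log growth
factors are averaged.  The result is insensitive to τ (5–50 yr), to the
perturbation size (10⁻⁷–10⁻¹¹), to dt (0.02–0.1) and to burn-in
(10⁴–5·10⁴ yr), and converges with averaging horizon.

For the three-node perturbed-uniform scenario at 10α_c both estimators
give λ ≈ 2.3–2.6 × 10⁻³ /yr (they agree within their joint uncertainty;
asserted in the tests), i.e. a predictability horizon 1/λ of roughly
380–430 years — inside the 300–1000-yr band this class of
parametrizations produces, though above the ~290 yr that a fit from the
upper part of the single-window distribution would suggest.  Sign
pattern across regimes: λ < 0 at the stable equilibrium, |λ| < 5×10⁻⁴
on the limit cycle, λ > 10⁻³ in the chaotic scenario.

## Synchronization and symmetry breaking

With identical nodes and a permutation-symmetric interaction matrix the
synchronized subspace is *exactly* invariant, so exactly symmetric
initial conditions can never desynchronize and the network degenerates to
a rescaled single system (which, for A = 11ᵀ/N + δI, would be a limit
cycle at α(1+δ)).  The chaos lives in the weakly unstable transverse
directions; network initial conditions are therefore per-node (1, 100, 1)
with a seeded multiplicative perturbation of relative size 10⁻⁶.  After
the transient the nodes stay approximately synchronized — the median
pairwise distance is ~4% of the attractor diameter — but collapse spikes
transiently desynchronize them (maxima of ~40%); both numbers are
reported by the chaos runner.

## Scenario defaults

* Chaos scenario: N = 3, A = ones/3 + δI with δ = 10⁻²/3, no migration,
  common rate 10α_c.  Extrema scans over the rate show the cluster count
  jumping above two at ≈ 3α_c.
* Diffusion scans: independent extraction (A = I), sustainable nodes at
  2α⋆, unsustainable at {1.5, 2, 2.5}×α_c, σ ∈ [0, 0.3] in steps of
  0.005 (scan default) or 0.01 (random-graph experiment).  Topology
  layouts, chosen once: chain of 5 with the sustainable node at the
  centre; ring of 5 with one sustainable node; star of 5 with a
  sustainable hub (every neighbour unsustainable).  Note the chain and
  ring layouts are related by a reflection-symmetry quotient and give
  identical totals — a property of these layouts, not an error.
* Adjacent-vs-separated comparison: chain of 6 with the sustainable pair
  at {2,3} (adjacent) vs {1,4} (separated); the globally-sustainable σ
  window is never longer in the adjacent arrangement.
* Random-graph experiment: connected Erdős–Rényi graphs, N = 20, edge
  probability 4/19 (resampled until connected, cap 1000), sustainable
  fractions in 5% steps placed as greedy-random independent sets
  (resampled; infeasible placements are recorded, not fatal), σ scanned
  from 0.3 downward with early exit on success.  N = 20 is the smallest
  round size at which a 20% fraction is four nodes and an independent
  set of that size is likely at average degree 4.

## What the generator does and does not emulate

All inputs are generated internally from the model itself; there is no
observational data.  Conclusions are statements about this dynamical
system — its bifurcations, its chaotic regime, its stabilization by
diffusion — and transfer to real socio-ecological systems only insofar
as the model's assumptions (single aggregate capacity, logistic
resources, quadratic cooperative extraction, migration as linear
diffusion on an undirected graph) are credible abstractions.  Directed or
weighted migration, time-varying couplings, heterogeneous node
parameters beyond the extraction rate, and community-structured
topologies are out of scope.

## Numerical choices at a glance

| quantity | value | why |
| --- | --- | --- |
| dt (trajectories / scans) | 0.05 / 0.1 yr | spike stiffness; halving changes nothing asserted |
| negative clamp band | (−10⁻⁹, 0) | RK4 substep roundoff only |
| extrema / ratio tolerance | 10⁻³ relative | separates period structure from RK4 noise |
| Lyapunov perturbation | 10⁻⁹ per component | result invariant 10⁻⁷–10⁻¹¹ |
| Benettin τ | 20 yr | result invariant 5–50 yr |
| spectrum | Hann, mean removed, one segment, peaks > 1% of max | makes "density of peaks" operational |
| Hopf bisection tolerance | 10⁻⁶ relative | far below any downstream sensitivity |
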