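# ecosocnet

Dynamics of socio-ecological systems — single societies and networks of
them — for researchers studying long-term sustainability, collapse, and
the limits of predictability of coupled human–natural systems.

## The model

A society is a triple: capacity/population *x*, regenerative resources
*y*, and wealth/returns *z*:

```
ẋ = (b z / (x + ε) − d x) (1 − e^(−z/ε))
ẏ = r y (1 − y/K) − α x² y
ż = α x² y − c z
```

Capacity grows with returns per unit capacity and decays in proportion to
its size; resources regrow logistically to carrying capacity *K* and are
extracted in proportion to the *square* of capacity (cooperating units of
extraction); extraction feeds wealth, which decays at rate *c*.  The
factor involving ε only regularizes the flow near the origin.

The extraction rate α organizes everything:

* **α < α⋆ = cd/(Kb)** — no society persists; the resource-only state
  (0, K, 0) is stable.
* **α⋆ < α < α_c** — a transcritical bifurcation hands stability to an
  interior equilibrium E (the *sustainable* regime).  Capacity at E is
  maximal at α = 2α⋆.
* **α > α_c** — a supercritical Hopf bifurcation, with

  ```
  α_c = [2cd + (c+2d)²] / (4Kb) · (1 + √(1 + 8rcd(c+2d)/[2cd+(c+2d)²]²))
  ```

  replaces E by a limit cycle whose swings approach the origin: recurrent
  collapse, the *unsustainable* regime.

Networks of N societies couple through an extraction interaction matrix
**A** (node *i*'s extraction is α_i x_i y_i Σ_j A_ij x_j) and through
migration modelled as graph-Laplacian diffusion −σ **B** x, which
conserves total population.  Two headline phenomena:

* with **A** = 11ᵀ/N + δI (a tiny non-uniformity, δ = 10⁻²/N) and a common
  extraction rate above ≈ 3α_c, the nearly-synchronized network becomes
  **chaotic** — a positive largest Lyapunov exponent sets a predictability
  horizon of a few hundred years;
* with independent extraction (**A** = I) and a mix of sustainable
  (α = 2α⋆) and unsustainable (α = 1.5α_c) societies, moderate diffusion
  can pin the *whole* network to a fixed point; on random graphs of
  average degree 4 about 20% of sustainable societies — placed so that no
  two are adjacent — typically suffices.

## A worked example

```sh
$ python examples/01_single_society_regimes.py
Extraction-rate thresholds (per capacity^2 per year):
  transcritical alpha_star      = 1.2500e-05
  Hopf alpha_c (closed form)    = 7.2005e-05
  Hopf alpha_c (eigenvalue scan)= 7.2005e-05
  ...
Equilibria at the typical rate alpha = 2.5e-05 (= 2 alpha_star):
  O: (x=   0.000, y=   0.00, z=   0.00)  unstable
  N: (x=   0.000, y= 100.00, z=   0.00)  unstable
  E: (x=  31.623, y=  50.00, z=  25.00)  stable

Long-run behaviour from initial condition (1, 100, 1):
  alpha = 2.500e-05: fixed_point  (population swing max-min = 0.00)
  alpha = 1.440e-04: limit_cycle  (population swing max-min = 42.18)
  alpha = 3.600e-04: limit_cycle  (population swing max-min = 36.95)
```

The closed-form Hopf threshold agrees with independent eigenvalue-crossing
bisection to machine precision; the society at the typical rate sits at
the maximal sustainable population x = √1000 ≈ 31.6; above the threshold
the population swings by ~42 units (collapse-and-recovery cycles), and
pushing extraction higher *shrinks* the swing.  The other examples cover
the bifurcation diagram (`02`), network chaos and its diagnostics (`03`),
diffusion-induced stabilization on a star (`04`), and the random-graph
sustainable-fraction experiment (`05`).

A thin CLI mirrors the runners:

```sh
ecosocnet thresholds
ecosocnet sigma-scan --topology star --multiple 1.5 --out-dir results/star
ecosocnet chaos --seed 0
```

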