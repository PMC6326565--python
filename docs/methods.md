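# Methods

`dosegrid` quantifies the information lost when a phase I dose-finding
trial restricts a continuous dose range to a small set of discrete dose
levels. It implements two Bayesian model-based designs — the continual
reassessment method (CRM) and escalation with overdose control (EWOC) —
over the same posterior engine, simulates trials against known
dose–toxicity truth curves, and scores each design × dose-scheme
combination on safety and efficiency.

## Dose–toxicity model

Doses are standardized to `[X_min, X_max] = [0, 1]`. The working model
for the probability of a dose-limiting toxicity (DLT) is a
two-parameter logistic regression

    P(DLT | dose = x) = F(β0 + β1 x),   F(u) = 1 / (1 + e^(−u)),  β1 > 0,

reparametrized in clinically meaningful terms: `ρ0 = P(DLT | x = X_min)`
and `γ`, the maximum tolerated dose (MTD), defined by
`P(DLT | dose = γ) = θ` with target toxicity level `θ = 0.33`. The
mapping

    β0 = (γ F⁻¹(ρ0) − X_min F⁻¹(θ)) / (γ − X_min)
    β1 = (F⁻¹(θ) − F⁻¹(ρ0)) / (γ − X_min)

requires `ρ0 < θ` for a positive slope. The likelihood of `k` observed
(dose, outcome) pairs is the product of Bernoulli terms; priors are
independent uniforms on `ρ0` and `γ` over the bounded box (a rescaled
Beta family is available as a hook). By default the prior truncates
`ρ0 < θ`, enforcing `β1 > 0`; the flag `PriorSpec(truncate_rho0=False)`
admits the full `(0, 1)` support.

## Posterior computation: deterministic quadrature

Because the parameter space is a bounded rectangle, the posterior is
computed by midpoint-rule tensor quadrature rather than MCMC: nodes are
cell midpoints of an `n_ρ × n_γ` grid (default 201 × 201, contract
minimum 64 per axis), log-likelihood is accumulated in log space with
max-shift normalization, and every posterior summary (mean, quantiles)
is a deterministic function of the data. This removes Monte Carlo error
from the dose recommendations entirely, which matters when comparing
designs whose recommendations differ by fractions of a dose unit.

Numerical choices:

* **Midpoints, not endpoint-inclusive nodes.** The midpoint rule is
  O(h²) for smooth integrands; equal weights on endpoint-inclusive
  nodes would be O(h) and can bias the γ mean by ~h/2 when the
  posterior has mass at the boundary. Midpoints also avoid the
  degenerate node `γ = X_min`, where the reparametrization has no
  slope, and make prior quantiles exact under the uniform prior.
* **Quantiles** interpolate linearly on the midpoint CDF (cumulative
  mass minus half the node's own mass), anchored at `(X_min, 0)` and
  `(X_max, 1)`; ties resolve to the leftmost attaining dose
  (safety-conservative).
* With ρ0-truncation on, the ρ0 nodes are laid directly on `(0, θ)`,
  spending the full grid resolution on the live support.
* The trial engine accumulates per-record log-likelihood terms
  incrementally and caches them per (dose, outcome), so sequential
  updating is exactly the batch update and discrete-scheme trials cost
  one grid exponentiation per patient.

Accuracy contract (tested): on short histories, the γ posterior mean
and 5/25/50% quantiles at the default resolution agree with a
4×-resolution brute-force Riemann quadrature within 10⁻³ dose units.

## Designs

Both designs start the first patient at the lowest dose. The final MTD
estimate for both is the posterior mean of γ after `n` patients
(posterior-median and quantile estimators are available as options).

* **CRM** assigns the dose whose model-estimated toxicity is closest to
  θ. The plug-in coefficients come from the posterior means of
  `(ρ0, γ)` through the reparametrization; on the continuous support
  the assigned dose is therefore exactly the posterior-mean MTD,
  clipped to `[0, 1]`; on a discrete scheme the `|θ − F̂(d)|` objective
  is scanned over the dose set with ties to the lower dose.
* **EWOC** assigns the α-quantile of the γ posterior, so the posterior
  probability of exceeding the MTD is α. The feasibility bound follows
  the conditional schedule C(0.05, 0.05): α starts at 0.05 and
  increases by 0.05 after every DLT-free outcome, holds after a DLT,
  and caps at 0.50 (at the cap EWOC recommends the posterior median).

Discrete schemes apply two constraints to the raw recommendation:
rounding (default *nearest*, with an exact midpoint resolved to the
lower dose for safety; *round-down* available) and a *no-skip* rule —
an escalation may exceed the highest previously administered dose level
by at most one index, while de-escalation is unrestricted.

## Truth curves (the synthetic-data generator)

True dose–toxicity curves take the form `p(x) = G(a + b·x)` with `G`
the CDF of one of four standardized families: logistic, normal, and
skew-normal with slant λ = +3 or −3 (CDF `Φ(u) − 2·T(u, λ)` with `T`
Owen's T function; quantiles by bracketed root-finding). The intercept
and slope are calibrated so that `p(0) = ρ0_true` and
`p(γ_true) = θ = 0.33`. Since this pins an affine transform at two
points, any location/scale labelling of the family is absorbed into
`(a, b)`: only the shape and slant matter (tested pointwise).

The study grid crosses 4 truth shapes × true MTDs {0.2, 0.4, 0.6, 0.8}
× sample sizes {20, 40, 60} × 6 dose schemes (continuous; equally
spaced grids of 21, 11, 9, 6, and 5 doses) × 2 designs, with cohorts of
one patient and Bernoulli DLT outcomes.

`ρ0_true` per shape is a scenario input, not a design parameter. The
defaults — logistic 0.10, normal 0.05, skew-normal(+3) 0.15,
skew-normal(−3) 0.01 — are the values under which the package's
optimal-toxicity-dose enumeration reproduces the reference enumeration
cell-for-cell across all four shapes; for each shape the
feasible window is narrow (e.g. ±0.001–0.004), so the enumeration
effectively identifies them. All are overridable per scenario.

What the generator does *not* emulate: patient heterogeneity and
covariates, late-onset or time-to-event toxicity, non-monotone or
plateauing curves, inter-cohort accrual dynamics, and stopping rules.
Passing tests therefore demonstrate the designs' behaviour under an
idealized monotone-curve Bernoulli world, not clinical performance.

## Operating characteristics

Per scenario, over replicated trials: bias and RMSE of the MTD
estimate; average DLT rate; percentage of trials whose observed DLT
proportion lies within θ ± 0.10; and two optimality measures, each
reported at trial level (final estimate inside the interval) and
patient level (fraction of administered doses inside):

* the **optimal MTD interval** `(γ(1−δ), γ(1+δ))` with δ = 0.15 — the
  defining statement of this interval also appears with δ = 0.10, but
  every printed endpoint uses 0.15, so 0.15 is the default (δ is
  configurable);
* the **optimal toxicity interval** `{x : θ − 0.10 < p(x) < θ + 0.10}`
  by monotone inversion of the truth curve. The band is likewise quoted
  ambiguously (0.05 in one place, 0.10 where results are shown); 0.10
  is the default and both are configurable.

Interval endpoints are open, matching the defining strict inequalities;
when inversion runs past a dose boundary the interval is clipped there
and the boundary dose itself counts as optimal, because it satisfies
the toxicity inequality (e.g. the logistic truth with MTD 0.8 has
`p(1.0) ≈ 0.417 < 0.43`). Dose-count percentages are reported to one
decimal, half-up. Where the reference enumeration's printed percentage
and count disagree, the count (pure geometry) governs.

## Study orchestration

Replicate RNG streams derive counter-style from
`(base seed, scenario index, replicate index)`, so results are
invariant to execution order, to parallelization, and to the replicate
counts of other scenarios. Cross-scenario aggregation pools the 16
truth scenarios (4 shapes × 4 MTDs) per (design, scheme, n) cell and
reports the median and 25th/75th percentiles, with quantiles by linear
interpolation between order statistics.

## Problem sizes used by the test suite

The enumeration tables and posterior-accuracy checks run at full
precision. The simulation-based checks run a reduced study — 200
replicates per scenario on a 65 × 65 posterior grid with a fixed base
seed — which is sufficient for the qualitative orderings they assert
(scheme RMSE rankings, DLT-rate bounds, RMSE monotonicity in n) while
keeping the suite to minutes on one core. `analysis/03_oc_study.py
--full` runs the full-size study (1000 replicates, 201 × 201).

## Known limitations

* The quadrature posterior is exact only up to grid resolution; an
  MCMC backend could be added behind the same contracts but is not
  provided.
* No stopping rules, cohort expansion, two-agent combinations,
  covariate adjustment, or informative priors beyond the Beta hook.
* The α cap of 0.50 and the lowest-dose start are conventional choices;
  both are configurable, and results for heavily safe scenarios (many
  consecutive no-DLT outcomes) are mildly sensitive to the cap.
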