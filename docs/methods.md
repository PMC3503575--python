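# Methods

## Uncertainty model

All propagation is first-order (linearized) ISO-style quadrature: for an
output `e = f(k_1, …, k_m)` of independent inputs,
`U_e² = Σ (∂e/∂k_i)² U_ki²`, with `U` always a *standard* (1-σ)
uncertainty, never an expanded one. Inputs are treated as uncorrelated —
there are no covariance terms in the model — so correlated instruments
(e.g. one balance weighing both slurry states) are outside scope.

Partial derivatives default to central finite differences with relative
step 1e-6 (absolute floor 1e-12). For smooth algebraic yield expressions
the truncation error is O(h²) ≈ 1e-12 relative and round-off is
≈ 1e-10 relative, comfortably inside the 1e-6 tolerance used to verify the
engine against hand-derivable closed forms (sum, product, quotient, power)
and against the batch-yield analytic identity
`u_r(Y)² = Σ u_r(k)² + (f_IS/(1−f_IS))² u_r(f_IS)²`. An expression object
may supply a `gradient(values)` hook for exact derivatives; both routes
satisfy the same contract. Contribution fractions are defined as
`term_i / U_e²`, the only decomposition consistent with the quadrature.

The independent check on the linearization is `mc_oracle`: n independent
Gaussian draws per input pushed through the same expression. For
product/quotient/sum forms with relative input uncertainties ≤ 5 % the
sampled standard deviation agrees with the quadrature within 2 % at n = 10⁶
(the linearization error scales with the square of the relative
uncertainty, so at instrument-level uncertainties the two are effectively
identical).

## Yield formulas

Units: masses kg, flows kg/h, concentrations g/L, densities kg/L; the
kg↔g conversion happens inside the formulas. Yields are fractions
internally and percent only at the I/O boundary. Yields are never clipped
to [0, 1]; out-of-range values get a `yield_out_of_range` flag so a bad
run is visible rather than silently truncated.

**Pretreatment (xylose from xylan).** Batch form as in the README.
Continuous runs replace the slurry mass by a slurry mass flow and the
biomass mass by the feed dry-mass flow. When the slurry flow is not
measured it is derived as
`(feed_dry/(1−moisture) + water + acid) · (1−flash_loss)`; this
mass-balance form is a declared stand-in (the actual pilot-reactor
bookkeeping is not published). The derived-flow budget can either be
collapsed to a single measurement (`budget.as_measurement()`) or — the
default in `xylose_yield` — expanded so every primary flow appears
individually in the yield budget.

**Enzymatic hydrolysis (glucose from cellulose).**
`Y_G = [m_f (1−f_IS_f)/ρ_L · C_G] / (m_0 · f_IS_0 · x_C) · (162/180)`.
The initial f_IS enters *multiplicatively* (it sets the cellulose charge),
so a 1 % absolute uncertainty on f_IS ≈ 0.20 is a 5 % relative effect —
this is why the hydrolysis budget is f_IS-dominated.

**Fermentation (ethanol from xylose).** With consumed/produced masses
taken as concentration deltas times state-matched liquor volumes
`V = m_slurry (1−f_IS)/ρ_L`, and an assumed hexose (glucose + fructose)
ethanol yield `a` (default 0.95, a constant with zero uncertainty):
`Y = [ΔEtOH − a·0.511·(ΔGlc + ΔFru)] / (0.511·ΔXyl)`, where 0.511 g/g is
the stoichiometric ethanol yield from either hexose or pentose sugar. The
run carries *two* slurry states (initial and final mass and f_IS). This is
deliberate: with a single shared volume the volume cancels algebraically
and f_IS would contribute exactly zero to the budget, contradicting how
these yields are actually bookkept at the bench, where initial sugars and
final ethanol are referenced to different broth states. A negative
numerator (hexose-attributed ethanol exceeding the measured total) is
flagged, not raised. Galactose and arabinose ethanol yields are not
modelled at the yield level.

Molecular weights default to the integer values 150/132 (xylose/xylan) and
180/162 (glucose/anhydroglucose) and are configurable.

## Plant surrogate and economics

The surrogate is a stoichiometric chain of three reaction slates over a
component mass-flow stream, with water and CO₂ explicit so every reaction
satisfies `reactant + water = products` exactly and total stream mass is
conserved to machine precision. Slate sizes are 21 (pretreatment), 8
(enzymatic hydrolysis, two sequential stages of 4), and 31 (fermentation:
five sugars × ethanol + residual sinks). Only the five key reactions
(xylan→xylose, arabinan→arabinose, cellulose→glucose, glucose→ethanol,
xylose→ethanol) carry meaningful defaults (0.90/0.90/0.90/0.95/0.85); the
remaining positions are *named placeholders with approximate yields* —
fidelity of individual side-reaction yields to any proprietary design
model is explicitly not claimed. Fermentation sink reactions (cell mass,
organic acids, glycerol, xylitol, lumped byproduct) share the residual
`1 − y_ethanol` by fixed weights, so mass closure holds for any sampled
ethanol yield up to 100 %. The single-product `Reaction` record accepts a
coproducts map (ethanol 0.511 + CO₂ 0.489) precisely so this closure is
exact.

Economics are levelized cost, not discounted cash flow: annualized capital
($60M/yr), fixed operating ($15M/yr), feedstock ($58.5/dry US ton at
83,333 kg dry/h ≈ 2000 Mg/day), a variable cost proportional to feed
($0.04/kg), minus a power credit on the boiler stream (lignin + unconverted
solids + cells, 2.0 kWh/kg at $0.06/kWh), over annual gallons (8410 h/yr,
2.988 kg/gal). These magnitudes are chosen to be representative of a
2000-Mg/day cellulosic ethanol plant; a single calibration scalar then pins
the base case to the declared target ($2.15/gal, the standard published
base case). What the surrogate is designed to preserve is the *relative*
response of MESP to compositions and yields; absolute dollar fidelity is a
non-goal. Under the defaults the elasticity of MESP to glucan (−0.64) is
about twice that to xylan (−0.32) — glucose carries more ethanol per unit
polymer and higher conversion defaults — and lignin (−0.10) matters far
less because electricity is worth much less than ethanol.

## Sensitivity analysis

Normalized sensitivity is the least-squares slope of ln(MESP) vs ln(X)
over 7 evenly log-spaced points spanning the perturbation range. Seven
points (rather than two) give an R² diagnostic for curvature; for exact
power laws the exponent is recovered to 1e-9 regardless of range, and the
result is invariant to positive rescaling of the output. The default range
is ±15 % of base. Where competing reactions share a substrate the upper
bound is reduced so the perturbed yield never exceeds
`min(cap, 100 − (group_total − base))`; an upper bound below a 1 %
relative headroom tolerance collapses to zero, so a reaction group already
at ~100 % total conversion (e.g. a 99.7 %-total fermentation group) is
perturbed only downward. The tolerance is this package's convention — the
underlying rule ("no headroom ⇒ 0") does not specify a cutoff.

## Monte Carlo

Inputs (composition fractions and the five key yields, percent scale) are
sampled independently as `Normal(base, u)` truncated to
`[base − 2u, min(base + 2u, max, 100)]` by rejection — not clipping, which
would put point masses on the bounds. Sampled glucan/xylan/lignin fractions
update the composition with the extractives component absorbing closure;
other components stay fixed. The default input table uses base yields with
their maximum attainable values (90/95, 90/95, 90/95, 95/100, 85/95) and
uncertainties (0.53, 0.34, 0.17 for composition; 2.7, 7.6, 5.2, 3.0, 3.0
for yields, percentage points). Note these tabulated yield uncertainties
differ from the uncertainties propagated from the emulated runs; the table
is used as given for the MC, and the discrepancy is inherent to treating
the table as the study's declared sampling design.

Summaries: sample mean; equal-tailed 95 % probability interval (2.5th and
97.5th percentiles) with half-width `(hi − lo)/2`; mode as the argmax of a
Gaussian KDE with Silverman bandwidth on a 512-point grid (bin-width
independent, unlike a histogram mode). Positive skew of the MESP
distribution (mean > mode, expected because yields are truncated above) is
logged as a soft check, not asserted — it is a property of the sampled
distribution, not a contract.

Apportionment regresses the MESP samples on standardized inputs by least
squares and assigns each input its squared standardized coefficient —
the variance it explains under independence — summed by unit-operation
group and normalized to 1. For a near-linear model this matches a
principal-component/variance decomposition; it is exact for linear models
(an additive model with coefficients 3 and 4 and equal input variances
splits 9/25 vs 16/25). Constant inputs are dropped with a warning.

## Synthetic data

The generator's true state is the declared study condition: true yields
56.4 % (pretreatment xylose), 77.8 % (hydrolysis glucose), 86.2 %
(fermentation ethanol-from-xylose, with the 95 % hexose assumption built
into the constructed ethanol totals). The pretreatment scale emulates a
1-Mg/day continuous reactor (42 kg dry/h feed at 10 % moisture, 90 kg/h
water, 3 kg/h acid, 5 % flash loss, f_IS 0.20, ρ 1.05); hydrolysis and
fermentation are 1-kg bench batches with self-consistent solids balances
(the hydrolysis final f_IS follows from the cellulose actually consumed).
Instrument classes: f_IS 1.0 % *absolute* (flagged: the convention could
also be read as relative; absolute is used throughout), flows 2 % relative,
laboratory masses 0.2 % relative (a balance, not a flow meter — this
package's own class, chosen as typical for bench gravimetry),
concentrations 1 % relative, density 0.5 % relative, composition absolute
at the standard compositional-analysis uncertainties.

Noise is Gaussian and independent across measurements, matching the
propagation model's assumptions — so the 2σ coverage test (92–98 % over
500 replicates, nominal ≈ 95 %) is a clean check of the propagation
arithmetic, *not* evidence about real instruments, which drift, correlate
(shared calibrations) and suffer sampling heterogeneity of slurries. None
of those effects are simulated. Zero-noise round trips recover truth to
1e-9, pinning the inversion algebra independently of the statistics.

Under these conditions the propagated uncertainties are ≈ 1.7 (pretreatment),
≈ 4.2 (hydrolysis) and ≈ 6.9 (fermentation) percentage points, with the
f_IS pair contributing ≈ 88 % and ≈ 61 % of the hydrolysis and fermentation
variance respectively — the hydrolysis and fermentation budgets are
f_IS-dominated, the pretreatment budget is spread across flows,
composition and f_IS with no single dominant term. The absolute
uncertainty magnitudes are properties of the emulated instrument set, not
of any particular laboratory's.

## Problem sizes and numerical choices

Defaults used by the test suite and the acceptance script: 10⁶ draws for
the sampling oracle, 5,000 Monte Carlo plant evaluations, 500 replicates
per unit for coverage, 7-point sensitivity stencils — sizes at which every
stochastic tolerance in the tests is several standard errors wide.
Degenerate inputs are errors, not NaNs: zero substrate (x_X, cellulose
charge, consumed xylose) raises an undefined-yield error; f_IS = 1, empty
truncation intervals, zero ethanol in the MESP denominator, and non-finite
expression values all raise with the offending quantity named. All
randomness flows through `numpy.random.default_rng` seeds; identical seeds
give bit-identical budgets, samples and reports.

## Known limitations

- First-order propagation only; strongly nonlinear expressions at large
  relative uncertainties need the sampling oracle instead.
- No correlated inputs, in either propagation or Monte Carlo.
- The economic layer is a calibrated levelized-cost surrogate; absolute
  MESP statistics (mode/mean/interval) characterize the surrogate, not a
  full process-simulator + discounted-cash-flow model, and the variance
  apportionment shifts accordingly.
- Oligomeric sugars appear only as lumped slate reactions, not in the
  three headline yields (which are monomeric).
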