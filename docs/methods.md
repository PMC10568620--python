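# Methods

## Model and assumptions

The package models an EGFR-mutant NSCLC tumor as four genotype
populations with continuous, deterministic cell counts: Type-W (driver
mutation only, sensitive to both TKI generations), Type-X (T790M,
resistant to first/second-generation TKIs), Type-Y (C797S, resistant to
osimertinib) and Type-Z (both secondary mutations, resistant to both).
Under a constant drug regimen each type grows or decays exponentially and
acquires resistance mutations at small constant per-day rates; mutation
is irreversible (no back-mutation), there is no density dependence or
carrying capacity, and mutations unrelated to resistance are treated as
neutral.  Counts are non-negative reals — the model is an expectation
over a large population, so fractional counts are meaningful and no
extinction threshold is applied.

Under one regimen the dynamics are the triangular linear system

```
w' = a w,   x' = g w + b x,   y' = h w + c y,   z' = k w + p x + q y + f z.
```

Therapy is a contiguous sequence of phases, each a constant regimen; the
state at a phase boundary seeds the next phase.

## Exact solution

Because the coupling is triangular the system solves in closed form.
With `E(r) = exp(r t)` and the divided difference
`D(r, s) = (E(r) − E(s)) / (r − s) ≥ 0`:

```
w(t) = W0 E(a)
x(t) = X0 E(b) + g W0 D(a, b)
y(t) = Y0 E(c) + h W0 D(a, c)
z(t) = Z0 E(f) + A D(a, f) + B D(b, f) + C D(c, f)

A = W0 (k + g p/(a−b) + h q/(a−c))      # e^{at} inflow into Z, including
                                        # the W→X→Z and W→Y→Z chains
B = p (X0 − g W0/(a−b))                 # e^{bt} inflow
C = q (Y0 − h W0/(a−c))                 # e^{ct} inflow
```

These formulas were re-derived directly from the differential equations
(substituting the x and y solutions into the z equation and grouping the
inflow by eigenvalue) and are validated against an independent adaptive
ODE integration rather than against any printed rendering of the
solution.  Grouping by eigenvalue can round a mathematically non-negative
component a few ulp below zero, so outputs are clamped at 0.

**Degenerate rates.**  The cascade divides by the rate differences
`a−b, a−c, a−f, b−f, c−f`.  When any of these is within 1e-8 (relative to
the largest growth-rate magnitude) of zero — a repeated eigenvalue — the
solver logs the event and defers to the numerical oracle at rel_tol 1e-12
instead of implementing the L'Hôpital limit formulas.  Such parameter
sets never arise at the bundled defaults, the fallback is exact to the
package's tolerances, and the scenario generator rejects degenerate draws
outright.

**Numerical oracle.**  `numeric_reference_state` integrates the system
with DOP853 at a caller-chosen relative tolerance (default 1e-10) and an
absolute floor of 1e-250, i.e. far below any attainable count, so error
control is purely relative.  This matters: under a strongly suppressive
drug a component can decay through a hundred orders of magnitude over
1000 days, and any ordinary absolute tolerance would make the comparison
with the closed form meaningless there.  Pure relative control is sound
here because every component is a non-negative sum of exponentials and
never crosses zero.  Agreement between the two routes is ≤ 1e-6 relative
per genotype across 100 random scenarios and three horizons (measured
worst case ≈ 6e-9).

All arithmetic is carried in linear (not log) space: the largest
magnitudes involved (~e²² growth on ~1e9 cells, ≈ 4e12) are comfortably
within double precision.

## Default parameters

Rates are per day; the bundled table (`tkiswitch/data/defaults.yaml`)
derives from published TKI cell-line growth measurements:

| regimen | a (W) | b (X) | c (Y) | f (Z) |
|---------|-------|-------|-------|-------|
| A (erlotinib) | −0.17 | +0.045 | −0.13 | +0.022 |
| B (osimertinib) | −0.32 | −0.15 | +0.024 | +0.022 |
| C (combination) | −0.064 | −0.0335 | −0.0335 | +0.022 |

All five mutation rates are 1e-7/day in every regimen.  Type-Z grows at
+0.022/day under **all** regimens: it is resistant to both drugs, so its
rate cannot be negative under any of them — this is also what the
simulated day-1000 burdens require.  The standard initial condition is a
clinically just-detectable tumor of 1e9 cells (≈1 cm) seeded with
X0 = Y0 = 1e4, Z0 = 10, Type-W the remainder.  Default switch days are
the median progression-free survival under each first-line drug: day 307
(erlotinib-first) and day 567 (osimertinib-first); the horizon is 1000
days.  Everything is overridable through a YAML/JSON config whose omitted
fields fall back to these values.

## Scheduling and recurrence

`simulate_schedule` evaluates every output point by the closed form from
the phase-start state, so the output grid (default 1-day step, phase
boundaries always included) affects only what is reported, never
accuracy; `final_total` skips the grid entirely.  Schedules may hold any
number of contiguous phases, but the experiments exercise at most two, as
the clinical question poses it.

Recurrence is defined as the first day the total burden re-attains its
initial value after having been strictly below it (linearly interpolated
between grid points): regrowth to baseline after a treatment-induced
nadir.  No standard clinical definition maps exactly onto a
deterministic trajectory, so cross-strategy *ordering* of recurrence
times is the robust output; absolute days shift by tens of days under
alternative definitions (e.g. nadir-relative regrowth thresholds).

## Experiments

All experiments are pure functions of (rate table, initial state, grids)
and hence bit-reproducible.  Grid choices, all configurable:

* **Switch-time sweep** — integer switch days 1..999; reports finals,
  minimum and argmin.
* **Proportion sweep** — one resistant type's initial fraction varies
  (X, Y over 1e-8..1e-1; Z over 1e-9..1e-5) with 8 log-spaced points per
  decade plus the exact decade points; the other seeds stay standard and
  Type-W absorbs the remainder of the fixed 1e9 total.
* **Selection map** — 25×25 log-spaced grid of initial (X, Y) fractions
  over [1e-8, 1e-1]², Z0 fixed at 10; per cell the three strategies'
  day-1000 totals and the argmin label.  Finals within relative 1e-9 of
  the minimum count as ties and resolve by the fixed precedence
  B-first > A-first > C (arbitrary but documented; ties essentially never
  occur off exact-symmetry configurations).
* **Sensitivity grids** — one rate varies, everything else fixed: for
  sequential strategies a 2-D grid over the rate's value under the
  first-line (rows) and second-line (columns) regimen; for the
  combination a 1-D sweep under regimen C.  Growth-rate axes span the
  default ±0.1/day on 21 linear points (crossing the sign change);
  mutation-rate axes span 1e-9..1e-5/day on 17 log points, bracketing
  biologically plausible values.
* **Area composition** — rebuilds the map (default 15×15, coarser for
  speed) for each value of one perturbed rate (e.g. `a_B`) and reports
  each strategy's fraction of map cells.

"Essentially unchanged" claims are operationalised as relative change
below 1% (configurable `flat_threshold`); seeding-threshold claims are
order-of-magnitude statements and are tested as: within 10% of the
low-fraction plateau two decades below the nominal threshold, and ≥10%
above it one decade past it.

## Synthetic scenarios

The scenario generator emulates the study conditions for property
testing: growth-rate magnitudes uniform within ±50% of the defaults with
signs fixed by the resistance structure (under A only X and Z grow; under
B only Y and Z; under C only Z), one shared set of five mutation rates
drawn log-uniform from [1e-9, 1e-5]/day, and initial compositions with
log-uniform resistant fractions (X, Y in [1e-8, 1e-2]; Z in [1e-9, 1e-5])
on a 1e9-cell tumor.  Draws whose growth rates nearly coincide are
rejected (≤1000 tries) so the closed form always applies.  Randomness
uses NumPy's PCG64 `default_rng`, reproducible across platforms for a
fixed seed.  The generator deliberately does **not** emulate features of
real tumors outside the model — stochastic extinction of small clones,
density limitation, measurement noise, inter-patient rate heterogeneity
beyond ±50% — so passing property tests certify the solver and pipeline
on the model's own terms, not clinical predictive accuracy.

## Known limitations

* Exponential growth without carrying capacity inflates late-time
  burdens; conclusions are comparative (strategy A vs B vs C), not
  absolute tumor sizes.
* Deterministic dynamics cannot represent extinction of the 10-cell
  Type-Z seed; with fractional counts, resistance always eventually
  emerges.
* Switch days are fixed calendar days, not burden-triggered; adaptive
  scheduling is out of scope.
* The two monotherapy sweep minima sit on broad, flat plateaus, so the
  reported argmin day is numerically fragile even though the minimum
  value is stable.
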