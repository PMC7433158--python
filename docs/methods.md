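# Methods

## Model

The simulator advances a weekly discrete-time system of four stocks over a
52-week year: patients of interest (`S_Pi`), diagnosed patients (`S_Pd`),
patients in treatment (`S_Ptr`) and open cases (`S_Poc`). Flows between
stocks are fixed fractions applied after stage-specific delays:

```
S_Pi(n)  = ρ · NC(n) + S_Pi(n−1)                          ρ = 0.98
S_Pd(n)  = ρ · ( S_Pd(n−1) + r₁ · S_Pi(n−d1) )            r₁ = 0.30
S_Ptr(n) = S_Ptr(n−1) + r₂ · S_Pd(n−d2)                   r₂ = 0.30
S_Poc(n) = q · S_Pi(n) + c · S_Ptr(n−d3)                  q = 0.70, c = 0.50
S_Pi(0, year k) = γ · S_Poc(52, year k−1)                 γ = 0.50
```

Indices before week 0 read as 0 by default (each year is self-contained;
see "Cross-year lags" below). The system is linear in `(NC, carry-over)`
with no constant term, which the tests exploit: doubling all inputs doubles
every stock exactly in binary floating point, and trajectories are
monotone in arrivals.

### Lag versus forward reading

The published equations can be read with the delayed terms indexed either
into the past (`n−d`) or into the future (`n+d`). The future-indexed form
is acausal as a stepping rule, so the package defaults to the lag reading
(`lag_direction="lag"`); the forward reading is retained as
`lag_direction="forward"` and evaluated stage-wise (beyond-horizon indices
read as 0) for comparison. Only the lag reading supports the conserving
semantics and the microsimulation.

### State semantics

Two interpretations of the same narrative are provided:

- **literal** (default): the equations above verbatim. `S_Pi` and `S_Pd`
  behave as cumulative registers — cases are counted in every stage they
  have ever reached — so the stocks are process registers, not
  simultaneous head-counts.
- **conserving**: a stage-structured head-count reading in which each case
  occupies exactly one stage per week. Retained arrivals wait `d1` weeks,
  then leave the evaluation pool at geometric rate `r₁` per week; diagnosed
  cases wait `d2` weeks, then enter treatment at geometric rate `r₂`;
  treatment lasts `d3` weeks, after which a fraction `c` of completers
  joins the open register. At year end the remaining undiagnosed (fraction
  `q`) and all diagnosed-but-untreated cases move to the open register,
  and a fraction `γ` of the register re-enters the next year.

The conserving stepper is, by construction, the exact expectation of the
agent microsimulation: the geometric stage-exit times are memoryless, so
scalar eligibility pools are sufficient statistics, and averaging the
stepper over the delay grid `d1 ∈ {2,3,4} × d2 ∈ {1,2}` (six equally
weighted combinations) matches agents that sample their delays uniformly —
exactly, by linearity of expectation. The test suite verifies this against
an independent pathway-enumeration oracle to 1e-12 and against 500 seeded
agent replicates within three standard errors at every week.

### Agent microsimulation

Each arriving case draws, from a single seeded `numpy` generator in arrival
order: a dropout Bernoulli(1−ρ); an evaluation delay `d1` and geometric
diagnosis week; a `d2` delay and geometric treatment-entry week; a fixed
(optionally uniform) treatment spell; a Bernoulli(q) year-end referral to
the open register if never diagnosed; and a Bernoulli(c) flag for remaining
open after completing treatment. Terminal statuses are `dropped_out`,
`open_no_treatment`, `in_treatment`, `closed` and `referred_external`.
Variant switches (`delay_sampling`, `diagnosis_mode`, `treatment_duration`)
expose simpler behaviours for testing.

### Capacity stress

`CapacitySpec` caps the weekly evaluation and treatment-entry flows at
`sessions_per_week × cases_per_session` (default: 40 evaluation sessions,
unbounded treatment). Flow above a cap overflows to external services and
leaves the system; with `queue_overflow=True` it is instead queued into the
next week's demand. At every week `served + overflow = demand` holds
exactly, and an unbounded specification reproduces the unconstrained run
bit for bit because both paths execute the same arithmetic.

### Steady state

With self-contained years the map from one year's final open cases to the
next is exactly affine, `Poc' = a·Poc + b`. `identify_annual_map` recovers
`(a, b)` from two probe runs (carry-over 0 and 1) and verifies affinity at
a third point; `find_stationary_state` returns the fixed point `b/(1−a)`
with a stability flag (`|a| < 1`). For configurations where the map is not
affine (capacity caps with short treatment spells), `solve_stationary`
falls back to damped fixed-point iteration (damping 0.5, tolerance 1e-9,
at most 10,000 iterations). Under the defaults `a = 0.35` — the product of
the carry-over, retention-like and open-register fractions along the
dominant path — so the map is strongly contractive and 30 chained years
reach the fixed point within 1e-6.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `retention_after_dropout` ρ | 0.98 | 2% of referred cases drop out |
| `diagnosis_fraction` r₁ | 0.30 | weekly completion of evaluation |
| `treatment_entry_fraction` r₂ | 0.30 | weekly entry into treatment |
| `nondiagnosed_to_open_fraction` q | 0.70 | undiagnosed kept on register |
| `completed_to_open_fraction` c | 0.50 | completers remaining open |
| `year_carryover_fraction` γ | 0.50 | register re-entering next year |
| `d1` | 3 (∈ {2,3,4}) | evaluation delay, weeks |
| `d2` | 1 (∈ {1,2}) | diagnosis → treatment delay, weeks |
| `d3` | 52 | treatment duration, weeks |
| `weeks_per_year` | 52 | horizon of one simulated year |

Dropout outside 2–5% and progression fractions outside 25–30% are accepted
but raise a `ParameterRangeWarning`, since they leave the narrative range
the defaults were taken from. `d1`, `d2` are restricted to their documented
sets; other structural violations raise `ValueError` naming the field.

### Cross-year lags

A delayed term near the start of a year can either read 0 (self-contained
years, the default) or resolve into the tail of the previous year
(`carry_lags_across_years=True`). The self-contained default was chosen
because it makes the annual map exactly affine and therefore makes the
identified fixed point consistent with long chained runs; the tail-reading
variant is retained for sensitivity analysis.

## Synthetic arrival generator

`ArrivalGenSpec` draws each week's new cases as independent
Poisson(445/52) variates, optionally modulated by normalized seasonality
weights. It emulates only the aggregate intake rate of the service — the
reported ~445 new cases per year spread over the year — and not referral
sources, age structure, diagnosis mix, or within-year autocorrelation. The
bundled census fixture records the three catchment municipal communities'
2001 and 2011 populations (314,876 total in 2011).

## Numerical choices

- Pure float64 arithmetic; no linear-algebra solves are needed because the
  yearly kernel is a short explicit recursion.
- Exact equality is asserted only where IEEE-754 guarantees it: doubling by
  a power of two, identical arithmetic paths (uncapped stress), and the
  year-boundary expression. Property-based tests sample fractions on a
  1/1000 grid so intermediate products stay in the normal float range,
  where power-of-two scaling is lossless; comparisons against the
  independent oracles use 1e-9 absolute tolerance.
- Seeded reproducibility everywhere: replicate seeds derive from one
  `numpy.random.default_rng(seed)`, and identical configurations reproduce
  output files byte for byte (CSV floats printed with `%.12g`).

## Limitations

- Fractions and delays are constant in time; no age, severity or diagnosis
  heterogeneity.
- The literal semantics is a register model, not a head-count model; the
  two deliberately diverge (e.g. dropout handling) and are both exposed.
- Capacity stress models throughput caps only, not staff scheduling or
  session length.
- The steady-state analysis assumes a repeating annual arrival schedule.
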