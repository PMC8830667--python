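# Methods

## The model

vaxcov estimates how a change in vaccine presentation (the physical and
logistical form of a vaccine: storage requirements, administration method,
container size, schedule fit, acceptability, dose count) would change the
vaccination coverage rate of a population. Coverage is modelled as the
probability of clearing a set of *technology-addressable barriers*: an
individual is vaccinated only if they overcome every barrier, once per
required dose.

For a population with per-barrier failure prevalences
`p = (p_1, …, p_n)` and a presentation with technology scores
`v = (v_1, …, v_n)` and dose count `D`, the **uncalibrated coverage** is

```
U = ( ∏_i [ 1 − p_i (1 − v_i) ] )^D
```

`p_i` is the probability of *not* overcoming barrier `i` with no
technology help; `v_i` scales that failure probability down, to zero when
the barrier is fully neutralised. Barriers are assumed independent of one
another and doses independent of each other with a constant per-dose
probability — both are simplifying assumptions; see Limitations.

`U` only accounts for technology-addressable barriers, so it is mapped
onto the observed coverage scale by a **linear calibration**
`C = S·U + β` anchored at two points:

- the *calibration vaccine*: a presentation already deployed in the
  population, with observed coverage `C_c` and computed uncalibrated
  coverage `U_c`;
- the *perfect presentation*: `U = 1` by construction, whose calibrated
  coverage is the population's maximum technology-achievable coverage
  `M` (an input — typically the best coverage any vaccine achieves in
  that population, since the remainder reflects non-technology barriers).

Hence `S = (M − C_c)/(1 − U_c)` and `β = C_c − S·U_c`. The estimate for a
test presentation is reported in headroom form

```
C_t = M − k·x_t,   k = M − C_l,   x_t = 1 − (U_t − U_l)/(1 − U_l)
```

where `C_l = S·U_l + β` and `U_l` is the uncalibrated coverage of the
*least desirable* presentation (all scores zero, maximal dose count
`d_worst`). `k` is the coverage headroom technology can move; `x_t` is the
residual failure probability of the test presentation net of that
baseline.

**An algebraic identity worth knowing:** because `M = S·1 + β`, the
headroom form collapses to `C_t = S·U_t + β` exactly. Two consequences
the test suite exploits: estimating the calibration presentation itself
returns `C_c` identically, and `C_t` does not depend on `U_l` (so
sweeping `d_worst` leaves `C_t` unchanged — `k` and `x_t` move, their
product's effect does not). `k` and `x_t` remain useful diagnostics and
are always reported in the audit trail.

## Validity and the exclusion rule

`C_t > 1` is possible only when `M > 1`. Reported administrative coverage
does exceed 100% in practice (denominator problems), and when a
high-coverage vaccine defines `M` while the calibration vaccine lags far
behind, the fitted slope is large and the estimate can overshoot. This is
a model-misuse signal, not a number to clamp: such estimates are flagged
invalid, excluded from multi-region aggregates, and the excluded share of
the total birth cohort is always reported. `fit_calibration` therefore
accepts `M > 1`; it rejects `C_c > M` (the ceiling must be a ceiling),
`U_c = 1` (vertical calibration line — pick a different calibration
vaccine), and `U_l > U_c` (a least-desirable presentation that outperforms
the deployed one is mis-specified).

## Technology scores: the rubric

Each barrier has a five-level categorical scale (Low, Medium-Low, Medium,
Medium-High, High) mapped to numeric scores. The shipped defaults:

| barrier              | Low | Med-Low | Med | Med-High | High |
|----------------------|-----|---------|-----|----------|------|
| vaccine_schedule     | 0   | 0.25    | 0.50| 0.75     | 1    |
| temperature_storage  | 0   | 0.25    | 0.50| 0.80     | 1    |
| administration       | 0   | 0.40    | 0.70| 0.90     | 1    |
| acceptability (generic)      | 0 | 0.30 | 0.40| 0.70   | 1    |
| acceptability (pork_product) | 0 | 0.75 | 0.90| 0.95   | 1    |
| doses_per_container  | 0   | 0.20    | 0.40| 0.75     | 1    |

These are expert judgements, so they ship as data (CSV), not code; any
replacement rubric is validated (five levels per barrier/variant, scores
in [0, 1], non-decreasing Low→High). Acceptability has two variants
because which concern applies (a generic acceptability issue vs. the
presence of a pork product in manufacture) is an analysis choice the
presentation spec must name. Dose requirements are handled through the
dose count `D`, not as a vector entry.

## Population scores: priority fallback

Barrier prevalences come from proxy indicators organised in a priority
hierarchy (priority 1 = closest to the ideal definition). Resolution
takes the smallest-priority non-missing value and records which priority
served, so every profile carries provenance. Missingness is an explicit
marker — a recorded 0 means "barrier absent", which is informative.
Duplicate priorities for one region/barrier pair are an input error.
Indicators whose source reports the *pass* probability set a `complement`
flag rather than the caller guessing polarity.
`subregion_weighted_average` provides population-weighted roll-ups when
only sub-region data exist.

## Channels, aggregation, equity

Routine immunisation and campaign (SIA) delivery can be modelled as two
channels with region-specific shares. A barrier not applicable in a
channel (e.g. schedule compliance during a campaign) is treated as absent
for that channel's population — effective `p_i = 0`, a population
property, not a technology one. The full calibration runs per channel and
`C_t` is the share-weighted mean of the per-channel estimates (averaging
the final estimates, not intermediates, is a choice; the per-channel
intermediates are all in the audit log).

Multi-region aggregates are birth-cohort-weighted means over valid
regions; the additional-vaccinated count is `Σ (C_t − C_c)·births`.
Sub-national equity per country is `E = 1 − Σ_i (max(c) − c_i)/(r − 1)`
over the `r ≥ 2` regional estimates: 1 means perfectly even coverage.
Rankings sort by percentage-point gain, ties broken by region id for
determinism.

## Sensitivity sweeps

Up to three global parameters (`M`, `C_c`, `d_worst`) can be swept over
explicit grids; each grid point is a full re-fit, output in long format.
`M` and `C_c` overrides replace every region's value — a deliberate
simplification for what-if analysis, since region-specific grids would
explode the config surface.

## The synthetic generator

Real inputs (national coverage estimates, facility and household surveys,
demographic tables) cannot be redistributed, so `synthetic_data` draws an
internally consistent stand-in. Defaults describe a 73-country cohort:
per-barrier prevalences uniform within plausible low/middle-income ranges
(schedule 0.05–0.60, cold chain 0.05–0.60, administration 0.05–0.50,
acceptability 0–0.40, vial-opening refusal 0–0.15), calibration coverage
`C_c ~ U(0.40, 0.92)`, ceiling `M = min(C_c + U(0.02, 0.15), 1)`, birth
cohorts 20 k–5 M, routine-channel share 0.60–1.00, and a two-priority
indicator hierarchy with 30% missingness at priority 1 and a guaranteed
priority-2 fallback (the complement of the same quantity, exercising the
polarity flag). All draws are uniform — no distributional guidance exists
for these quantities and uniform maximises edge coverage — and a fixed
seed reproduces byte-identical files.

Two optional modes exist for testing specific mechanisms:
`overreported_m_rate` gives a fraction of regions a ceiling drawn from
`U(1.10, 1.35)` (administrative over-reporting) so the exclusion path is
reachable; `calibration_truth` draws a slope/intercept pair per region and
constructs `C_c = S·U_c + β`, `M = S + β`, emitting the truth table so
refitting must recover `(S, β)` to float precision.

What the generator does *not* emulate: correlation between barriers and
coverage across countries, non-uniform marginals, sub-national
heterogeneity structure, or measurement error in proxies. Passing tests
on synthetic data therefore demonstrate the machinery's correctness and
internal consistency, not the realism of any particular coverage number.

## The agent-level Monte-Carlo oracle

`simulate_agents` simulates individuals who must clear every barrier for
each dose (barrier `i` cleared with probability `1 − p_i(1 − v_i)`). At
`correlation = 0` all clearances are independent and the empirical
fraction matches the closed form within binomial error (tests assert
within 4 standard errors at n = 100 000). At `correlation > 0` failures
are positively coupled through a single standard-normal frailty factor
shared across all of an agent's draws (Gaussian copula with the exact
marginal failure probabilities). With no technology help, coupling
concentrates failures in the same agents and raises coverage relative to
independence — tests document this direction empirically per seed. The
correlation knob is a probe of the independence assumption, never part of
the analytic path.

## Numerical choices

- All probabilities are fractions in [0, 1] internally; percent
  formatting (one decimal) and count rounding (half-even) happen only in
  `summary()` and the report files.
- Dose counts are integers ≥ 1; fractional "expected doses" are rejected.
- Channel shares must sum to 1 within 1e−9.
- Test tolerances: 1e−12 for anchor/algebraic identities, 1e−9 for
  composed floating-point pipelines, 4 binomial standard errors for
  Monte-Carlo agreement.
- Degenerate inputs raise typed validation errors naming the offending
  field rather than producing NaN or infinity.
- Problem sizes: property tests run a few hundred randomised cases;
  identity checks use 10 000 random contexts; enumeration checks cover
  full 5-point grids up to 3 barriers and 4 doses (2^12 outcomes per
  case, chunked); end-to-end runs use 73 synthetic countries.

## Known limitations

- Barrier independence and the constant per-dose probability are
  structural assumptions; calibration absorbs some, not all, of the
  resulting bias, and the correlation knob only characterises its
  direction.
- The linear calibration is anchored at two points; far from the
  calibration vaccine the linearity assumption is untested.
- The rubric defaults are judgement-based; the package treats them as
  replaceable data for exactly that reason.
- `M`, channel shares and the proxy-indicator polarity are user inputs
  the model cannot validate against ground truth.
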