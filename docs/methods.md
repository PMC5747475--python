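# Methods

## Model

A kidney-transplant waitlist candidate is modeled as a continuous-time
stochastic process `X(t)` on 16 states: 12 transient states formed by
crossing six CPRA categories (0%, 1–79%, 80–89%, 90–94%, 95–98%, 99–100%)
with active/inactive status, plus four absorbing outcomes (deceased-donor
transplant, living-donor transplant, death/deteriorated, other removal).
The clock is **days since listing** (clock-forward): the process is assumed
Markov in elapsed time from the listing origin, i.e. time-inhomogeneous but
with no further dependence on history.  The category breakpoints follow US
allocation policy (priority points at 80%+, regional/national priority at
99/100%), which is also why a priority-rule change is expected to act on
specific CPRA bands.

Transitions are allowed between every ordered pair of transient states and
from every transient state to every absorbing state, **except** the six
inactive → deceased-donor entries: inactive candidates do not receive
deceased-donor offers, so that hazard is structurally zero (12·15 − 6 = 174
transitions).  Note that the transition *probability* from an inactive state
into deceased-donor transplant is still positive — it flows through
reactivation — only the direct hazard is constrained.

### Assumptions, stated bluntly

* **Markov in t-since-listing.**  Dynamic prediction "given history through
  day s" therefore reduces to "given the state at day s".  Duration-in-state
  effects (semi-Markov behavior) are not modeled.
* **Independent right censoring**, including the deliberate censoring at a
  policy date: the censored are assumed exchangeable with those who remain.
* **No covariates in the intensities.**  Subgroups (race, blood group, ...)
  are handled by filtering records and refitting, not by regression;
  semi-parametric covariate adjustment is out of scope.

## Estimation

From the long-format table (one at-risk row per allowed transition per state
interval), the counting processes are `Y_i(u)` — intervals with
`t_start < u ≤ t_stop` in state i — and `dN_ij(u)` — realized i→j
transitions at u.

* Nelson–Aalen: `Â_ij(t) = Σ_{u≤t} dN_ij(u)/Y_i(u)`.
* Aalen–Johansen: `P̂(s,t) = Π_{u∈(s,t]} (I + dÂ(u))`, where each factor
  carries all transitions observed at u (ties enter one factor, keeping row
  sums exactly 1), off-diagonals `dN_ij/Y_i`, diagonals minus the row sum,
  absorbing rows zero.  The grid is the union of event times and requested
  report times; all curves are right-continuous step functions.
* Variances: the Greenwood-type hazard increment
  `dN_ij (Y_i − dN_ij)/Y_i³` (a Poisson-type `dN/Y²` flag exists for
  sensitivity checks), with within-row multinomial covariances
  `(δ_jl Y_i dN_ij − dN_ij dN_il)/Y_i³`.  The full 256×256 covariance of
  `vec P̂(s,t)` is propagated through each product factor by the delta
  method; in the two-state reduction this reproduces the classical
  Greenwood formula exactly (verified to 1e-12 in the tests).
* Confidence bands: pointwise normal approximation, linear scale truncated
  to [0,1] by default (the common default of established multi-state
  software); log-transformed bands are available.  Which scale published
  analyses used is generally not stated, so both are provided.

Two-cohort contrasts (e.g. before/after a policy change) are reported as
paired estimates with a CI-overlap flag; no formal two-sample test is
constructed, since overlap is how such figures are conventionally read.

## Censoring schemes

`CensoringScheme` supports an administrative horizon and, independently,
censoring at a calendar policy date (default 2014-12-04, configurable),
converted per subject to days since listing.  Censor-at-policy truncates the
trajectory and converts later terminal events to censorings; lifting the
censoring simply ignores the policy date.  Truncation is idempotent, and the
policy-censored fit is byte-identical to fitting manually truncated records
(tested).  The administrative horizon of a lifted-censoring analysis is a
config value, since data-pull dates vary by extract.

## Synthetic cohorts

Real registry extracts require a data-use agreement, so cohorts are
simulated from a piecewise-constant-intensity Markov process on the same
174-transition structure — rich enough to exercise time-inhomogeneity while
admitting an exact oracle, `P(s,t) = Π_p exp(Δ_p Q_p)`.  Sampling is exact:
holding times by inversion of the piecewise-constant exit intensity,
destinations proportional to rates at the jump instant, one seeded stream
consumed in documented per-subject order (initial state, listing-date
offset, covariates, censoring draw, alternating holding/destination draws).
A fixed seed reproduces the cohort byte-for-byte.

Continuous-time paths are encoded into registry-like records on an
**integer-day grid** (registry resolution): jump days are `ceil(t)`, bumped
forward a day on collision so the day sequence is strictly increasing and
the encoded record re-derives to exactly the simulated jump sequence (the
round trip is tested).  Distributional checks of the sampler target the
continuous-time paths directly.

Two stock scenarios (rates per day, chosen once at realistic registry
magnitudes; they are illustrative, not estimates):

* `default_scenario` — registry-shaped: ~98% of initial mass in the two
  lowest CPRA categories, 85% listed active, deceased-donor intensity
  1e-4–4e-4 falling with CPRA (a pre-reform pattern), death intensity
  1.2e-4 active vs 3.5e-4 inactive, inactivation 8e-4, reactivation 1.6e-3,
  CPRA moves mostly adjacent (2e-4 vs 2e-5), light exponential dropout
  (2e-4), three-year horizon.
* `validation_scenario` — estimator validation: uniform initial mass over
  all 12 states so every row of `P̂(0,t)` is informed, rates at the high end
  of realistic magnitudes (deceased-donor 6e-4–1e-3, death 5e-4/1e-3,
  reactivation 2.5e-3) to give informative event counts at n ≈ 1,000,
  two-year horizon.

What the simulator deliberately does **not** emulate: duration-dependent
(semi-Markov) intensities, covariate-dependent intensities, the allocation
mechanism itself, multiple listings, or missing/erroneous registry fields
beyond a missing-CPRA-at-listing flag.  Passing tests therefore demonstrate
estimator correctness under the model's own assumptions, not robustness to
their violation in real registry data.

## Numerical choices

* Ties: all events at one time share one product factor (exact row sums).
* `Y_i(u) = 0` with events is impossible by construction and raises.
* Zero-length intervals are dropped with a warning; a terminal event on the
  listing day is shifted to day 0.5 so the subject contributes risk time.
* Same-day updates merge into a single combined transition (daily registry
  resolution); a CPRA update within its category creates no interval.
* Missing CPRA at listing maps to 0% with a logged flag (configurable).
* Fractional CPRA floors to an integer percent before categorization, so
  values in (0,1) fall in the 0% category.
* Matrix exponentials via `scipy.linalg.expm`; probabilities conserve row
  sums to ~1e-15 because each factor is exactly row-stochastic.

## Validation design and known limitations

The estimators are validated three ways: exact small-sample oracles
(brute-force `(I+dÂ)` products; Kaplan–Meier, cumulative-incidence and
closed-form Greenwood reductions, cross-checked against lifelines),
structural invariants (row sums, Chapman–Kolmogorov, monotone absorbing
columns, forbidden-hazard zero), and Monte-Carlo recovery of known
generating intensities against the matrix-exponential oracle with
interval-coverage checks over seeded replicates (problem sizes: one cohort
of 5,000 for point recovery; 50 replicates of 1,000 for coverage).

On sup-norm recovery, note the information budget: with 12 transient states,
each row of `P̂(0,365)` rests on roughly n/12 subjects, so at n = 5,000 the
per-entry sampling noise is ~0.01–0.02 and the *maximum* error over all
entries concentrates around 0.04–0.06 even for a perfectly specified
estimator; sup-norm agreement much below that requires cohort sizes an
order of magnitude larger.  Bias is negligible (verified by fitting on
exact continuous-time paths).

Linear confidence bands undercover slightly for small-probability entries
(observed pooled coverage ≈ 92–93% at nominal 95% with ~85 subjects per
initial state); log bands improve this at the cost of asymmetry.  The
variance recursion is exact for the delta method but, like all Greenwood
variants, is itself noisy when risk sets shrink below ~20.
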