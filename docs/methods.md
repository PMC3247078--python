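# Methods

This note records the model, the numerical choices and their
rationale, and what the packaged tests do and do not establish.

## The switch and its macrostates

The core object is a two-species positive-feedback circuit: transcript
X is produced at a basal rate `k1` plus a Hill-type activation by Y,
transcript Y is produced by a Hill-type activation by X, and both decay
linearly.  All kinetic parameters are rates per minute and amounts are
copy numbers; the nominal set is

| parameter | value | meaning |
|---|---|---|
| `k1` | 0.055 /min | basal X production (~3.3 transcripts/h) |
| `V1 = V2` | 0.55 /min | maximal feedback production (~33 transcripts/h) |
| `M1 = M2` | 25 | half-saturation copy number |
| `h` | 3 | Hill coefficient (real-valued; scans use non-integer values) |
| `u1 = u2` | 0.01 /min | degradation (~70 min transcript half-life) |

With these values the deterministic system has a low stable point
(≈ (5.5, 0.6)), a saddle (≈ (19.3, 17.4)) and a high stable point
(≈ (54.4, 50.1)).  The macrostate threshold `L = 55` on `x + y`
separates the basins; the boundary `x + y = L` itself is classified
*on*.  The off/on regions as defined overlap on that line, and
absorbing semantics need an unambiguous rule: a cell that reaches the
threshold has initiated the (irreversible) transformation.

Equilibria are found by multi-start Newton iteration (`scipy`'s hybr)
seeded from a 14×14 grid over the invariant box
`[0, (k1+V1)/u1] × [0, V2/u2]`, de-duplicated at 1e-3 copies, accepted
at RHS norm < 1e-9, and classified by the Jacobian spectrum with a
1e-12 tolerance on zero real parts (ties are flagged `degenerate`
rather than silently classified).  A brute-force nullcline-composition
scan at 0.05-copy resolution serves as the independent oracle in the
tests.

## Absorbing Markov model

Microstates are integer pairs with `x + y <= B`; every production event
that would leave the region is redirected to a single absorbing *on*
state.  Propensities are literally the deterministic rate laws — the
network is not given by elementary mass-action reactions, and the
rate-law (Rao–Arkin style) propensity approximation is used throughout,
consistently in the master equation and in the Gillespie simulation.

The default boundary is `B = L = 55`, giving 1596 off-states + 1
absorbing state (n = 1597).  `B` is configurable and the headline
numbers are demonstrated to be boundary-insensitive over
`B ∈ {54, 55, 56}` (half-life 5.91 / 5.94 / 5.96 years); no finer
truncation control (e.g. finite-state-projection error bounds) is
attempted.

Dominant mode.  All eigenvalues of the non-absorbing block lie strictly
in the left half-plane (the block is an irreducible, diagonally
dominant Metzler matrix), and the rightmost eigenvalue λ1 is real and
simple with a positive eigenvector.  Two solvers are provided:

* dense full-spectrum (`scipy.linalg.eig`), the robust reference,
  ~2 s at n ≈ 1600;
* sparse shift-invert Arnoldi around σ = 0 (λ1 is the eigenvalue of
  smallest modulus), with a fixed all-ones start vector for
  determinism, ~20 ms.

The default picks sparse above n = 300; the two agree to < 1e-12
relative at n = 1597 (asserted in the tests).  One numerical caveat:
the true Perron eigenvector spans > 20 orders of magnitude, so entries
below ~eps times the largest entry underflow; positivity is enforced
(and tested) on every resolvable entry, and the solver raises if any
entry is genuinely negative beyond -1e-10 of the maximum.

Transient solution.  `solve_cme` integrates `dP/dt = AP` either by
dense matrix exponentials between output times (exact; used for small
spaces) or by the BDF stiff integrator with the sparse generator as
Jacobian (rtol 1e-8, atol 1e-12); the two agree to 1e-6 componentwise
at small truncations.  Output times are log-spaced over 1e-3–200 years
to resolve both the minute-scale transient and the year-scale tail.
The initial condition is a point mass at the integer state nearest the
low attractor — (6, 1) at nominal parameters — modelling cells born in
the off steady state.  A linear regression of `log p_off` over the last
decade of the grid recovers the spectral decay rate to 0.5% and a
prefactor `c1 ≈ 0.97`, confirming the single-exponential tail.

Time units: one year = 525600 minutes (365 × 1440), applied once at the
reporting boundary.

## Gillespie simulation

Direct-method SSA with the same propensities; X-production merges the
basal and feedback channels (identical unit step).  Hill terms are
table-lookups over the copy-number axis (extended on demand), which
makes the pure-Python event loop fast enough for the packaged
protocols (~5×10⁵ events/s).  Three boundary modes: `free` (untruncated),
`absorbing(B)` (first-passage sampling) and `reflecting(B)` (truncated
conservative network whose stationary law — the null vector of the
reflecting generator — is the oracle for occupancy tests).  Replicate
r of a set uses seed `seed + r`, so sets are reproducible and
order-independent.

The full stationary protocol behind the published histogram
(500 realizations × 300 years ≈ 5×10⁷ retained samples) is ~10⁷
reaction events per realization and is not a desk-scale test; it
remains available behind `switchpool simulate --full`.  The packaged
check uses 20 realizations × 3 years with 0.25 y burn-in, half started
at each deterministic attractor, and verifies that the two occupancy
modes fall within 5 copies of the attractors.  Because the scaled run
samples local occupancy rather than the fully mixed stationary law,
the *relative* mass of the two modes is start-dependent and is not
asserted — only the mode locations are.  Histograms are time-weighted
(holding-time) occupancies, normalized to total retained time.

First-passage validation uses a literally reduced barrier: nominal
kinetics with absorbing boundary B = 20, where the mean absorption
time (~3×10⁴ minutes) is Monte-Carlo accessible; the empirical
exponential rate must bracket |λ1| of the matched B = 20 generator
within 3 standard errors.

## Pool statistics

`N_r(t) ~ Binomial(N0, p_off(t))` under cell independence (explicit
assumption of this module; interactions live only in the feedback
model).  The depletion-time CDF is the binomial CDF evaluated at `Nd`
along the `p_on(t)` curve.  Between CME output points `p_off` is
interpolated linearly in the log (the decay is exponential there); the
density comes from central differences on a 4001-point bracketing grid
and moments from trapezoidal quadrature.

Exact binomial CDF evaluation (`scipy.stats.binom`) is the reference
path.  For large pools (N0 > 1e4) a continuity-corrected normal
approximation is used in the sweep — with the first Edgeworth
(skewness) term, because at the crossing σ ≈ 32 and the plain normal
approximation is off by ~2×10⁻³ while the corrected one is ~1×10⁻⁵
(the packaged bound is 1e-4, asserted against the exact path).

Nominal results: E[Td] = 59.18 y, sd = 0.271 y, and the log-ratio
approximation ln(N0/Nd)/|λ1| = 59.18 y agrees with the full
computation to well under 2%.

## Delayed-feedback population model

Suppression enters through the basal rate,
`k1(n2) = k1_max * Kn / (Kn + n2)` (nominal `k1_max = 0.06`/min,
`Kn = 8.2e4`, τ = 0.4 y, N0 = 1e6), and through it λ1 becomes a
function of the growing-follicle count.

Rate map.  λ1 is tabulated at 41 grid points (0 plus log-spaced to N0),
each an exact eigensolve of the rebuilt generator, and interpolated by
PCHIP in log–log coordinates (log|λ1| vs log(1+n2)): |λ1| spans ~6
orders of magnitude over the grid, and monotone cubic interpolation of
the raw values would lose all relative accuracy at the suppressed end.
Held-out grid points are reproduced to < 1%.  Below ~1e-9/year the
eigenvalue is smaller than the solver's absolute accuracy
(eps·‖A‖); such rates are floored at 1e-12/year and ironed monotone —
they correspond to ≪ 1 initiation per pool lifetime and are
dynamically irrelevant.

Integrator.  The growing compartment is a pure conveyor with residence
exactly τ, so `n2(t)` equals the integral of the inflow
`I(t) = |λ1(n2)| n1` over the trailing window of length τ, and the
outflow is identically zero for t < τ (nothing has completed its
residence; equivalently `n1 + n2 = N0` before the first cohort exits —
this identity holds to machine precision in the scheme).  The
integrator stores I on a fixed grid commensurate with τ (default step
τ/20), recovers n2 by a moving trapezoidal quadrature of that history,
and advances n1 by an iterated trapezoidal corrector; the stored
inflow value is exactly the one used in both updates, which makes the
discrete mass balance `n1 + n2 + exited = N0` exact and keeps n2
non-negative by construction.  This matters because the early
transient is pulsatile with period ~τ (inflow bursts, suppression
overshoots, the delayed outflow releases it); a naive method-of-steps
update that clamps n2 at zero during these pulses degrades to
first-order convergence and misses the depletion time by years at
practical steps.  With the quadrature form, halving the step from the
default changes Td by < 0.01 y.  The τ = 0 limit (outflow cancels
inflow instantly, single-exponential decline at the unsuppressed rate)
is handled analytically and asserted exactly.

Nominal depletion (n1 ≤ 10³) occurs at 49.11 years, and the model
intrinsically produces the accelerating decline near age ~38 as
suppression unwinds.

## Sensitivity scans and robustness

One-at-a-time multiplicative factors {0.8, 0.9, 0.95, 1.05, 1.1, 1.3}
on each parameter group (paired parameters V1/V2, u1/u2, M1/M2 scaled
jointly; `h` scaled continuously).  Single-cell entries recompute the
full generator and use `ln(N0/Nd)/|λ1|`; population entries rebuild
the λ1(n2) map and integrate the delay model.  Population entries
above 500 years are *reported* as ">500" (the table convention) but
the underlying crossing is still integrated (up to 3000 y) so that
fold-changes can be compared honestly.  Perturbed parameter sets that
lose bistability are flagged, not dropped.  The robustness property —
for every shared kinetic parameter the 0.9→1.1 fold-change in Td is
smaller with feedback than without — holds with large margins
(e.g. u: 284× vs 22×; M: 1609× vs 93×).

The middle columns (0.9–1.1) of both tables are tightly reproducible;
the extreme corners (0.8, 1.3) amplify the truncation-boundary
convention by the row's own sensitivity and should be read as
order-of-magnitude entries.

## Synthetic cohort

No individual-level clinical data ship with the package; the cohort
generator emulates the two kinds of observations the model is compared
against.  Parameter heterogeneity across individuals is lognormal
with mean-one factors, independent across parameter groups — a minimal
positivity-preserving choice for "genetic variation in kinetics" with
no distributional information to constrain it.  By default only the
degradation rates vary.  Each individual's depletion age comes from
the full feedback model with a per-individual rate map; individuals
whose perturbed switch loses bistability are excluded and counted.
Count observations are `n1(age) · exp(ε)`, ε ~ N(0, σ²) with σ = 0.3
by default: clinical follicle counts span orders of magnitude and
scatter roughly uniformly on a log axis.

A 2% CV on u spreads depletion ages by tens of years (the per-unit-CV
sensitivity to u is >10× that to the population parameter Kn even at
10× the CV); a 0.6% CV reproduces the clinically reported
menopause-age sd of ≈ 3.8 years while keeping the cohort mean near the
base model's 49 years.  What the generator does *not* emulate:
within-individual count-measurement error structure, age-dependent
ascertainment, correlated parameter variation, or any real genetic
architecture — passing cohort tests shows the mechanism's
order-of-magnitude plausibility, not agreement with actual clinical
distributions.

## Problem sizes and limitations

Packaged tests and the acceptance script use: the full n = 1597 state
space for every eigenvalue and transient computation; B ≤ 12 spaces
for integrator and SSA-vs-CME cross-checks; 20×3-year SSA runs for the
stationary histogram; 80–200 Monte-Carlo first-passage replicates; and
40-point rate maps for the population model.  Known limitations: the
truncation convention of the original state-space dimension is
ambiguous (a plausible alternative reading gives n = 1653; boundary
insensitivity over B ∈ {54, 55, 56} is demonstrated instead); the
model has no multi-stage follicle development, no endocrine input, no
atresia/ovulation split beyond the fixed residence time; and the
identification of the two transcripts with specific ovarian factors
(KITL and KGF/HGF) is a labelling hypothesis, not a fitted claim.
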