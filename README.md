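# switchpool

How do gene-regulatory events that take minutes produce physiology that
unfolds over decades?  `switchpool` implements a multi-scale model in
which the answer is a *stochastic bistable switch*: a two-transcript
positive-feedback circuit whose rare, fluctuation-driven transitions
from its low (*off*) to its high (*on*) expression state set a
years-to-decades time constant at the tissue level.  The case study is
growth initiation of ovarian follicles — each resting (primordial)
follicle carries an independent copy of the switch, switching *on*
irreversibly commits it to growth, and depletion of the pool to ~10³
follicles marks the onset of menopause.

The package is aimed at systems biologists and modellers who want a
tested, reproducible implementation of the full chain: deterministic
switch analysis → absorbing Markov/master-equation model → dominant
switching rate → binomial pool statistics → delayed-feedback population
dynamics → sensitivity scans → synthetic cohorts.

## Model

**Single cell.**  Transcript copy numbers $(x, y)$ obey

$$\dot x = k_1 + \frac{V_1 y^h}{M_1^h + y^h} - u_1 x, \qquad
  \dot y = \frac{V_2 x^h}{M_2^h + x^h} - u_2 y .$$

At the nominal kinetics ($k_1{=}0.055$, $V_{1,2}{=}0.55$,
$M_{1,2}{=}25$, $h{=}3$, $u_{1,2}{=}0.01$; rates per minute) the system
is bistable.  The cell is *off* while $x + y < L$ ($L = 55$) and *on*
once $x + y \ge L$, irreversibly.

**Stochastic switching.**  On the integer lattice the same rate laws
act as propensities of a Markov jump process.  Collapsing the on-region
into one absorbing state gives a finite master equation
$\dot P = A P$ with a $1597 \times 1597$ generator (boundary $B = 55$).
All eigenvalues of the non-absorbing block $A_{\mathrm{rev}}$ lie in
the open left half-plane and the rightmost, $\lambda_1$, is real and
simple with positive eigenvector, so the survival probability decays as
$p_{\mathrm{off}}(t) \approx c_1 e^{\lambda_1 t}$.  Numerically
$\ln 2 / |\lambda_1| \approx 5.9$ years — a molecular circuit with
minute-scale kinetics yields a year-scale stochastic clock.

**Pool of cells.**  For $N_0 = 10^6$ independent follicles the
remaining count is $N_r(t) \sim \mathrm{Bin}(N_0,\, 1 - p_{on}(t))$ and
the depletion time $T_d = \min\{t : N_r(t) \le N_d\}$ ($N_d = 10^3$)
has CDF $P(N_r(t) \le N_d)$.  The mean is $\approx 59$ years with a
standard deviation of only $\approx 0.27$ years, and is well
approximated by $\ln(N_0/N_d)/|\lambda_1|$.

**Population feedback.**  Growing follicles suppress initiation
(AMH-style): $k_1(n_2) = k_{1,\max} K_n / (K_n + n_2)$, making
$\lambda_1$ a function of the growing count $n_2$ inside the delay
system

$$\dot n_1 = -|\lambda_1(n_2)|\, n_1, \qquad
  \dot n_2 = |\lambda_1(n_2)|\, n_1 - \text{(inflow at } t - \tau).$$

With $k_{1,\max}{=}0.06$/min, $K_n{=}8.2\times10^4$, $\tau{=}0.4$ y the
pool depletes at ~50 years, and — the headline result — the depletion
age becomes far more robust to kinetic parameter variation than in the
feedback-free model.

## Worked example

```python
import switchpool as swp

params = swp.SwitchParameters.nominal()

# dominant switching mode of the absorbing Markov model
s = swp.lambda1(params, B=55)
print(f"lambda1 = {s.lambda1_per_year:.4f}/y, half-life = {s.half_life_years:.2f} y")

# master-equation transient and pool depletion statistics
sol = swp.pon_curve(params, B=55)
dep = swp.depletion_time_stats(sol.times_years, sol.p_on, swp.PoolConfig())
print(f"E[Td] = {dep.mean_years:.2f} y, sd = {dep.sd_years:.3f} y")

# delayed-feedback population model
fb = swp.FeedbackParameters.nominal()
td = swp.depletion_time(fb, Nd=1e3, rate_map=swp.build_rate_map(fb, B=55))
print(f"feedback-model depletion at {td:.2f} y")
```

prints

```
lambda1 = -0.1167/y, half-life = 5.94 y
E[Td] = 59.18 y, sd = 0.271 y
feedback-model depletion at 49.11 y
```

The half-life is the single-cell off→on stochastic clock; `E[Td]` is
the age at which the independent pool falls to 10³ cells (a ~59-year
mean with day-to-week-scale spread); the feedback model shifts the
depletion age to ~49 years and makes it robust.

The same stages are scripted as a narrative analysis under `analysis/`
(`01_switch_equilibria.py` … `07_synthetic_cohort.py`, each writing CSV/JSON
tables under `results/`) and exposed as a CLI:

```bash
switchpool equilibria
switchpool lambda1 --boundary 55
switchpool pool --N0 1000000 --Nd 1000
switchpool dde --tau-years 0.4
switchpool scan --model single_cell
```

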