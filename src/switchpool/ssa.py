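"""Exact Gillespie simulation of the stochastic switch.

Direct-method SSA over the integer lattice, with the same
non-elementary propensities as the master equation.  Three boundary
modes:

* ``free`` — the untruncated network (used for stationary statistics;
  the distribution is bimodal with peaks near the two deterministic
  attractors);
* ``absorbing`` — the run stops when a production event first takes
  x + y past the boundary B (first-passage sampling, matching the
  absorbing Markov model);
* ``reflecting`` — production events that would leave x + y <= B are
  rejected (finite truncated network whose stationary law is the null
  vector of the reflecting generator; used as a small-system oracle).

X-production combines the basal and feedback channels (v1 + v2) since
both produce the same unit step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .switch import SwitchParameters
from .units import MINUTES_PER_YEAR
from .cme import StateSpace, build_generator, enumerate_states

__all__ = [
    "SsaTrajectory",
    "FirstPassageSample",
    "simulate_ssa",
    "stationary_histogram",
    "estimate_first_passage",
    "reflecting_stationary",
]


@dataclass(frozen=True)
class SsaTrajectory:
    """One realization: event times (minutes) and visited microstates."""

    times_min: np.ndarray  # (E+1,) including t=0
    states: np.ndarray  # (E+1, 2) integer microstates
    seed: int
    mode: str
    B: int | None
    absorbed: bool  # True if the run ended by absorption


def _hill_table(v: float, M: float, h: float, cap: int) -> np.ndarray:
    s = np.arange(cap, dtype=float)
    return v * s**h / (M**h + s**h)


def simulate_ssa(
    params: SwitchParameters,
    init: tuple[int, int],
    t_max_min: float,
    seed: int,
    mode: str = "free",
    B: int | None = None,
    record: bool = True,
) -> SsaTrajectory:
    """Direct-method SSA from ``init`` until ``t_max_min`` (or absorption).

    Bit-reproducible for a fixed seed.  With ``record=False`` only the
    initial and final states are kept (first-passage use).
    """
    if t_max_min <= 0:
        raise ValueError("t_max_min must be positive")
    x, y = int(init[0]), int(init[1])
    if x < 0 or y < 0:
        raise ValueError("initial state must be non-negative")
    if mode not in ("free", "absorbing", "reflecting"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode != "free" and (B is None or B < 1):
        raise ValueError(f"mode {mode!r} requires a boundary B >= 1")

    p = params
    cap = 4 * int((p.k1 + p.V1) / p.u1 + (p.V2 / p.u2 if p.u2 > 0 else 0)) + 64
    hx = _hill_table(p.V2, p.M2, p.h, cap)  # v4 as a function of X
    hy = _hill_table(p.V1, p.M1, p.h, cap)  # v2 as a function of Y
    k1, u1, u2 = p.k1, p.u1, p.u2

    rng = np.random.default_rng(seed)
    rand = rng.random
    log = np.log

    t = 0.0
    times = [0.0]
    states = [(x, y)]
    absorbed = False
    while True:
        a1 = k1 + hy[y]  # X + 1
        a2 = u1 * x  # X - 1
        a3 = hx[x]  # Y + 1
        a4 = u2 * y  # Y - 1
        if mode == "reflecting" and x + y >= B:
            a1 = 0.0
            a3 = 0.0
        atot = a1 + a2 + a3 + a4
        if atot <= 0.0:
            raise RuntimeError(f"zero total propensity at state {(x, y)}")
        t -= log(rand()) / atot
        if t >= t_max_min:
            t = t_max_min
            break
        u = rand() * atot
        if u < a1:
            x += 1
        elif u < a1 + a2:
            x -= 1
        elif u < a1 + a2 + a3:
            y += 1
        else:
            y -= 1
        if x >= cap or y >= cap:  # extend the Hill lookup tables
            cap *= 2
            hx = _hill_table(p.V2, p.M2, p.h, cap)
            hy = _hill_table(p.V1, p.M1, p.h, cap)
        if record:
            times.append(t)
            states.append((x, y))
        if mode == "absorbing" and x + y > B:
            absorbed = True
            break
    if times[-1] < t:
        # close the final holding interval at t_max (or record the final
        # state when per-event recording is off)
        times.append(t)
        states.append((x, y))
    return SsaTrajectory(
        times_min=np.array(times),
        states=np.array(states, dtype=np.int32).reshape(-1, 2),
        seed=seed,
        mode=mode,
        B=B,
        absorbed=absorbed,
    )


def stationary_histogram(
    trajectories: list[SsaTrajectory], burn_in_min: float
) -> "OccupancyHistogram":
    """Time-weighted occupancy over (X, Y), pooled across realizations.

    Each visited state is weighted by its holding time after discarding
    the burn-in.  Sums to 1.
    """
    xmax = max(int(traj.states[:, 0].max()) for traj in trajectories) + 1
    ymax = max(int(traj.states[:, 1].max()) for traj in trajectories) + 1
    H = np.zeros(xmax * ymax)
    tot = 0.0
    for traj in trajectories:
        t, s = traj.times_min, traj.states
        if burn_in_min >= t[-1]:
            raise ValueError("burn_in must be shorter than the simulated time")
        # holding time of each visited state, clipped at the burn-in boundary
        hold = t[1:] - np.maximum(t[:-1], burn_in_min)
        hold = np.clip(hold, 0.0, None)
        codes = s[:-1, 0].astype(np.int64) * ymax + s[:-1, 1]
        H += np.bincount(codes, weights=hold, minlength=xmax * ymax)
        tot += hold.sum()
    if tot <= 0:
        raise ValueError("no retained simulated time after burn-in")
    return OccupancyHistogram(H=(H / tot).reshape(xmax, ymax))


@dataclass(frozen=True)
class OccupancyHistogram:
    H: np.ndarray  # (X, Y) occupancy probabilities, sums to 1

    def modes(self, min_separation: float = 10.0) -> list[tuple[int, int]]:
        """Local occupancy maxima separated by at least ``min_separation``
        copies (Chebyshev), ordered by decreasing mass."""
        order = np.argsort(self.H, axis=None)[::-1]
        found: list[tuple[int, int]] = []
        for flat in order:
            x, y = np.unravel_index(flat, self.H.shape)
            if self.H[x, y] <= 0:
                break
            if all(max(abs(x - a), abs(y - b)) >= min_separation for a, b in found):
                found.append((int(x), int(y)))
            if len(found) >= 4:
                break
        return found


@dataclass(frozen=True)
class FirstPassageSample:
    """Absorption times across independent replicates."""

    times_years: np.ndarray
    B: int
    seed: int

    @property
    def mean_years(self) -> float:
        return float(self.times_years.mean())

    @property
    def sd_years(self) -> float:
        return float(self.times_years.std(ddof=1))

    @property
    def rate_per_year(self) -> float:
        """MLE of the exponential rate, 1 / mean."""
        return 1.0 / self.mean_years

    @property
    def rate_se_per_year(self) -> float:
        """Standard error of the rate estimate, rate / sqrt(n)."""
        return self.rate_per_year / np.sqrt(len(self.times_years))


def estimate_first_passage(
    params: SwitchParameters,
    B: int,
    n_reps: int,
    seed: int,
    init: tuple[int, int] | None = None,
) -> FirstPassageSample:
    """Monte-Carlo first-passage (absorption) times for boundary B.

    Replicate r uses seed ``seed + r`` so the set is reproducible and
    order-independent.  Starts from the integer state nearest the off
    attractor unless ``init`` is given.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if init is None:
        from .switch import low_equilibrium

        eq = low_equilibrium(params)
        init = (int(round(eq.state[0])), int(round(eq.state[1])))
    times = np.empty(n_reps)
    horizon = 1e13  # effectively until absorption
    for r in range(n_reps):
        traj = simulate_ssa(
            params, init, horizon, seed=seed + r, mode="absorbing", B=B, record=False
        )
        if not traj.absorbed:
            raise RuntimeError("replicate hit the safety horizon before absorbing")
        times[r] = traj.times_min[-1] / MINUTES_PER_YEAR
    return FirstPassageSample(times_years=times, B=B, seed=seed)


def reflecting_stationary(params: SwitchParameters, B: int) -> tuple[StateSpace, np.ndarray]:
    """Stationary law of the truncated *reflecting* network.

    Builds the absorbing generator, redirects boundary-leaving
    production flux back onto the diagonal (removes it), and solves for
    the null vector of the resulting conservative generator.  Used as
    the CME-side oracle for SSA occupancy tests.
    """
    space = enumerate_states(B)
    G = build_generator(params, space)
    m = space.n_off
    Arev = G.A_rev.tolil()
    # cancel absorption outflow from the diagonal -> reflecting walls
    a_abs = G.a_abs
    for i in np.nonzero(a_abs)[0]:
        Arev[i, i] += a_abs[i]
    Q = Arev.toarray()
    # null vector: smallest singular vector (columns sum to 0)
    _, _, vt = np.linalg.svd(Q)
    pi = vt[-1]
    if pi.sum() < 0:
        pi = -pi
    if pi.min() < -1e-10:
        raise RuntimeError("stationary vector is not non-negative")
    pi = np.clip(pi, 0.0, None)
    return space, pi / pi.sum()
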