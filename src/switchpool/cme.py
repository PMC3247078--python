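"""Absorbing Markov-chain / chemical master equation model of switching.

The integer microstates (X, Y) with X + Y <= B form the *off* region;
every microstate beyond the boundary is collapsed into a single
absorbing *on* state, making the transformation irreversible.  Reaction
propensities are taken equal to the deterministic rate laws (the
non-elementary Hill kinetics are used directly as propensities).

The resulting master equation is the linear ODE  dP/dt = A P  with a
sparse generator A whose columns sum to zero.  Block form:

    A = [[A_rev, 0],
         [a_abs, 0]]

A_rev couples the off-microstates, a_abs holds the absorption
propensities.  All eigenvalues of A_rev have negative real part; the
rightmost one, lambda1, is real and simple with a strictly positive
eigenvector, and governs the asymptotic decay of the survival
probability:  p_off(t) ~ c1 * exp(lambda1 * t).  The switching
half-life is ln 2 / |lambda1|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .switch import SwitchParameters, evaluate_rates, low_equilibrium
from .units import MINUTES_PER_YEAR

__all__ = [
    "StateSpace",
    "GeneratorMatrix",
    "SpectralSummary",
    "CmeSolution",
    "TailFit",
    "enumerate_states",
    "build_generator",
    "dominant_mode",
    "lambda1",
    "solve_cme",
    "pon_tail_fit",
    "initial_distribution",
]


@dataclass(frozen=True)
class StateSpace:
    """Enumerated off-microstates plus one absorbing on-state.

    States are ordered diagonal by diagonal: s = x + y ascending, x
    descending within a diagonal — (0,0), (1,0), (0,1), (2,0), (1,1),
    (0,2), ...  The absorbing state is appended last.
    """

    B: int
    states: np.ndarray  # (m, 2) int array of off-microstates
    index: dict = field(repr=False)

    @property
    def n_off(self) -> int:
        return len(self.states)

    @property
    def absorbing_index(self) -> int:
        return len(self.states)

    @property
    def n(self) -> int:
        """Total dimension including the absorbing state."""
        return len(self.states) + 1

    def state_index(self, x: int, y: int) -> int:
        return self.index[(x, y)]


def enumerate_states(B: int) -> StateSpace:
    """Enumerate off-microstates with x + y <= B.

    B = 0 is the degenerate single-state space {(0,0)}; B < 0 is an
    error.  Off-state count is (B+1)(B+2)/2.
    """
    if B < 0:
        raise ValueError("boundary B must be non-negative")
    states = np.array(
        [(s - i, i) for s in range(B + 1) for i in range(s + 1)], dtype=int
    ).reshape(-1, 2)
    index = {(int(x), int(y)): i for i, (x, y) in enumerate(states)}
    return StateSpace(B=B, states=states, index=index)


@dataclass(frozen=True)
class GeneratorMatrix:
    """Sparse generator of the absorbing chain (rates per minute)."""

    A: sp.csc_matrix  # full n x n generator, absorbing column zero
    space: StateSpace
    params: SwitchParameters

    @property
    def A_rev(self) -> sp.csc_matrix:
        m = self.space.n_off
        return self.A[:m, :m]

    @property
    def a_abs(self) -> np.ndarray:
        m = self.space.n_off
        return np.asarray(self.A[m, :m].todense()).ravel()


def build_generator(params: SwitchParameters, space: StateSpace) -> GeneratorMatrix:
    """Assemble the sparse generator from the rate laws.

    Production events (X+1 at rate v1+v2(Y); Y+1 at rate v4(X)) that
    leave the off region route to the absorbing state; degradation
    events (v3, v5) always stay internal.
    """
    B, idx, m = space.B, space.index, space.n_off
    n = space.n
    rows, cols, vals = [], [], []
    for i, (X, Y) in enumerate(space.states):
        v1, v2, v3, v4, v5 = evaluate_rates((X, Y), params)
        out = 0.0
        for rate, tx, ty in ((v1 + v2, X + 1, Y), (v3, X - 1, Y), (v4, X, Y + 1), (v5, X, Y - 1)):
            if rate <= 0.0:
                continue
            j = idx[(tx, ty)] if tx + ty <= B and tx >= 0 and ty >= 0 else m
            rows.append(j)
            cols.append(i)
            vals.append(rate)
            out += rate
        rows.append(i)
        cols.append(i)
        vals.append(-out)
    A = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return GeneratorMatrix(A=A, space=space, params=params)


@dataclass(frozen=True)
class SpectralSummary:
    """Dominant decay mode of the non-absorbing block."""

    lambda1_per_min: float  # rightmost eigenvalue of A_rev, real and < 0
    eigvec: np.ndarray  # positive, normalized to sum 1
    method: str

    @property
    def lambda1_per_year(self) -> float:
        return self.lambda1_per_min * MINUTES_PER_YEAR

    @property
    def rate_per_year(self) -> float:
        """Asymptotic switching rate |lambda1| in events per year."""
        return -self.lambda1_per_year

    @property
    def half_life_years(self) -> float:
        return np.log(2.0) / (-self.lambda1_per_min) / MINUTES_PER_YEAR


_DENSE_MAX = 300  # above this, shift-invert Arnoldi is much faster


def dominant_mode(G: GeneratorMatrix, method: str = "auto") -> SpectralSummary:
    """Rightmost eigenvalue of A_rev and its positive eigenvector.

    method 'dense' computes the full spectrum (robust reference for
    n <~ 2000); 'sparse' uses shift-invert Arnoldi around 0 (lambda1 is
    the eigenvalue of smallest modulus since the spectrum lies in the
    open left half-plane); 'auto' picks by size.
    """
    m = G.space.n_off
    if method == "auto":
        method = "dense" if m <= _DENSE_MAX else "sparse"
    if m == 1:
        # degenerate single off-state: scalar absorption
        lam = G.A_rev[0, 0]
        return SpectralSummary(float(lam), np.array([1.0]), method="scalar")
    if method == "dense":
        w, v = scipy.linalg.eig(G.A_rev.toarray())
        i = int(np.argmax(w.real))
        lam, vec = w[i], v[:, i]
    elif method == "sparse":
        try:
            w, v = spla.eigs(G.A_rev, k=1, sigma=0.0, which="LM", v0=np.ones(m))
        except spla.ArpackNoConvergence as err:
            raise RuntimeError(
                "shift-invert eigensolver failed to converge; retry with "
                "method='dense' (feasible up to n ~ 2000)"
            ) from err
        lam, vec = w[0], v[:, 0]
    else:
        raise ValueError(f"unknown method {method!r}")
    if abs(lam.imag) > 1e-12 * max(abs(lam.real), 1e-300):
        raise RuntimeError(f"dominant eigenvalue is not numerically real: {lam}")
    vec = vec.real if abs(vec.imag).max() <= 1e-9 * abs(vec.real).max() else None
    if vec is None:
        raise RuntimeError("dominant eigenvector has a non-negligible imaginary part")
    if vec.sum() < 0:
        vec = -vec
    # far-tail entries can round off to tiny negatives; anything larger
    # signals a genuine failure of the Perron structure
    if vec.min() < -1e-10 * vec.max():
        raise RuntimeError("dominant eigenvector is not positive")
    vec = np.clip(vec, 0.0, None)
    vec = vec / vec.sum()
    return SpectralSummary(float(lam.real), vec, method=method)


def lambda1(params: SwitchParameters, B: int = 55, method: str = "auto") -> SpectralSummary:
    """Convenience: enumerate, assemble and extract the dominant mode."""
    return dominant_mode(build_generator(params, enumerate_states(B)), method=method)


@dataclass(frozen=True)
class CmeSolution:
    """Transient solution of the master equation."""

    times_min: np.ndarray  # (T,)
    P: np.ndarray  # (n, T) probability vectors
    space: StateSpace

    @property
    def times_years(self) -> np.ndarray:
        return self.times_min / MINUTES_PER_YEAR

    @property
    def p_on(self) -> np.ndarray:
        return self.P[self.space.absorbing_index]

    @property
    def p_off(self) -> np.ndarray:
        return 1.0 - self.p_on


def initial_distribution(params: SwitchParameters, space: StateSpace) -> np.ndarray:
    """Point mass at the integer microstate nearest the off attractor.

    Models a cell starting in the deterministic off steady state.
    """
    eq = low_equilibrium(params)
    x, y = int(round(eq.state[0])), int(round(eq.state[1]))
    if x + y > space.B:
        raise ValueError(
            f"off attractor {(x, y)} lies outside the off region (B={space.B})"
        )
    p0 = np.zeros(space.n)
    p0[space.state_index(x, y)] = 1.0
    return p0


def solve_cme(
    G: GeneratorMatrix,
    p0: np.ndarray,
    times_min: np.ndarray,
    method: str = "auto",
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> CmeSolution:
    """Integrate dP/dt = A P on the requested output times.

    method 'expm' propagates with dense matrix exponentials between
    output times (exact up to roundoff; for small spaces); 'bdf' uses a
    stiff implicit integrator with the sparse generator as Jacobian;
    'auto' picks expm for n <= 256.
    """
    times_min = np.asarray(times_min, dtype=float)
    if np.any(np.diff(times_min) <= 0):
        raise ValueError("times must be strictly increasing")
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (G.space.n,):
        raise ValueError(f"p0 must have length {G.space.n}")
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-10:
        raise ValueError("p0 must be a probability vector")
    if method == "auto":
        method = "expm" if G.space.n <= 256 else "bdf"

    tgrid = times_min if times_min[0] == 0.0 else np.concatenate([[0.0], times_min])
    if method == "expm":
        Ad = G.A.toarray()
        P = np.empty((G.space.n, len(tgrid)))
        P[:, 0] = p0
        for k in range(1, len(tgrid)):
            dt = tgrid[k] - tgrid[k - 1]
            P[:, k] = scipy.linalg.expm(Ad * dt) @ P[:, k - 1]
    elif method == "bdf":
        Acsr = G.A.tocsr()
        sol = solve_ivp(
            lambda t, p: Acsr @ p,
            (0.0, tgrid[-1]),
            p0,
            t_eval=tgrid,
            method="BDF",
            jac=G.A,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff CME integration failed: {sol.message}; "
                "consider a coarser or shorter time grid"
            )
        P = sol.y
    else:
        raise ValueError(f"unknown method {method!r}")
    if times_min[0] != 0.0:
        P = P[:, 1:]
    return CmeSolution(times_min=times_min, P=P, space=G.space)


def pon_curve(
    params: SwitchParameters,
    B: int = 55,
    t_max_years: float = 200.0,
    n_times: int = 240,
    method: str = "auto",
) -> CmeSolution:
    """End-to-end p_on(t): generator at boundary B, initial point mass at
    the off attractor, log-spaced output times from 1e-3 years."""
    space = enumerate_states(B)
    G = build_generator(params, space)
    times = np.logspace(-3, np.log10(t_max_years), n_times) * MINUTES_PER_YEAR
    return solve_cme(G, initial_distribution(params, space), times, method=method)


@dataclass(frozen=True)
class TailFit:
    """Exponential-tail regression of the survival probability."""

    c1: float  # prefactor of the dominant mode, > 0
    slope_per_min: float  # fitted decay rate (should equal lambda1)
    slope_ratio: float  # slope / lambda1
    n_points: int
    truncated: bool  # True if underflowed tail points were dropped


def pon_tail_fit(sol: CmeSolution, summary: SpectralSummary) -> TailFit:
    """Regress log p_off over the last decade of the time grid.

    Checks the transient solution against the spectral prediction
    p_off(t) ~ c1 * exp(lambda1 * t); requires the solution to span at
    least three switching half-lives.
    """
    t = sol.times_min
    t_half = np.log(2.0) / (-summary.lambda1_per_min)
    if t[-1] < 3.0 * t_half:
        raise ValueError(
            f"solution spans {t[-1] / t_half:.2f} half-lives; need >= 3 for a tail fit"
        )
    mask = t >= t[-1] / 10.0
    poff = sol.p_off[mask]
    tt = t[mask]
    ok = poff > 1e-290
    truncated = bool(np.any(~ok))
    if truncated:
        warnings.warn("dropping underflowed p_off values from the tail fit")
        poff, tt = poff[ok], tt[ok]
    if len(tt) < 2:
        raise ValueError("not enough positive tail points for a fit")
    slope, intercept = np.polyfit(tt, np.log(poff), 1)
    return TailFit(
        c1=float(np.exp(intercept)),
        slope_per_min=float(slope),
        slope_ratio=float(slope / summary.lambda1_per_min),
        n_points=int(len(tt)),
        truncated=truncated,
    )
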