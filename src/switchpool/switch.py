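"""Deterministic two-component positive-feedback switch.

The switch couples two transcripts X and Y.  X is produced at a basal
rate ``k1`` plus a Hill-type activation by Y; Y is produced by a
Hill-type activation by X; both degrade linearly:

    dx/dt = k1 + V1 * y**h / (M1**h + y**h) - u1 * x
    dy/dt =      V2 * x**h / (M2**h + x**h) - u2 * y

With the nominal parameter set the system is bistable: a low ("off")
attractor, a saddle, and a high ("on") attractor.  The macrostate of a
cell is *off* when x + y < L and *on* when x + y >= L; crossing the
threshold models the irreversible initiation of a cellular
transformation (here, follicle growth initiation).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "SwitchParameters",
    "Equilibrium",
    "NOMINAL_L",
    "evaluate_rates",
    "rhs",
    "jacobian",
    "find_equilibria",
    "simulate_ode",
    "classify_macrostate",
]

#: Nominal macrostate threshold on x + y (copy number).
NOMINAL_L = 55

# Parameter groups scaled jointly in sensitivity scans; the feedback
# rates, half-saturation constants and degradation rates come in
# symmetric pairs.
_SCAN_GROUPS = {
    "k1": ("k1",),
    "V": ("V1", "V2"),
    "u": ("u1", "u2"),
    "M": ("M1", "M2"),
    "h": ("h",),
}


@dataclass(frozen=True)
class SwitchParameters:
    """Kinetic constants of the switch; all rates per minute, amounts in
    transcript copy numbers.

    k1 : basal production rate of X
    V1, V2 : maximal feedback production rates
    M1, M2 : half-saturation copy numbers
    h : Hill coefficient (real-valued; non-integer values arise in
        sensitivity scans)
    u1, u2 : first-order degradation rates
    """

    k1: float = 0.055
    V1: float = 0.55
    V2: float = 0.55
    M1: float = 25.0
    M2: float = 25.0
    h: float = 3.0
    u1: float = 0.01
    u2: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k1", "M1", "M2", "h", "u1", "u2"):
            if not getattr(self, name) > 0:
                raise ValueError(f"parameter {name} must be strictly positive")
        for name in ("V1", "V2"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")

    @classmethod
    def nominal(cls) -> "SwitchParameters":
        """The packaged nominal parameter set."""
        return cls()

    def replace(self, **kwargs) -> "SwitchParameters":
        return dataclasses.replace(self, **kwargs)

    def scaled(self, group: str, factor: float) -> "SwitchParameters":
        """Multiply one scan group ('k1', 'V', 'u', 'M' or 'h') by ``factor``.

        Paired parameters (V1/V2, u1/u2, M1/M2) are scaled together.
        """
        if group not in _SCAN_GROUPS:
            raise KeyError(f"unknown scan group {group!r}; options: {sorted(_SCAN_GROUPS)}")
        if factor <= 0:
            raise ValueError("scale factor must be strictly positive")
        return self.replace(**{f: getattr(self, f) * factor for f in _SCAN_GROUPS[group]})


@dataclass(frozen=True)
class Equilibrium:
    """A fixed point of the deterministic switch."""

    state: tuple[float, float]
    stability: str  # "stable" | "unstable" | "saddle"
    eigenvalues: tuple[complex, complex]
    degenerate: bool = False  # eigenvalue real part within tolerance of 0

    @property
    def total(self) -> float:
        return self.state[0] + self.state[1]


def _hill(v: float, M: float, h: float, s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    sh = np.where(s > 0, s, 0.0) ** h
    return v * sh / (M**h + sh)


def evaluate_rates(state: Sequence[float], params: SwitchParameters) -> np.ndarray:
    """The five reaction rates (v1..v5) at a microstate.

    v1 = k1 (basal X production), v2 = Hill activation of X by Y,
    v3 = X degradation, v4 = Hill activation of Y by X, v5 = Y degradation.
    """
    x, y = float(state[0]), float(state[1])
    if x < 0 or y < 0:
        raise ValueError(f"microstate components must be non-negative, got {(x, y)}")
    p = params
    return np.array(
        [
            p.k1,
            _hill(p.V1, p.M1, p.h, y),
            p.u1 * x,
            _hill(p.V2, p.M2, p.h, x),
            p.u2 * y,
        ]
    )


def rhs(t: float, xy: Sequence[float], params: SwitchParameters) -> np.ndarray:
    """Right-hand side of the switch ODE (time in minutes)."""
    x, y = xy
    p = params
    dx = p.k1 + _hill(p.V1, p.M1, p.h, y) - p.u1 * x
    dy = _hill(p.V2, p.M2, p.h, x) - p.u2 * y
    return np.array([dx, dy])


def _hill_deriv(v: float, M: float, h: float, s: float) -> float:
    if s <= 0:
        # d/ds [V s^h / (M^h + s^h)] -> 0 for h > 1, V/M for h = 1
        return v / M if h == 1 else 0.0
    sh = s**h
    return v * h * s ** (h - 1) * M**h / (M**h + sh) ** 2


def jacobian(xy: Sequence[float], params: SwitchParameters) -> np.ndarray:
    x, y = xy
    p = params
    return np.array(
        [
            [-p.u1, _hill_deriv(p.V1, p.M1, p.h, y)],
            [_hill_deriv(p.V2, p.M2, p.h, x), -p.u2],
        ]
    )


_RES_TOL = 1e-9
_DEDUP_TOL = 1e-3
_EIG_TOL = 1e-12


def find_equilibria(params: SwitchParameters, n_starts: int = 14) -> list[Equilibrium]:
    """Locate all fixed points by multi-start root finding.

    Starts are seeded from a coarse grid over the invariant box
    [0, (k1+V1)/u1] x [0, V2/u2]; converged roots are de-duplicated at
    1e-3 copies and classified by the Jacobian spectrum.  Returned
    sorted by x + y ascending.
    """
    p = params
    xmax = (p.k1 + p.V1) / p.u1
    ymax = max(p.V2 / p.u2, 1.0)
    roots: list[np.ndarray] = []
    for x0 in np.linspace(0, xmax, n_starts):
        for y0 in np.linspace(0, ymax, n_starts):
            sol = root(lambda xy: rhs(0.0, xy, p), [x0, y0], jac=lambda xy: jacobian(xy, p), method="hybr")
            if not sol.success:
                continue
            xy = sol.x
            if xy[0] < -1e-6 or xy[1] < -1e-6:
                continue
            xy = np.clip(xy, 0.0, None)
            if np.linalg.norm(rhs(0.0, xy, p)) > _RES_TOL:
                continue
            if any(np.max(np.abs(xy - r)) < _DEDUP_TOL for r in roots):
                continue
            roots.append(xy)
    if not roots:
        raise RuntimeError(
            "no equilibrium found: multi-start root search failed to converge "
            f"anywhere on [0, {xmax:.3g}] x [0, {ymax:.3g}]"
        )
    out = []
    for xy in roots:
        eigs = np.linalg.eigvals(jacobian(xy, p))
        re = np.real(eigs)
        degenerate = bool(np.any(np.abs(re) <= _EIG_TOL))
        if np.all(re < -_EIG_TOL):
            stab = "stable"
        elif np.all(re > _EIG_TOL):
            stab = "unstable"
        else:
            stab = "saddle" if np.any(re > _EIG_TOL) else "stable"
        out.append(
            Equilibrium(
                state=(float(xy[0]), float(xy[1])),
                stability=stab,
                eigenvalues=(complex(eigs[0]), complex(eigs[1])),
                degenerate=degenerate,
            )
        )
    out.sort(key=lambda e: e.total)
    return out


def low_equilibrium(params: SwitchParameters) -> Equilibrium:
    """The off-state attractor (smallest x + y); must be stable."""
    eq = find_equilibria(params)[0]
    if eq.stability != "stable":
        raise RuntimeError(f"lowest equilibrium is not stable: {eq}")
    return eq


def simulate_ode(
    params: SwitchParameters,
    init: Sequence[float],
    t_grid: Iterable[float],
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the switch ODE on ``t_grid`` (minutes); returns (len(t), 2)."""
    t = np.asarray(list(t_grid), dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be an increasing 1-D sequence of at least 2 times")
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial state must be non-negative")
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        init,
        t_eval=t,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def classify_macrostate(state: Sequence[float], L: float = NOMINAL_L) -> str:
    """'on' iff x + y >= L, else 'off'.

    The off/on regions share the line x + y = L; the boundary is
    classified *on* (the irreversible reading: a cell that reaches the
    threshold has initiated the transformation).
    """
    if L <= 0:
        raise ValueError("macrostate threshold L must be positive")
    x, y = state[0], state[1]
    if x < 0 or y < 0:
        raise ValueError("microstate components must be non-negative")
    return "on" if x + y >= L else "off"
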