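"""Synthetic cohort generator.

No individual-level clinical data ship with the model, so this module
generates the kind of observations the population model is compared
against: (i) a cohort of individuals whose switch parameters vary
between them, each with a model-computed depletion (menopause) age, and
(ii) noisy age-versus-follicle-count tables emulating clinical count
scatter.

Parameter heterogeneity is lognormal and independent across parameter
groups (positivity-preserving, mean-one factors); count noise is
multiplicative lognormal, since clinical follicle counts scatter over
orders of magnitude.  By default only the degradation rates u1 = u2
vary: the depletion time is far more sensitive to the shared kinetic
parameters than to the population-level ones, so a percent-scale spread
in u already yields a year-scale spread in depletion age.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feedback import FeedbackParameters, PopulationTrajectory, build_rate_map, depletion_time
from .switch import find_equilibria

__all__ = ["CohortSpec", "SyntheticObservations", "sample_cohort", "sample_counts"]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort size, per-group parameter CVs, noise level and seed."""

    n_individuals: int = 20
    cvs: dict = field(default_factory=lambda: {"u": 0.02})
    seed: int = 0
    observation_ages: tuple[float, ...] = tuple(float(a) for a in range(0, 55, 5))
    count_sigma: float = 0.3  # sd of log-scale count noise

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if any(cv < 0 for cv in self.cvs.values()):
            raise ValueError("CVs must be non-negative")
        if any(not 0 <= a <= 100 for a in self.observation_ages):
            raise ValueError("observation ages must lie in [0, 100] years")
        if self.count_sigma < 0:
            raise ValueError("count_sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticObservations:
    """Per-individual draws and depletion times, plus summary stats."""

    factors: pd.DataFrame  # (individual, parameter group) multiplicative factors
    depletion_years: np.ndarray
    n_excluded: int  # individuals dropped for losing bistability
    seed: int

    @property
    def mean_years(self) -> float:
        return float(self.depletion_years.mean())

    @property
    def sd_years(self) -> float:
        return float(self.depletion_years.std(ddof=1)) if len(self.depletion_years) > 1 else 0.0


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one lognormal multipliers with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def sample_cohort(
    spec: CohortSpec,
    base: FeedbackParameters | None = None,
    Nd: float = 1e3,
    B: int = 55,
    rate_map_points: int = 25,
) -> SyntheticObservations:
    """Draw a cohort and compute each individual's depletion time.

    Each individual's parameter groups are scaled by independent
    mean-one lognormal factors; the depletion time comes from the full
    feedback population model with a per-individual rate map.
    Individuals whose perturbed switch loses bistability are excluded
    (counted in ``n_excluded``).
    """
    base = base or FeedbackParameters.nominal()
    rng = np.random.default_rng(spec.seed)
    groups = sorted(spec.cvs)
    draws = {g: _lognormal_factor(rng, spec.cvs[g], spec.n_individuals) for g in groups}
    factors = pd.DataFrame(draws, index=range(spec.n_individuals))

    tds = []
    kept_rows = []
    n_excluded = 0
    for i in range(spec.n_individuals):
        p = base
        for g in groups:
            p = p.scaled(g, float(factors.loc[i, g]))
        eqs = find_equilibria(p.switch_at(0.0))
        if not (len(eqs) == 3 and sum(e.stability == "stable" for e in eqs) == 2):
            n_excluded += 1
            continue
        rm = build_rate_map(p, B=B, n_points=rate_map_points)
        tds.append(depletion_time(p, Nd=Nd, rate_map=rm))
        kept_rows.append(i)
    return SyntheticObservations(
        factors=factors.loc[kept_rows],
        depletion_years=np.array(tds),
        n_excluded=n_excluded,
        seed=spec.seed,
    )


def sample_counts(
    traj: PopulationTrajectory,
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy age-vs-count observations from a model trajectory.

    counts = n1(age) * exp(eps), eps ~ N(0, sigma^2); columns
    (age_years, count).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    ages = np.asarray(spec.observation_ages, dtype=float)
    if ages.max() > traj.times_years[-1]:
        raise ValueError("observation ages exceed the trajectory horizon")
    n1 = np.interp(ages, traj.times_years, traj.n1)
    eps = rng.normal(0.0, spec.count_sigma, size=len(ages))
    counts = np.maximum(n1 * np.exp(eps), 0.0)
    return pd.DataFrame({"age_years": ages, "count": counts})
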