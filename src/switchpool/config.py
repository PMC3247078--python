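"""Run configuration: validated parameter files and pipeline driver.

Configs are JSON or YAML; any key left out falls back to the packaged
nominal values (the single-cell and population parameter tables),
unknown keys are rejected.  All kinetic parameters are stored per
minute; all reported times are years.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .feedback import FeedbackParameters
from .pool import PoolConfig
from .switch import NOMINAL_L, SwitchParameters

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "run_pipeline", "STAGES"]

STAGES = ("equilibria", "lambda1", "cme", "pool", "dde", "scan", "simulate", "cohort")


class ConfigError(ValueError):
    pass


class SwitchSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k1: float = Field(0.055, gt=0, description="basal X production, 1/min")
    V1: float = Field(0.55, ge=0)
    V2: float = Field(0.55, ge=0)
    M1: float = Field(25.0, gt=0)
    M2: float = Field(25.0, gt=0)
    h: float = Field(3.0, gt=0)
    u1: float = Field(0.01, gt=0)
    u2: float = Field(0.01, gt=0)
    L: int = Field(NOMINAL_L, gt=0, description="macrostate threshold on x+y")


class PoolSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    N0: int = Field(1_000_000, gt=0)
    Nd: int = Field(1_000, ge=1)


class FeedbackSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    k1_max: float = Field(0.06, gt=0)
    Kn: float = Field(8.2e4, gt=0)
    tau_years: float = Field(0.4, ge=0)
    t_end_years: float = Field(600.0, gt=0, description="integration horizon")


class SsaSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reps: int = Field(20, ge=1)
    t_max_years: float = Field(3.0, gt=0)
    burn_in_years: float = Field(0.25, ge=0)
    mode: str = "free"


class ScanSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    model: str = "single_cell"
    factors: list[float] = [0.8, 0.9, 0.95, 1.05, 1.1, 1.3]
    parameters: Optional[list[str]] = None


class RunConfig(BaseModel):
    """Complete configuration of an end-to-end run."""

    model_config = ConfigDict(extra="forbid")
    switch: SwitchSection = SwitchSection()
    boundary_B: int = Field(55, ge=0)
    pool: PoolSection = PoolSection()
    feedback: FeedbackSection = FeedbackSection()
    ssa: SsaSection = SsaSection()
    scan: ScanSection = ScanSection()
    seed: int = 0
    verbosity: int = 1

    def switch_parameters(self) -> SwitchParameters:
        s = self.switch
        return SwitchParameters(
            k1=s.k1, V1=s.V1, V2=s.V2, M1=s.M1, M2=s.M2, h=s.h, u1=s.u1, u2=s.u2
        )

    def pool_config(self) -> PoolConfig:
        return PoolConfig(N0=self.pool.N0, Nd=self.pool.Nd)

    def feedback_parameters(self) -> FeedbackParameters:
        s, f = self.switch, self.feedback
        return FeedbackParameters(
            k1_max=f.k1_max,
            Kn=f.Kn,
            tau_years=f.tau_years,
            V1=s.V1,
            V2=s.V2,
            M1=s.M1,
            M2=s.M2,
            h=s.h,
            u1=s.u1,
            u2=s.u2,
            N0=float(self.pool.N0),
        )


def _format_validation_error(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {loc}: {e['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a JSON/YAML config; missing keys take the nominal defaults,
    unknown keys are rejected with a message naming them."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as err:
        raise ConfigError(f"cannot parse {path}: {err}") from err
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    try:
        return RunConfig.model_validate(data)
    except ValidationError as err:
        raise ConfigError(_format_validation_error(err)) from err


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def run_pipeline(cfg: RunConfig, stages, out_dir: str | Path, log=print) -> dict:
    """Run a subset of pipeline stages, writing artifacts under out_dir.

    Returns a summary dict with the key numbers of each executed stage;
    also written as summary.json.
    """
    from . import cme as cme_mod
    from . import cohort as cohort_mod
    from . import feedback as fb
    from . import pool as pool_mod
    from . import sensitivity as sens
    from . import ssa as ssa_mod
    from .units import MINUTES_PER_YEAR

    stages = list(stages)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; choose from {list(STAGES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.switch_parameters()
    B = cfg.boundary_B
    summary: dict = {"boundary_B": B, "state_space_n": None, "seed": cfg.seed}

    sol = None
    if "equilibria" in stages:
        from .switch import find_equilibria

        rows = []
        for eq in find_equilibria(params):
            rows.append(
                {
                    "state_x": eq.state[0],
                    "state_y": eq.state[1],
                    "stability": eq.stability,
                    "eig_re_1": eq.eigenvalues[0].real,
                    "eig_re_2": eq.eigenvalues[1].real,
                }
            )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "equilibria.csv", index=False)
        summary["n_equilibria"] = len(rows)
        log(f"[equilibria] {len(rows)} fixed points -> equilibria.csv")

    if {"lambda1", "cme", "pool"} & set(stages):
        space = cme_mod.enumerate_states(B)
        G = cme_mod.build_generator(params, space)
        summary["state_space_n"] = space.n
        log(f"[setup] state space n = {space.n} (B = {B})")

    if "lambda1" in stages:
        import scipy.io

        s = cme_mod.dominant_mode(G)
        summary["lambda1_per_year"] = s.lambda1_per_year
        summary["half_life_years"] = s.half_life_years
        scipy.io.mmwrite(out / "generator.mtx", G.A)
        (out / "spectral_summary.json").write_text(
            json.dumps(
                {
                    "lambda1_per_min": s.lambda1_per_min,
                    "lambda1_per_year": s.lambda1_per_year,
                    "half_life_years": s.half_life_years,
                    "n": space.n,
                },
                indent=2,
            )
        )
        log(f"[lambda1] lambda1 = {s.lambda1_per_year:.4e}/y, half-life = {s.half_life_years:.3f} y")

    if "cme" in stages or "pool" in stages:
        times = np.logspace(-3, np.log10(200.0), 240) * MINUTES_PER_YEAR
        sol = cme_mod.solve_cme(G, cme_mod.initial_distribution(params, space), times)
        import pandas as pd

        pd.DataFrame(
            {"time_years": sol.times_years, "p_on": sol.p_on, "p_off": sol.p_off}
        ).to_csv(out / "pon_curve.csv", index=False)
        log("[cme] p_on(t) -> pon_curve.csv")

    if "pool" in stages:
        import pandas as pd

        pc = cfg.pool_config()
        dep = pool_mod.depletion_time_stats(sol.times_years, sol.p_on, pc)
        s = cme_mod.dominant_mode(G)
        approx = pool_mod.expected_depletion_time_approx(s, pc)
        pd.DataFrame(
            {"time_years": dep.times_years, "cdf": dep.cdf, "pdf": dep.pdf}
        ).to_csv(out / "depletion_distribution.csv", index=False)
        summary["Etd_years"] = dep.mean_years
        summary["sd_years"] = dep.sd_years
        summary["Etd_approx_years"] = approx
        (out / "pool_summary.json").write_text(
            json.dumps(
                {"mean_years": dep.mean_years, "sd_years": dep.sd_years, "approx_years": approx},
                indent=2,
            )
        )
        log(f"[pool] E[Td] = {dep.mean_years:.2f} y, sd = {dep.sd_years:.3f} y, approx = {approx:.2f} y")

    if "dde" in stages:
        import pandas as pd

        fp = cfg.feedback_parameters()
        rm = fb.build_rate_map(fp, B=B)
        traj = fb.simulate_dde(
            fp, cfg.feedback.t_end_years, rate_map=rm, stop_below=0.5 * cfg.pool.Nd
        )
        td = fb.depletion_time_from_trajectory(traj, cfg.pool.Nd)
        pd.DataFrame(
            {
                "time_years": traj.times_years,
                "n1": traj.n1,
                "n2": traj.n2,
                "lambda1_per_year": traj.lambda1_used_per_year,
            }
        ).to_csv(out / "population_trajectory.csv", index=False)
        summary["Td_feedback_years"] = td
        log(f"[dde] feedback-model depletion at {td:.2f} y")

    if "scan" in stages:
        spec = sens.ScanSpec(
            model=cfg.scan.model,
            factors=tuple(cfg.scan.factors),
            parameters=tuple(cfg.scan.parameters) if cfg.scan.parameters else None,
        )
        res = sens.run_scan(spec, params, cfg.feedback_parameters(), cfg.pool_config(), B=B)
        res.to_frame().to_csv(out / f"scan_{cfg.scan.model}.csv")
        summary[f"scan_{cfg.scan.model}"] = "written"
        log(f"[scan] {cfg.scan.model} table -> scan_{cfg.scan.model}.csv")

    if "simulate" in stages:
        import pandas as pd

        from .switch import find_equilibria

        eqs = find_equilibria(params)
        stable = [e for e in eqs if e.stability == "stable"]
        inits = [tuple(int(round(c)) for c in e.state) for e in stable]
        t_max = cfg.ssa.t_max_years * MINUTES_PER_YEAR
        trajs = [
            ssa_mod.simulate_ssa(
                params, inits[r % len(inits)], t_max, seed=cfg.seed + r, mode=cfg.ssa.mode, B=B if cfg.ssa.mode != "free" else None
            )
            for r in range(cfg.ssa.reps)
        ]
        hist = ssa_mod.stationary_histogram(trajs, cfg.ssa.burn_in_years * MINUTES_PER_YEAR)
        xs, ys = np.nonzero(hist.H)
        pd.DataFrame({"x": xs, "y": ys, "probability": hist.H[xs, ys]}).to_csv(
            out / "ssa_histogram.csv", index=False
        )
        summary["ssa_modes"] = [list(m) for m in hist.modes()]
        log(f"[simulate] {cfg.ssa.reps} realizations; occupancy modes at {hist.modes()}")

    if "cohort" in stages:
        spec = cohort_mod.CohortSpec(seed=cfg.seed)
        obs = cohort_mod.sample_cohort(spec, cfg.feedback_parameters())
        summary["cohort_mean_years"] = obs.mean_years
        summary["cohort_sd_years"] = obs.sd_years
        obs.factors.assign(depletion_years=obs.depletion_years).to_csv(
            out / "cohort.csv", index_label="individual"
        )
        log(f"[cohort] mean = {obs.mean_years:.1f} y, sd = {obs.sd_years:.2f} y")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
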