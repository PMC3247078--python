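"""Depletion time of a pool of independent cells.

With N0 = 1e6 cells each switching independently at the CME-computed
p_on(t), the remaining count is binomial and the depletion time (first
time only Nd = 1e3 remain — the menopause-onset convention) has a very
sharp distribution.  Writes results/depletion_distribution.csv and
results/pool_summary.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from switchpool import (
    PoolConfig,
    SwitchParameters,
    depletion_time_stats,
    dominant_mode,
    build_generator,
    enumerate_states,
    expected_depletion_time_approx,
    pon_curve,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results", type=Path)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    params = SwitchParameters.nominal()
    cfg = PoolConfig()
    sol = pon_curve(params, B=55)
    dep = depletion_time_stats(sol.times_years, sol.p_on, cfg)
    summary = dominant_mode(build_generator(params, enumerate_states(55)))
    approx = expected_depletion_time_approx(summary, cfg)

    thin = slice(None, None, 8)  # the fine quadrature grid is denser than needed on disk
    pd.DataFrame(
        {"time_years": dep.times_years[thin], "cdf": dep.cdf[thin], "pdf": dep.pdf[thin]}
    ).to_csv(args.out / "depletion_distribution.csv", index=False)
    out = {
        "mean_years": dep.mean_years,
        "sd_years": dep.sd_years,
        "approx_years": approx,
        "N0": cfg.N0,
        "Nd": cfg.Nd,
    }
    (args.out / "pool_summary.json").write_text(json.dumps(out, indent=2))
    print(f"E[Td]  = {dep.mean_years:.2f} years (full binomial computation)")
    print(f"sd(Td) = {dep.sd_years:.3f} years")
    print(f"approx = {approx:.2f} years  (ln(N0/Nd)/|lambda1|)")
    print(
        f"\nsd/mean = {dep.sd_years / dep.mean_years:.2%}: despite every single "
        "cell switching at a random time, the pool as a whole depletes at an "
        "almost deterministic age — the binomial averaging of 1e6 independent "
        "exponential clocks."
    )


if __name__ == "__main__":
    main()
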