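"""One-at-a-time sensitivity of the depletion time, with and without
population feedback.

Reproduces the two sensitivity tables: the single-cell (independent
pool) model is exquisitely sensitive to the kinetic parameters — a 10%
change in degradation rates moves the depletion time by an order of
magnitude — while the delayed-feedback population model compresses the
same perturbations dramatically.  Writes results/scan_single_cell.csv
and results/scan_population.csv.  The population scan integrates ~40
eigenvalue maps and takes a few minutes.
"""

import argparse
from pathlib import Path

from switchpool import ScanSpec, run_scan


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results", type=Path)
    ap.add_argument(
        "--skip-population", action="store_true", help="only the fast single-cell table"
    )
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sc = run_scan(ScanSpec(model="single_cell"))
    sc.to_frame().to_csv(args.out / "scan_single_cell.csv")
    print("Single-cell model: expected depletion times (years)")
    print(sc.to_frame().to_string())

    if args.skip_population:
        return

    pop = run_scan(ScanSpec(model="population"))
    pop.to_frame().to_csv(args.out / "scan_population.csv")
    print("\nPopulation model: depletion times (years; '>500' = censored)")
    print(pop.to_frame().to_string())

    print("\nRobustness (fold-change in Td between factors 0.9 and 1.1):")
    for g in ("k1", "V", "u", "M", "h"):
        f_sc = max(sc.values.loc[g, 0.9], sc.values.loc[g, 1.1]) / min(
            sc.values.loc[g, 0.9], sc.values.loc[g, 1.1]
        )
        f_pop = max(pop.values.loc[g, 0.9], pop.values.loc[g, 1.1]) / min(
            pop.values.loc[g, 0.9], pop.values.loc[g, 1.1]
        )
        print(f"  {g:>3}: single-cell {f_sc:9.1f}x   population {f_pop:6.1f}x")
    print(
        "\nFeedback buys robustness: the population fold-changes are uniformly "
        "far smaller, and the depletion time is nearly flat in the two new "
        "population parameters (Kn, tau)."
    )


if __name__ == "__main__":
    main()
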