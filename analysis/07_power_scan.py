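"""Cumulative-season power contrast: kinship is detected long before reciprocity.

Fits the single-effect kinship and reciprocal models on growing prefixes of
the season sequence (reciprocal flags recomputed within each window so no
future information leaks in) and reports the first prefix at which each 95%
credible interval excludes zero.

Writes results/power_series.csv and results/power_series.png.
"""

import argparse

import pandas as pd

from starhelp import powerscan
from starhelp.datamodel import read_analysis_table
from starhelp.datamodel import HelpingLedger


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", default="results/analysis_table.csv")
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/power_series.csv")
    ap.add_argument("--plot", default="results/power_series.png")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--step", type=int, default=4)
    ap.add_argument("--chains", type=int, default=2)
    ap.add_argument("--iterations", type=int, default=1100)
    ap.add_argument("--warmup", type=int, default=350)
    args = ap.parse_args()

    table = read_analysis_table(args.table)
    visits = pd.read_csv(f"{args.data}/observations.csv")
    exposure = pd.read_csv(f"{args.data}/exposure.csv")
    nests = pd.read_csv(f"{args.data}/nests.csv")
    ledger = HelpingLedger(visits=visits, exposure=exposure)

    max_s = int(table["season"].max())
    grid = list(range(args.step, max_s + 1, args.step))
    series = []
    for effect in ("kinship", "reciprocal"):
        s = powerscan.cumulative_estimates(
            table, effect, ledger=ledger, nests=nests, season_grid=grid,
            chains=args.chains, iterations=args.iterations, warmup=args.warmup,
            seed=args.seed,
        )
        series.append(s)
        detect = powerscan.detection_season(s)
        n_fail = int((~s["converged"]).sum())
        where = f"season {detect}" if detect is not None else "never within the record"
        print(f"{effect}: detected (CrI above zero) at {where}; "
              f"{n_fail} of {len(s)} prefix fits non-converged")

    pd.concat(series, ignore_index=True).to_csv(args.out, index=False)
    powerscan.plot_power_series(series, path=args.plot)
    print(f"-> {args.out}, {args.plot}")


if __name__ == "__main__":
    main()
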