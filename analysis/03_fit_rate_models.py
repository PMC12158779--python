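"""Fit the negative-binomial multilevel helping-rate model suite.

Response: minutes of help per possible helper per nest per day, with
log(observation minutes) as offset and helper, nest and helper-breeder-pair
random intercepts.  Fits the kinship-only, reciprocal-only, joint and
generalized-reciprocity-control models on all helpers and reports standardized
coefficients with equal-tailed 95% credible intervals and incidence rate
ratios.  Reciprocal models exclude resident females (they never breed, so help
can never be returned to them through a role swap).

Writes results/model_coefficients.csv.
"""

import argparse

from starhelp.datamodel import read_analysis_table
from starhelp.ratemodel import run_model_suite, suite_coefficient_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", default="results/analysis_table.csv")
    ap.add_argument("--out", default="results/model_coefficients.csv")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--chains", type=int, default=2)
    ap.add_argument("--iterations", type=int, default=2500)
    ap.add_argument("--warmup", type=int, default=500)
    args = ap.parse_args()

    table = read_analysis_table(args.table)
    results = run_model_suite(
        table, subsets=[None], chains=args.chains, iterations=args.iterations,
        warmup=args.warmup, seed=args.seed, strict=False,
    )
    coef = suite_coefficient_table(results)
    coef.to_csv(args.out, index=False)
    print(coef.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    for res in results:
        note = "" if res.converged else "  [NOT CONVERGED]"
        print(f"{res.spec.name}: max R-hat "
              f"{res.diagnostics['max_rhat_fixed']:.3f}{note}")
    for res in results:
        for n in res.notes:
            print(f"note ({res.spec.name}): {n}")


if __name__ == "__main__":
    main()
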