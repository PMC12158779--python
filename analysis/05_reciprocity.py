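"""Reciprocal helping accounting: pairs, latencies, role switches.

Flags, for every pair ever seen helping, whether return help was observable
(the one-time helper later bred while the partner was present and not
breeding), detects pairs with help in both directions, measures latencies
between first help given and first help returned, and tallies breeder/helper
role switches per lifetime with exact binomial intervals per sex-by-dispersal
class.

Writes results/reciprocity.csv and results/reciprocity_summary.json.
"""

import argparse
import json
import os

import pandas as pd

from starhelp import datamodel, recip


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/reciprocity.csv")
    ap.add_argument("--summary", default="results/reciprocity_summary.json")
    args = ap.parse_args()

    d = args.data
    ledger, nests, individuals = datamodel.load_ledger(
        os.path.join(d, "observations.csv"),
        os.path.join(d, "nests.csv"),
        os.path.join(d, "individuals.csv"),
        exposure_csv=os.path.join(d, "exposure.csv"),
    )
    presence = datamodel.presence_from_individuals(individuals)
    observable = recip.reciprocity_possible(ledger, nests, roles=None, presence=presence)
    pairs, summary = recip.detect_reciprocal_pairs(
        ledger, nests, individuals, observable=observable
    )
    recip.pairs_to_frame(pairs).to_csv(args.out, index=False)

    roles_path = os.path.join(d, "roles.csv")
    if os.path.exists(roles_path):
        roles = pd.read_csv(roles_path)
        tallies = recip.tally_role_switches(roles, individuals, complete_lifetimes_only=True)
        summary["role_switches"] = {
            k: v for k, v in tallies.items() if k != "switch_counts"
        }

    with open(args.summary, "w") as fh:
        json.dump(summary, fh, indent=1, default=str)

    print(f"pairs ever seen helping: {summary['n_pairs_with_help']}")
    print(f"pairs with observable return help: {summary['n_observable']}")
    print(f"reciprocated pairs: {summary['n_reciprocated']}")
    if summary["mean_latency_days"] is not None:
        print(f"mean latency between help given and returned: "
              f"{summary['mean_latency_days']:.0f} days")
    if "role_switches" in summary:
        rs = summary["role_switches"]
        print(f"role switches per complete lifetime: {rs['mean_switches']:.2f} "
              f"± {rs['sem_switches']:.2f} s.e.m. (n = {rs['n_individuals']})")


if __name__ == "__main__":
    main()
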