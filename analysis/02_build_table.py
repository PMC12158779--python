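"""Build the dyad-day analysis table from the CSV bundle.

Loads the observation ledger, infers presence from first/last seasons,
zero-codes non-helping group members that were present (the rule that guards
kinship effects against group structure), attaches closest-parent
pedigree relatedness and the reciprocal-help covariate, and writes
results/analysis_table.csv.
"""

import argparse
import os

from starhelp import datamodel, recip
from starhelp.kinship import load_pedigree, pedigree_relatedness


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--out", default="results/analysis_table.csv")
    ap.add_argument("--reciprocal-mode", default="atemporal",
                    choices=["atemporal", "prior"])
    args = ap.parse_args()

    d = args.data
    ledger, nests, individuals = datamodel.load_ledger(
        os.path.join(d, "observations.csv"),
        os.path.join(d, "nests.csv"),
        os.path.join(d, "individuals.csv"),
        exposure_csv=os.path.join(d, "exposure.csv"),
    )
    relatedness = pedigree_relatedness(load_pedigree(os.path.join(d, "pedigree.csv")))
    presence = datamodel.presence_from_individuals(individuals)
    table, report = datamodel.build_analysis_table(
        ledger, presence, nests, individuals, relatedness=relatedness
    )
    table = recip.attach_reciprocal(table, ledger, nests, mode=args.reciprocal_mode)
    datamodel.write_analysis_table(table, args.out)

    zeros = (table["help_minutes"] == 0).mean()
    print(f"analysis table: {len(table)} dyad-day rows -> {args.out}")
    print(f"zero-coded rows (present non-helpers): {100 * zeros:.1f}%")
    print(f"rows flagged reciprocal ({args.reciprocal_mode}): "
          f"{100 * table['reciprocal'].mean():.1f}%")
    print(f"exclusions: {report.dropped_zero_exposure} zero-exposure nest-days, "
          f"{report.dropped_no_presence} helpers without presence records, "
          f"{report.cross_group_rows} cross-group visits retained")


if __name__ == "__main__":
    main()
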