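#!/usr/bin/env python
"""Paired control-vs-IUGR comparisons of the measured cohorts.

Aggregates the per-heart summaries from 02_measure_sarcomeres.py and, for
each age group, tests control vs IUGR on heart-level SL, ABL and TTIL with a
two-sided paired t-test and a classical one-way ANOVA (both are reported;
each row is labelled with its test).  Also prints the SL/ABL ratio of cohort
means, which should sit near 2.15 (fetal) and 2.11 (adult) regardless of
group: the ratio is a property of sarcomere architecture, not of growth
restriction.

Run from the repository root:  python analysis/03_cohort_statistics.py
"""

import argparse
from pathlib import Path

import pandas as pd

from sarcoshg.stats import compare_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    hearts = pd.read_csv(args.results / "heart_summaries.csv")
    tables = []
    for age, sub in hearts.groupby("age"):
        table = compare_all(sub)
        table["age"] = age
        tables.append(table)
        print(f"\n=== {age} cohorts ===")
        for _, row in table[table.test == "paired_t"].iterrows():
            name = row.variable.replace("_um_mean", "").upper()
            star = " *" if row.significant else ""
            print(
                f"{name:4s}: control {row.control_mean:.3f} ± {row.control_sd:.3f} vs "
                f"IUGR {row.iugr_mean:.3f} ± {row.iugr_sd:.3f} um, "
                f"paired t p = {row.pvalue:.3f}{star}"
            )
        ok = sub[~sub.excluded]
        for g in ("control", "iugr"):
            gg = ok[ok.group == g]
            ratio = gg.sl_um_mean.mean() / gg.abl_um_mean.mean()
            print(f"SL/ABL ratio of cohort means, {g}: {ratio:.3f}")

    out = pd.concat(tables, ignore_index=True)
    out.to_csv(args.results / "group_comparisons.csv", index=False)
    print(f"\nwrote {args.results}/group_comparisons.csv")


if __name__ == "__main__":
    main()
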