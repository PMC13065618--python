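#!/usr/bin/env python
"""Univariate group comparisons and biomarker-descriptor correlations.

One-way ANOVA + Tukey HSD for every descriptor across the six conditions,
then Pearson and Spearman correlation matrices between the biomarker
columns and all descriptors (raw p-values, mirroring the study's
reporting).  Prints the descriptors with the strongest group separation.

Writes results/stats/anova_tukey.csv and correlation matrices.
"""

import argparse
from pathlib import Path

import pandas as pd

from leukoflow.descriptors import CLASSICAL_COLUMNS, FEATURE_COLUMNS
from leukoflow.groupstats import anova_tukey, correlations

BIOMARKER_CANDIDATES = ["MPO", "sE_selectin", "IL8", "GM_CSF"]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    table = pd.read_csv(args.cohort, na_values=["NA"])
    table["condition"] = [f"{g}+TNF" if t else g
                          for g, t in zip(table["group"], table["tnf"])]
    desc = [c for c in list(FEATURE_COLUMNS) + list(CLASSICAL_COLUMNS)
            if c in table.columns]
    biomarkers = [c for c in BIOMARKER_CANDIDATES if c in table.columns]

    args.out.mkdir(parents=True, exist_ok=True)
    res = anova_tukey(table, desc, group_col="condition")
    res.tidy().to_csv(args.out / "anova_tukey.csv", index=False, na_rep="NA")
    top = res.anova.sort_values("p").head(8)
    print("descriptors with the strongest six-condition separation (ANOVA):")
    for var, row in top.iterrows():
        print(f"  {var:28s} F = {row['F']:8.2f}   p = {row['p']:.2e}")

    for method in ("pearson", "spearman"):
        if not biomarkers:
            break
        c, p = correlations(table, biomarkers, desc, method=method)
        c.to_csv(args.out / f"correlations_{method}_r.csv", na_rep="NA")
        p.to_csv(args.out / f"correlations_{method}_p.csv", na_rep="NA")
        strongest = c.abs().stack().sort_values(ascending=False).head(3)
        print(f"strongest {method} biomarker-descriptor correlations:")
        for (bm, d), v in strongest.items():
            print(f"  {bm} ~ {d}: |r| = {v:.2f}")
    print(f"tables written under {args.out}")


if __name__ == "__main__":
    main()
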