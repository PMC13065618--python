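#!/usr/bin/env python
"""Exploratory PCA of the descriptor space.

Correlation-matrix PCA of the 45 descriptors with eigenvalue > 1 component
retention and varimax rotation, used (as in the study design) purely to
inspect dimensionality and redundancy, never for classification.

Writes results/pca/pca_summary.csv and rotated loadings.
"""

import argparse
from pathlib import Path

import pandas as pd

from leukoflow.descriptors import FEATURE_COLUMNS
from leukoflow.discriminant import pca_varimax
from leukoflow.pipeline import prepare_design


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/pca"))
    args = ap.parse_args()

    table = pd.read_csv(args.cohort, na_values=["NA"])
    X, n_imputed = prepare_design(table, [c for c in FEATURE_COLUMNS
                                          if c in table.columns])
    res = pca_varimax(X)

    args.out.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame({
        "component": [f"PC{k+1}" for k in range(len(res.eigenvalues))],
        "eigenvalue": res.eigenvalues,
        "percent_variance": res.percent_variance,
        "retained": res.retained,
    })
    summary.to_csv(args.out / "pca_summary.csv", index=False)
    res.rotated_loadings.to_csv(args.out / "varimax_loadings.csv", na_rep="NA")

    n_ret = int(res.retained.sum())
    cum2 = res.percent_variance[:2].sum()
    print(f"{n_ret} components retained (eigenvalue > 1); "
          f"PC1 explains {res.percent_variance[0]:.1f}%, "
          f"PC1+PC2 {cum2:.1f}% of total variance")
    if res.dropped_variables:
        print(f"constant columns dropped: {res.dropped_variables}")
    if n_imputed:
        print(f"{n_imputed} missing values imputed as 0 before PCA")
    print(f"tables written under {args.out}")


if __name__ == "__main__":
    main()
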