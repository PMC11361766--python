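#!/usr/bin/env python
"""Step 4 — differential expression and the hypo-group shift.

Computes patient-vs-control differential expression from the MeRIP input
libraries (median-of-ratios normalization, Welch t, BH), then tests whether
the genes called hypomethylated in step 2 are shifted toward higher
expression relative to the non-hypo background (Wilcoxon rank-sum), and
writes the ECDF coordinates behind that comparison.

Run after steps 1-2:  python analysis/04_expression_shift.py
"""

import argparse
from pathlib import Path

import pandas as pd

from m6adecay.core_io import read_count_matrix
from m6adecay.expression import differential_expression, group_shift_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    merip = read_count_matrix(args.cohort / "merip_counts.tsv", args.cohort / "merip_meta.tsv")
    de = differential_expression(merip, "control", "patient")
    classes = pd.read_csv(args.out / "gene_classes.tsv", sep="\t", index_col="gene_id")["class"]
    hypo = set(classes.index[classes == "hypo"])

    shift, ecdf_tab = group_shift_test(de, hypo)
    args.out.mkdir(parents=True, exist_ok=True)
    de.rename_axis("gene_id").to_csv(args.out / "differential_expression.tsv", sep="\t")
    ecdf_tab.to_csv(args.out / "expression_shift_ecdf.tsv", sep="\t", index=False)
    print(f"genes tested: {len(de)}; hypo group: {shift.n_a}, background: {shift.n_b}")
    print(
        f"hypo-vs-background log2fc shift: delta_median = {shift.delta_median:.3f}, "
        f"rank-sum p = {shift.p_value:.3g}"
    )
    print(f"wrote {args.out / 'differential_expression.tsv'} and the ECDF table")


if __name__ == "__main__":
    main()
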