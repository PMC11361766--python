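#!/usr/bin/env python
"""Step 5 — reader targets, half-life shift, and the integrated report.

Calls reader-bound transcripts from RIP vs input, then joins methylation
classes (step 2), half-lives (step 3) and expression (step 4) into one
per-gene table and computes the three headline statistics: the expression
shift of hypo genes, the patient-vs-control half-life shift of hypo genes,
and the Fisher enrichment of hypo genes among reader targets.

Run after steps 1-4:  python analysis/05_reader_targets_integration.py
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from m6adecay.core_io import read_count_matrix
from m6adecay.integration import call_rip_targets, integrate_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    rip = read_count_matrix(args.cohort / "rip_counts.tsv", args.cohort / "rip_meta.tsv")
    targets = call_rip_targets(rip)
    print(f"reader targets called (padj<0.05, positive pulldown fold): {len(targets.genes)}")

    classes = pd.read_csv(args.out / "gene_classes.tsv", sep="\t", index_col="gene_id")["class"]
    de = pd.read_csv(args.out / "differential_expression.tsv", sep="\t", index_col="gene_id")
    hl = pd.read_csv(args.out / "half_lives.tsv", sep="\t")

    report, summary = integrate_report(classes, de, hl, targets)
    report.to_csv(args.out / "integrated_report.tsv", sep="\t")

    es, hs, ov = summary["expression_shift"], summary["halflife_shift"], summary["target_overlap"]
    flat = {
        "n_genes": summary["n_genes"],
        "n_hypo_called": summary["n_hypo"],
        "n_targets_called": len(targets.genes),
        "expression_shift_delta_median_log2fc": es.delta_median,
        "expression_shift_p": es.p_value,
        "halflife_median_ratio": summary["halflife_median_ratio"],
        "halflife_shift_p": hs.p_value,
        "hypo_target_odds_ratio": None if ov is None else ov.odds_ratio,
        "hypo_target_fisher_p": None if ov is None else ov.p_value,
    }
    (args.out / "headline_summary.json").write_text(json.dumps(flat, indent=2, default=float) + "\n")
    for k, v in flat.items():
        print(f"  {k}: {v}")
    print(f"wrote {args.out / 'integrated_report.tsv'} and headline_summary.json")


if __name__ == "__main__":
    main()
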