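#!/usr/bin/env python
"""Step 2 — detect methylated features and call differential methylation.

Detection: per replicate pair, features enriched in IP over input above the
unmethylated baseline mode (BH q < 0.01), kept when reproducible in >= 3
replicate pairs.  Differential test: overdispersion-moderated z on the
difference of pooled IP-vs-input log-odds, median-centered, BH-corrected,
classifying each detected feature hypo / hyper / unchanged at FDR < 0.01.

Run after step 1:  python analysis/02_differential_methylation.py
"""

import argparse
from pathlib import Path

from m6adecay.core_io import AnalysisConfig, read_count_matrix
from m6adecay.merip import (
    classify_genes,
    differential_methylation,
    replicate_enrichment_qvalues,
    significant_features,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = AnalysisConfig()

    merip = read_count_matrix(args.cohort / "merip_counts.tsv", args.cohort / "merip_meta.tsv")
    qvals = replicate_enrichment_qvalues(merip)
    detected = significant_features(qvals, cfg.fdr_methylation, cfg.min_samples)
    detected_ids = [f for f in merip.feature_ids if f in detected]
    print(f"detected methylated features (q<{cfg.fdr_methylation} in >={cfg.min_samples} reps): {len(detected_ids)}")

    calls = differential_methylation(merip.select_features(detected_ids), "control", "patient", cfg)
    classes = classify_genes(calls)

    args.out.mkdir(parents=True, exist_ok=True)
    calls.rename_axis("feature_id").to_csv(args.out / "methylation_calls.tsv", sep="\t")
    classes.rename("class").rename_axis("gene_id").to_csv(args.out / "gene_classes.tsv", sep="\t")
    n_hypo = (calls["class"] == "hypo").sum()
    n_hyper = (calls["class"] == "hyper").sum()
    print(f"differential calls at FDR<{cfg.fdr_methylation}: {n_hypo} hypo, {n_hyper} hyper")
    print(f"wrote {args.out / 'methylation_calls.tsv'} and {args.out / 'gene_classes.tsv'}")


if __name__ == "__main__":
    main()
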