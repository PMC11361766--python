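#!/usr/bin/env python
"""Step 3 — ERCC-calibrated half-life estimation from the decay time course.

Per library, log10(known spike attomole) is regressed on log10(spike CPM);
gene CPM is converted to attomole through the fit, replicates are averaged
per condition x timepoint, and the first-order rate K is the mean of the
per-timepoint rates -ln(C_t/C_0)/t over t = 3, 6 h; t1/2 = ln2/K with
non-positive rates censored.

Run after step 1:  python analysis/03_half_life_kinetics.py
"""

import argparse
from pathlib import Path

from m6adecay.core_io import read_count_matrix, read_spikein_reference
from m6adecay.decay import estimate_half_lives, fit_spikein_calibration


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    decay = read_count_matrix(args.cohort / "decay_counts.tsv", args.cohort / "decay_meta.tsv")
    ref = read_spikein_reference(args.cohort / "ercc_reference.tsv")

    fits = fit_spikein_calibration(decay, ref)
    r2 = [f.r_squared for f in fits.values()]
    print(f"spike calibration across {len(fits)} libraries: min R^2 = {min(r2):.4f}")

    hl = estimate_half_lives(decay, ref)
    args.out.mkdir(parents=True, exist_ok=True)
    hl.to_csv(args.out / "half_lives.tsv", sep="\t", index=False)
    for cond, sub in hl.groupby("condition"):
        ok = sub[~sub.censored]
        print(
            f"  {cond}: median t1/2 = {ok.halflife_h.median():.2f} h "
            f"({len(ok)} estimable, {sub.censored.sum()} censored)"
        )
    print(f"wrote {args.out / 'half_lives.tsv'}")


if __name__ == "__main__":
    main()
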