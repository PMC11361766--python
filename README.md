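# m6adecay

Spike-in-calibrated RNA decay kinetics and differential m6A methylation
analysis, with a ground-truth simulator for end-to-end validation.

## Scientific problem

N6-methyladenosine (m6A) marks on mRNA are read by proteins such as YTHDF2
that accelerate transcript degradation. If a disease state (for example,
neurons carrying a *C9ORF72* repeat expansion) loses m6A on a set of
transcripts, those transcripts escape reader-mediated decay: their
half-lives lengthen and their steady-state abundance rises. Demonstrating
this chain requires three measurements analyzed jointly:

1. **MeRIP-seq** — antibody-enriched (IP) vs input libraries locate
   m6A-marked transcripts and detect condition-dependent loss of
   methylation (hypomethylation);
2. **a transcription-shutoff decay time course** — after transcription is
   blocked, total mRNA shrinks, so within-library relative normalization
   is invalid; constant ERCC spike-ins anchor each library to the absolute
   (attomole) scale, from which first-order decay rates
   `ln(C_t/C_0) = -K t` and half-lives `t1/2 = ln2/K` follow;
3. **reader RIP-seq** — pulldown of the reader protein identifies its
   bound targets, closing the mechanistic loop: transcripts that are both
   hypomethylated and reader-bound should be the ones stabilized and
   upregulated.

This package implements each analysis stage, the bench-assay
quantifications that accompany such a study (standard-curve LC–MS m6A/A
stoichiometry, 2^-ddCt qPCR transforms, a z-scored proteomic screen), and
a negative-binomial simulator with known per-gene truth so that every
stage can be validated quantitatively.

## Model summary

The simulator draws, per gene, a methylation level *m* (a fraction of
genes is unmethylated; the rest draw *m* from a Beta distribution). In the
patient condition a fraction of methylated genes is hypomethylated
(*m* → δ·*m*, δ = 0.4). Decay couples to methylation through the reader:
`K = K0 + β·m` for reader targets, `K = K0` otherwise, so hypomethylated
targets are stabilized. Steady-state abundance scales as 1/K, which
propagates stabilization into upregulation. Sequencing counts are negative
binomial (`var = μ + φμ²`, φ = 0.05) around depth-scaled expected
proportions; IP and RIP libraries enrich each gene by `1 + gain·m`.
See `docs/methods.md` for the statistical methods and their rationale.

## Worked example

Run the numbered drivers in order (each reads the previous step's output
from `results/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_differential_methylation.py
python analysis/03_half_life_kinetics.py
python analysis/04_expression_shift.py
python analysis/05_reader_targets_integration.py
python analysis/06_bench_assays.py
```

With seed 1 this prints, along the way:

```
  genes: 2000  methylated: 1200
  truly hypomethylated in patient: 360
  reader targets: 719
detected methylated features (q<0.01 in >=3 reps): 1198
differential calls at FDR<0.01: 12 hypo, 0 hyper
spike calibration across 18 libraries: min R^2 = 0.9549
  control: median t1/2 = 4.56 h (1995 estimable, 5 censored)
  patient: median t1/2 = 4.62 h (1997 estimable, 3 censored)
hypo-vs-background log2fc shift: delta_median = 0.590, rank-sum p = 2.45e-06
reader targets called (padj<0.05, positive pulldown fold): 602
  halflife_median_ratio: 1.1751477804573076
  hypo_target_odds_ratio: 2.335570469798658
calibrated m6A/A ratio for the worked example: 0.00375
MeRIP-qPCR fold enrichment (Ct 20/18 vs 24/18): 16
```

All three headline directions reproduce: the genes called hypomethylated
are shifted up in expression (Δmedian log2fc = 0.59, rank-sum
p = 2.5×10⁻⁶), their patient/control median half-life ratio exceeds 1
(1.18), and they are enriched among called reader targets (odds ratio
2.34). The detection step recovers 1198 of the 1200 truly methylated
features with no false positives, and every hypo call is truly
hypomethylated. The same stages are also exposed as a CLI
(`m6adecay simulate|merip|decay|express|targets|integrate`).

## Reproduction

`scripts/acceptance.py` recomputes every headline quantity from scratch —
the noiseless kinetic closed loop, noisy half-life recovery, the
null-calibration and power of the differential-methylation test, the
end-to-end direction statistics on both the called gene sets and the
simulator's true sets, and the deterministic formula identities — and
writes them to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Representative output at seed 1 (runtime < 1 s):

```
"noiseless_kdecay_max_relative_error": 3.35e-15
"fraction_within_20pct_halflife_error": 0.544
"null_fraction_raw_p_below_0p05": 0.055
"hypo_call_empirical_fdr": 0.0
"truth_expression_shift_p": 3.78e-48
"truth_halflife_shift_p": 1.98e-10
"truth_hypo_target_fisher_p": 6.42e-26
"merip_qpcr_fold_enrichment_20_18_24_18": 16.0
```
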