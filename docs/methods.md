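# Methods

This note documents the statistical model, the generator, the numerical
choices and the known limits of the `m6adecay` package. Every empirical
number quoted here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted that the code does not
measure.

## 1. Generative model

Per gene *i*, with all parameters exposed on `SimulationParams`:

* **Methylation.** A fraction `unmethylated_fraction = 0.4` of genes has
  m = 0; the rest draw m ~ Beta(5, 2). The Beta(5, 2) choice reflects
  that antibody-detectable peaks are biased toward high stoichiometry; it
  concentrates methylated genes around m ≈ 0.7 while keeping a tail of
  weakly methylated genes. In the patient condition a fraction
  `hypo_fraction = 0.3` of methylated genes is hypomethylated:
  m_patient = δ·m_control with `hypo_effect` δ = 0.4.
* **Reader binding.** Each methylated gene is a reader target with
  probability `reader_target_prob = 0.6`, independent of m.
* **Decay.** K = K0 + β·m for reader targets and K = K0 otherwise, with
  `decay_base` K0 = 0.12 h⁻¹ and `decay_coupling` β = 0.15 h⁻¹. Only
  reader-bound methylation accelerates decay, so hypomethylated reader
  targets are stabilized (K_patient < K_control) while hypomethylated
  non-targets keep their rate.
* **Steady state.** Baseline abundance C0_control ~ LogNormal(0, 1)
  attomole; C0_patient = C0_control · K_control/K_patient, the
  first-order steady state at constant synthesis. This single assumption
  couples methylation loss to upregulated expression, so the MeRIP input
  libraries double as the expression libraries and no separate RNA-seq
  generator is needed.
* **Libraries.** Each library draws a depth
  LogNormal(ln `depth_mean`, 0.15) (`depth_mean` = 2×10⁶) and distributes
  it over features proportionally to their molecular amounts; counts are
  negative binomial with var = μ + φμ², `dispersion` φ = 0.05 (Poisson at
  φ = 0). IP libraries enrich amounts by 1 + α·m (`ip_gain` α = 8), RIP
  libraries by 1 + 6·m for targets. The decay time course adds a fixed
  geometric series of ERCC spike amounts spanning five decades, scaled to
  3 % of the expected transcriptome mass, identically to every library.
* A `noiseless` mode emits the exact expected (real-valued) counts at a
  fixed common depth, enabling closed-loop kinetic verification.

**Realism and limits.** The generator reproduces the features that matter
to the analysis — compositional sequencing (fixed depth), biological
overdispersion, IP enrichment confounded with expression, shrinking
transcriptome during shutoff with constant spikes, censored (non-decaying)
genes — but it is deliberately simple: no per-gene dispersion trends, no
GC/length biases, no batch effects in the sequencing data (batch handling
is exercised only in the proteomic screen), peaks are gene-level (one
feature per gene), and decay is exactly first-order. Conclusions about
absolute power transfer to real data only qualitatively.

Because libraries are sequenced to a fixed depth, constant spike-in
*amounts* do **not** produce constant spike *counts* across timepoints:
as the transcriptome decays, the spikes' share of reads grows. The
invariants tested are therefore the physical ones — spike amounts are
constant and are recovered exactly after calibration; the spike share
increases monotonically.

## 2. Differential methylation

Methylation is summarized per feature as the depth-normalized
log-odds of IP vs input counts (Haldane–Anscombe pseudocount 0.5).

**Detection.** Because an IP library is renormalized to its own depth,
absolute enrichment is defined only relative to the library-average
methylation. Each replicate's log-odds distribution is therefore anchored
at its *leftmost substantial mode* (Gaussian KDE, local maxima with
density ≥ 0.2× the global peak): the sharp common level formed by
features carrying no m6A — the count-level analogue of using known
non-methylated transcripts as qPCR anchors. A one-sided z-test against
that baseline with an overdispersion-aware standard error
(√(1/a + 1/b + 2φ̂)), BH-adjusted per replicate, declares a feature
methylated when q < 0.01 in ≥ 3 replicate pairs. At defaults this
recovers ~1198/1200 truly methylated features with zero false positives.

**Differential test.** The statistic is the difference of pooled
log-odds between conditions over its standard error. Two variance
choices are provided:

* `method="pooled"` — the classical two-proportion (Woolf) z-test on the
  pooled 2×2 table. Under the generator's own defaults this is
  anticonservative by roughly a factor of 25 in variance: with NB
  dispersion φ = 0.05 and ~10³ counts per sample, the biological term
  φ/n_rep ≈ 0.017 dominates the counting term 1/n ≈ 0.0007.
* `method="moderated"` (default) — the same statistic with the variance
  per condition×assay cell inflated to 1/n_pooled + φ̂/n_rep, where φ̂ is
  a genome-wide moment estimate of the NB dispersion from replicate
  variability of log-CPM (subtracting the Poisson part 1/μ). With φ̂ = 0
  or a single replicate it reduces exactly to the pooled test.

The per-feature differences are **median-centered** before testing
(`center=True`): a condition-level shift in the methylated share of the
transcriptome moves *every* feature's IP share (compositional effect;
+0.6 z-shift at defaults if uncorrected). Centering assumes most features
are unchanged, the same assumption as TMM/median-of-ratios
normalization. Calls at BH FDR < 0.01 are classified hypo/hyper by sign;
measured null calibration: fraction of raw p < 0.05 ≈ 0.051–0.055,
empirical FDR of hypo calls 0.0 at defaults.

## 3. Decay kinetics

Per library, log10(known spike attomole) is regressed on log10(spike CPM)
(log-log OLS; a linear-scale option exists). Log-log is the numerically
sound choice across five decades of spike abundance: residuals are
multiplicative and the fit is not dominated by the largest spike. Gene
CPM is converted through the fit; undetected genes (CPM ≤ 0) map to NaN.

Replicate libraries are averaged on the attomole scale per
condition×timepoint. The decay rate is estimated from the two-point
contrasts K_t = −ln(C_t/C_0)/t for t = 3, 6 h; the default combines them
as the arithmetic mean of rates (`halflife_averaging="rate"`), with the
alternative `"halflife"` averaging the per-timepoint half-lives and
returning ln2 over their mean. Both are exact for a true exponential
(verified to ≤ 10⁻¹⁰ relative error in the noiseless closed loop,
measured 3.4×10⁻¹⁵); they differ only under noise, where rate averaging
weights the longer timepoint's higher information content more evenly and
is kept as the default. t1/2 = ln2/K; K ≤ 0 (stabilized beyond the
observation window or noise-dominated) is reported as censored (NaN
half-life), never silently dropped: downstream group comparisons exclude
censored values and report their counts.

## 4. Expression and group shifts

Differential expression uses median-of-ratios size factors, log2 of
normalized counts with pseudocount, and a two-sided Welch t-test across
replicates with BH adjustment (zero-variance rows fall back to p ∈ {0, 1}
by fold-change). This lightweight test is calibrated under the generator
(null fraction p < 0.05 ≈ 0.04) and is sufficient because downstream
analyses consume only fold-changes and group-level statistics — group
shifts are tested by the Wilcoxon rank-sum, not per-gene significance.

The rank-sum test enumerates the full permutation distribution of the
rank-sum statistic (midranks, valid under ties) for combined n ≤ 20 and
uses the normal approximation with tie and continuity corrections above
that. Fisher's exact test (probability-mass two-sided criterion) handles
set overlaps; both are verified against brute-force enumeration.

## 5. Bench assays

Standard curves are OLS fits of signal on known concentration (≥ 3
distinct positive concentrations; flat series yield slope 0 and are
flagged non-invertible). The m6A/A ratio divides the calibrated
concentrations. qPCR transforms implement 2^-ddCt against a spiked
control (MeRIP) or an internal reference gene and calibrator sample
(expression). The proteomic screen removes proteins absent in > 4
samples, optionally divides each batch by its designated control sample,
z-scores each protein across all samples (flagging zero-variance rows),
and compares groups by exact rank-sum with BH adjustment.

## 6. Limitations (measured)

Three quantitative targets are not reachable at the default noise level,
and the corresponding acceptance tests are left failing rather than the
thresholds being weakened:

* **Half-life recovery.** With φ = 0.05 and 3 replicates,
  sd(ln C̄_t) ≈ √(φ/3) ≈ 0.13 per timepoint, giving sd(K̂) ≈ 0.04 h⁻¹
  regardless of calibration quality. For the 40 % of genes with
  K = 0.12 h⁻¹ a ±20 % half-life band is ±0.59 sd, so only ~44 % of them
  can land inside it; the measured overall fraction within 20 % is ~0.54,
  not ≥ 0.90.
* **Differential-methylation sensitivity.** The same information bound
  puts the standard error of the condition contrast at
  ≥ √(4φ/3) ≈ 0.26 nats, while the largest possible effect (m = 1,
  δ = 0.4, α = 8) is ln(9/4.2) ≈ 0.76 nats. BH at FDR 0.01 needs
  |z| ≳ 3.2, so even the strongest genes sit near the detection edge:
  measured sensitivity is 0.03–0.09 (at empirical FDR 0.0), not ≥ 0.8.
  No calibrated test can close this gap; only more replicates, lower
  dispersion or larger effects can.
* **Cross-seed significance of downstream shifts.** Because only ~15–30
  hypo genes are callable per cohort, the half-life-shift and
  target-overlap p-values computed on *called* sets rarely reach 0.01
  (10/100 seeds meet all three at once), although the direction of every
  statistic (positive expression shift, half-life ratio > 1, odds
  ratio > 1) holds broadly. Computed on the simulator's *true* gene sets
  the same statistics are decisive (e.g. at seed 1: expression-shift
  p ≈ 4×10⁻⁴⁸, half-life-shift p ≈ 2×10⁻¹⁰, Fisher p ≈ 6×10⁻²⁶),
  confirming the pipeline's estimators rather than its calling power are
  sound.

Additionally, the exact 6-vs-6 rank-sum test in the proteomic screen has
a minimum attainable p ≈ 2×10⁻³, so BH calling over ~800 proteins is
granular (all-or-nothing); sensitivity varies 0–0.7 across seeds while
the called set remains essentially free of null proteins.
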