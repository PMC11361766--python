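"""MeRIP enrichment quantification and differential methylation calling.

Methylation of a feature is summarized as the depth-normalized log2 ratio of
antibody-IP to input abundance.  Differential methylation between two
conditions is a z-test on the difference of IP-vs-input log-odds formed from
pooled depth-normalized counts (with Haldane–Anscombe pseudocount); the
standard error carries, besides the counting (Woolf) term, a genome-wide
moment estimate of the negative-binomial overdispersion of the replicate
libraries, so the test stays calibrated when biological replicate
variability exceeds counting noise.  With ``method="pooled"`` (or a single
replicate) the overdispersion term is dropped and the statistic reduces to
the classical two-proportion z-test on the pooled 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import AnalysisConfig, CountMatrix, ValidationError, bh_adjust

HYPO, HYPER, UNCHANGED = "hypo", "hyper", "unchanged"


def _pooled_assay_counts(m: CountMatrix, condition: str, assay: str) -> tuple[pd.Series, float, int]:
    """(summed counts per feature, summed library size, n replicates)."""
    try:
        sub = m.select_samples(condition=condition, assay=assay)
    except ValidationError as exc:
        raise ValidationError(
            f"condition {condition!r} lacks {assay} samples"
        ) from exc
    pooled = sub.counts.sum(axis=1)
    return pooled, float(pooled.sum()), len(sub.samples)


def compute_enrichment(m: CountMatrix, condition: str, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-feature IP-vs-input log2 enrichment for one condition.

    Counts are pooled across replicates per assay, depth-normalized, and a
    pseudocount is added before the ratio, so the value is finite and
    invariant to library depth rescaling.
    """
    ip, ip_tot, _ = _pooled_assay_counts(m, condition, "IP")
    inp, in_tot, _ = _pooled_assay_counts(m, condition, "input")
    log2_enrich = np.log2((ip + pseudocount) / ip_tot) - np.log2((inp + pseudocount) / in_tot)
    return pd.DataFrame(
        {
            "log2_enrichment": log2_enrich,
            "ip_counts": ip.astype(np.int64),
            "input_counts": inp.astype(np.int64),
        },
        index=m.counts.index,
    )


def significant_features(
    q_values: pd.DataFrame, q_threshold: float = 0.01, min_replicates: int = 3
) -> set[str]:
    """Features significant (q strictly below threshold) in enough replicates.

    ``q_values``: features x replicates frame of per-replicate q-values.
    """
    if min_replicates > q_values.shape[1]:
        raise ValidationError(
            f"min_replicates={min_replicates} exceeds the {q_values.shape[1]} replicates provided"
        )
    support = (q_values < q_threshold).sum(axis=1)
    return set(q_values.index[support >= min_replicates])


def _baseline_mode(values: np.ndarray) -> float:
    """Location of the sharpest mode of a 1-D sample (Gaussian KDE argmax).

    Because an IP library is sequenced to its own depth, IP-vs-input
    log-odds are shifted by the library-average methylation; features
    carrying no m6A form a sharp common mode at the bottom of the
    distribution (the same role non-methylated anchor transcripts play in
    MeRIP-qPCR), which serves as the zero-enrichment baseline.
    """
    kde = sps.gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    # leftmost local mode carrying substantial mass; methylated features
    # form their own (possibly taller) mode further right
    substantial = interior[dens[interior] >= 0.2 * dens.max()]
    if substantial.size == 0:
        return float(grid[np.argmax(dens)])
    return float(grid[substantial[0]])


def replicate_enrichment_qvalues(m: CountMatrix, phi: float | None = None) -> pd.DataFrame:
    """Per-replicate q-values for IP-over-input enrichment (peak detection).

    Each replicate pair (IP_r vs input_r, matched within condition) yields a
    one-sided test of enrichment above the unmethylated baseline mode: z on
    the baseline-anchored depth-normalized log-odds with an
    overdispersion-aware standard error, BH-adjusted per replicate.
    Columns are "<condition>/rep<r>".  Feeds :func:`significant_features`.
    """
    if phi is None:
        phi = _estimate_overdispersion(m)
    totals = m.counts.sum(axis=0).astype(float)
    pairs: dict[str, tuple[str, str]] = {}
    by_key = {(s.condition, s.assay, s.replicate): s.sample_id for s in m.samples}
    for (cond, assay, rep), sid in by_key.items():
        if assay != "IP":
            continue
        mate = by_key.get((cond, "input", rep))
        if mate is None:
            raise ValidationError(f"IP replicate {sid!r} has no matched input library")
        pairs[f"{cond}/rep{rep}"] = (sid, mate)
    out = {}
    for label, (ip_col, in_col) in sorted(pairs.items()):
        a = m.counts[ip_col].to_numpy(dtype=float) + 0.5
        b = m.counts[in_col].to_numpy(dtype=float) + 0.5
        ln_odds = np.log(a / totals[ip_col]) - np.log(b / totals[in_col])
        ln_odds = ln_odds - _baseline_mode(ln_odds)
        se = np.sqrt(1.0 / a + 1.0 / b + 2.0 * phi)
        p = sps.norm.sf(ln_odds / se)  # one-sided: enrichment above input
        out[label] = bh_adjust(p)
    return pd.DataFrame(out, index=m.counts.index)


def _estimate_overdispersion(m: CountMatrix) -> float:
    """Genome-wide NB dispersion phi from replicate variability of log-CPM.

    For a NB count with mean mu, Var(log count) ≈ 1/mu + phi; the per-gene
    across-replicate variance of log CPM (within each condition x assay
    group) estimates that sum, and subtracting the Poisson part and
    averaging over genes and groups isolates phi.
    """
    totals = m.counts.sum(axis=0).astype(float)
    cpm = m.counts / totals * 1e6
    mean_total = float(totals.mean())
    phis = []
    groups: dict[tuple[str, str], list[str]] = {}
    for s in m.samples:
        groups.setdefault((s.condition, s.assay), []).append(s.sample_id)
    for cols in groups.values():
        if len(cols) < 2:
            continue
        sub = np.log(cpm[cols].to_numpy() + 0.5)
        mu_counts = m.counts[cols].to_numpy(dtype=float).mean(axis=1)
        ok = mu_counts >= 5  # log variance ill-behaved at very low counts
        if not ok.any():
            continue
        s2 = sub[ok].var(axis=1, ddof=1)
        phis.append(np.mean(s2 - 1.0 / np.maximum(mu_counts[ok], 1.0)))
    if not phis:
        return 0.0
    return float(max(0.0, np.mean(phis)))


def differential_methylation(
    m: CountMatrix,
    cond_control: str,
    cond_patient: str,
    config: AnalysisConfig | None = None,
    method: str = "moderated",
    center: bool = True,
) -> pd.DataFrame:
    """Per-feature differential methylation test between two conditions.

    Returns a frame with enrich_control, enrich_patient, delta_log2
    (patient - control), p, fdr and class in {hypo, hyper, unchanged}.
    Features with zero pooled input in both conditions are dropped.
    """
    if config is None:
        config = AnalysisConfig()
    if method not in ("moderated", "pooled"):
        raise ValidationError("method must be 'moderated' or 'pooled'")
    pc = config.pseudocount

    cells = {}
    for cond in (cond_control, cond_patient):
        for assay in ("IP", "input"):
            cells[(cond, assay)] = _pooled_assay_counts(m, cond, assay)

    drop = (cells[(cond_control, "input")][0] == 0) & (cells[(cond_patient, "input")][0] == 0)
    keep = m.counts.index[~drop]
    if drop.any():
        import logging

        logging.getLogger(__name__).info(
            "differential_methylation: dropping %d feature(s) with zero pooled input in both conditions",
            int(drop.sum()),
        )

    phi = _estimate_overdispersion(m) if method == "moderated" else 0.0

    ln_odds = {}
    var = {}
    for cond in (cond_control, cond_patient):
        ip, ip_tot, n_ip = cells[(cond, "IP")]
        inp, in_tot, n_in = cells[(cond, "input")]
        ip = ip.loc[keep].to_numpy(dtype=float) + pc
        inp = inp.loc[keep].to_numpy(dtype=float) + pc
        ln_odds[cond] = np.log(ip / ip_tot) - np.log(inp / in_tot)
        var[cond] = (1.0 / ip + phi / n_ip) + (1.0 / inp + phi / n_in)

    delta_ln = ln_odds[cond_patient] - ln_odds[cond_control]
    if center:
        # IP libraries are sequenced to their own depth, so a shift in the
        # methylated share of the transcriptome moves every gene's IP share
        # (compositional effect).  Centering the log-odds differences at
        # their median removes it under the assumption that most features
        # are unchanged.
        delta_ln = delta_ln - np.median(delta_ln)
    se = np.sqrt(var[cond_control] + var[cond_patient])
    z = delta_ln / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    fdr = bh_adjust(p)

    delta_log2 = delta_ln / np.log(2)
    cls = np.where(
        (fdr < config.fdr_methylation) & (delta_log2 < 0),
        HYPO,
        np.where((fdr < config.fdr_methylation) & (delta_log2 > 0), HYPER, UNCHANGED),
    )

    enr_c = compute_enrichment(m, cond_control, pc).loc[keep, "log2_enrichment"]
    enr_p = compute_enrichment(m, cond_patient, pc).loc[keep, "log2_enrichment"]
    return pd.DataFrame(
        {
            "enrich_control": enr_c,
            "enrich_patient": enr_p,
            "delta_log2": delta_log2,
            "z": z,
            "p": p,
            "fdr": fdr,
            "class": cls,
        },
        index=keep,
    )


def classify_genes(
    calls: pd.DataFrame,
    peak_to_gene: Mapping[str, str] | None = None,
    exclude_hyper: bool = False,
) -> pd.Series:
    """Collapse peak-level calls to a two-way gene partition.

    A gene is "hypo" if at least one of its peaks is hypo, otherwise
    "non_hypo".  With ``exclude_hyper`` genes whose only significant peaks
    are hypermethylated are dropped from the background instead of being
    kept as non-hypo.  When features are already genes, pass no mapping.
    """
    if peak_to_gene is None:
        peak_to_gene = {f: f for f in calls.index}
    unmapped = [f for f in calls.index if f not in peak_to_gene]
    if unmapped:
        raise ValidationError(f"peaks without gene mapping: {unmapped[:5]}")
    genes = pd.Series({f: peak_to_gene[f] for f in calls.index}, name="gene")
    by_gene = calls["class"].groupby(genes)
    has_hypo = by_gene.apply(lambda s: (s == HYPO).any())
    has_hyper = by_gene.apply(lambda s: (s == HYPER).any())
    labels = pd.Series(np.where(has_hypo, HYPO, "non_hypo"), index=has_hypo.index)
    if exclude_hyper:
        labels = labels[~(has_hyper & ~has_hypo)]
    labels.index.name = "gene_id"
    return labels


def merip_qpcr_fold_enrichment(
    ct_ip_target: float, ct_ip_spike: float, ct_input_target: float, ct_input_spike: float
) -> float:
    """Spike-normalized MeRIP-qPCR fold enrichment of IP over input.

    Both fractions are referenced to the spiked control RNA:
    fold = 2^-[(Ct_ip_target - Ct_ip_spike) - (Ct_input_target - Ct_input_spike)].
    """
    for v in (ct_ip_target, ct_ip_spike, ct_input_target, ct_input_spike):
        if not np.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct = (ct_ip_target - ct_ip_spike) - (ct_input_target - ct_input_spike)
    return float(2.0 ** (-ddct))
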