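"""Reader-target calling, set-overlap enrichment, and the consolidated report.

The report joins, per gene, the methylation class, the expression
fold-change, the per-condition half-lives and reader-target membership, and
summarizes the three headline statistics: the hypo-vs-background expression
shift, the patient-vs-control half-life shift of hypo genes, and the
Fisher enrichment of the hypo set among reader targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import AnalysisConfig, CountMatrix, ValidationError
from .decay import HalfLifeShift, compare_half_life_groups
from .expression import ShiftResult, differential_expression, group_shift_test


@dataclass(frozen=True)
class TargetSet:
    label: str
    genes: frozenset[str]
    thresholds: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OverlapResult:
    label_a: str
    label_b: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # np.inf flags a zero off-diagonal product
    p_value: float
    universe_size: int


def call_rip_targets(
    m: CountMatrix, config: AnalysisConfig | None = None, label: str = "reader"
) -> TargetSet:
    """Reader targets: genes significantly enriched in RIP over input.

    Applies the expression filter, tests RIP vs input across replicates,
    and keeps genes with padj below the target threshold AND positive
    fold-change (upregulated-in-pulldown only).
    """
    if config is None:
        config = AnalysisConfig()
    rip = [s for s in m.samples if s.assay == "RIP"]
    inp = [s for s in m.samples if s.assay == "input"]
    if len(rip) < 2 or len(inp) < 2:
        raise ValidationError("need >= 2 RIP and >= 2 input replicates")
    # reuse the DE machinery with assay standing in for condition
    relabeled = [
        type(s)(s.sample_id, s.assay, "input", s.timepoint_h, s.replicate, s.batch)
        for s in m.samples
    ]
    mm = CountMatrix(m.counts.copy(), relabeled, m.feature_kind.copy(), real_valued=m.real_valued)
    de = differential_expression(mm, "input", "RIP", config, assay=None)
    hit = de.index[(de["padj"] < config.padj_targets) & (de["log2fc"] > 0)]
    return TargetSet(
        label,
        frozenset(hit),
        {"padj": config.padj_targets, "min_count": config.min_count, "min_samples": config.min_samples},
    )


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test (probability-mass criterion).

    Returns (sample odds ratio ad/bc with np.inf when bc = 0, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValidationError("table entries must be nonnegative integers")
    arr = np.round(arr).astype(int)
    if arr.sum() == 0:
        raise ValidationError("all-zero table")
    a, b = arr[0]
    c, d = arr[1]
    res = sps.fisher_exact(arr, alternative="two-sided")
    odds = np.inf if b * c == 0 and a * d > 0 else (a * d / (b * c) if b * c else np.nan)
    if b * c == 0 and a * d == 0:
        odds = np.nan
    return float(odds), float(res.pvalue)


def overlap_enrichment(set_a, set_b, universe, labels=("A", "B")) -> OverlapResult:
    """Fisher enrichment of two gene sets within a stated universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    stray = (set_a | set_b) - universe
    if stray:
        raise ValidationError(f"set elements outside universe: {sorted(stray)[:5]}")
    both = len(set_a & set_b)
    only_a = len(set_a - set_b)
    only_b = len(set_b - set_a)
    neither = len(universe) - both - only_a - only_b
    table = ((both, only_a), (only_b, neither))
    odds, p = fisher_exact_2x2(table)
    return OverlapResult(labels[0], labels[1], table, odds, p, len(universe))


def integrate_report(
    gene_classes: pd.Series,
    de: pd.DataFrame,
    half_lives: pd.DataFrame,
    targets: TargetSet | None,
    conditions: tuple[str, str] = ("control", "patient"),
) -> tuple[pd.DataFrame, dict]:
    """Join all layers per gene and compute the headline statistics.

    gene_classes: gene -> {hypo, non_hypo}; de: differential-expression
    frame; half_lives: long frame from the decay stage; targets: reader
    target set or None.  Returns (per-gene table sorted by gene id,
    summary dict).
    """
    if gene_classes.index.has_duplicates or de.index.has_duplicates:
        raise ValidationError("duplicate gene ids in inputs")
    ctrl, pat = conditions
    hl = half_lives.pivot(index="gene_id", columns="condition", values="halflife_h")
    if hl.index.has_duplicates:
        raise ValidationError("duplicate gene ids in half-life table")

    genes = sorted(set(gene_classes.index) | set(de.index) | set(hl.index))
    tab = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    tab["class"] = gene_classes.reindex(genes)
    tab["log2fc"] = de["log2fc"].reindex(genes)
    tab[f"halflife_{ctrl}_h"] = hl.get(ctrl, pd.Series(dtype=float)).reindex(genes)
    tab[f"halflife_{pat}_h"] = hl.get(pat, pd.Series(dtype=float)).reindex(genes)
    tab["delta_halflife_h"] = tab[f"halflife_{pat}_h"] - tab[f"halflife_{ctrl}_h"]
    tab["is_reader_target"] = (
        tab.index.isin(targets.genes) if targets is not None else False
    )

    hypo_set = set(gene_classes.index[gene_classes == "hypo"])
    summary: dict = {"n_genes": len(genes), "n_hypo": len(hypo_set)}

    shift, _ = group_shift_test(de, hypo_set)
    summary["expression_shift"] = shift

    hypo_hl = tab.loc[tab.index.isin(hypo_set)]
    hl_shift: HalfLifeShift = compare_half_life_groups(
        hypo_hl[f"halflife_{pat}_h"], hypo_hl[f"halflife_{ctrl}_h"]
    )
    summary["halflife_shift"] = hl_shift
    summary["halflife_median_ratio"] = (
        hl_shift.median_a / hl_shift.median_b if hl_shift.median_b > 0 else float("nan")
    )

    if targets is not None and targets.genes:
        universe = set(de.index)
        ov = overlap_enrichment(
            hypo_set & universe, set(targets.genes) & universe, universe,
            labels=("hypo", targets.label),
        )
        summary["target_overlap"] = ov
    else:
        summary["target_overlap"] = None
    return tab, summary
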