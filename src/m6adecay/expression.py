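"""Expression quantification, fold-changes and group-shift statistics.

Differential expression is deliberately lightweight: median-of-ratios depth
normalization, log2 fold-change with pseudocount, and a two-sided Welch
t-test across replicates, BH-adjusted.  The downstream analyses consume
only the normalized log2 fold-changes and a sanity-level significance, so a
full count-model fit is not required here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    AnalysisConfig,
    CountMatrix,
    ValidationError,
    bh_adjust,
    filter_low_expression,
    size_factors,
)
from .stats import RankSumResult, ecdf, rank_sum_test


@dataclass(frozen=True)
class ShiftResult:
    """Wilcoxon rank-sum summary of a grouped value shift."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    delta_median: float
    statistic: float
    p_value: float


def differential_expression(
    m: CountMatrix,
    cond_control: str,
    cond_patient: str,
    config: AnalysisConfig | None = None,
    assay: str | None = "input",
) -> pd.DataFrame:
    """Per-gene patient-vs-control differential expression.

    Genes are filtered (>= min_count in >= min_samples), counts are scaled
    by median-of-ratios size factors, and log2(normalized + pseudocount)
    values are compared by a two-sided Welch t-test between the replicate
    groups.  log2fc is patient minus control.  ``assay=None`` uses all
    samples of each condition; by default only input (expression) libraries
    are used.
    """
    if config is None:
        config = AnalysisConfig()
    if assay is not None:
        keep = [s for s in m.samples if s.assay == assay]
        m = CountMatrix(
            m.counts[[s.sample_id for s in keep]], keep, m.feature_kind.copy(),
            real_valued=m.real_valued,
        )
    cols_a = [s.sample_id for s in m.samples if s.condition == cond_control]
    cols_b = [s.sample_id for s in m.samples if s.condition == cond_patient]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValidationError("need >= 2 replicates per condition")

    filt = filter_low_expression(m, config.min_count, config.min_samples)
    sf = size_factors(filt)
    norm = filt.counts / sf
    logv = np.log2(norm + config.pseudocount)
    a = logv[cols_a].to_numpy()
    b = logv[cols_b].to_numpy()

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance rows trigger a precision warning; they are handled
        # explicitly below via the degenerate-row convention
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    # degenerate rows: zero variance in both groups
    degen = ~np.isfinite(p)
    p[degen & np.isclose(log2fc, 0.0)] = 1.0
    p[degen & ~np.isclose(log2fc, 0.0)] = 0.0
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "padj": bh_adjust(p),
            "mean_norm_control": norm[cols_a].mean(axis=1),
            "mean_norm_patient": norm[cols_b].mean(axis=1),
        },
        index=filt.counts.index,
    )


def group_shift_test(
    de: pd.DataFrame,
    hypo_set: set[str],
    value_col: str = "log2fc",
    labels: tuple[str, str] = ("hypo", "non_hypo"),
) -> tuple[ShiftResult, pd.DataFrame]:
    """Wilcoxon rank-sum of a per-gene value between hypo and background.

    Returns the shift summary and long-format ECDF coordinates for both
    groups (columns: group, value, ecdf).
    """
    in_hypo = de.index.isin(hypo_set)
    a = de.loc[in_hypo, value_col].to_numpy(dtype=float)
    b = de.loc[~in_hypo, value_col].to_numpy(dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty after intersection with detected genes")
    res: RankSumResult = rank_sum_test(a, b)
    frames = []
    for label, vals in zip(labels, (a, b)):
        xs, fs = ecdf(vals)
        frames.append(pd.DataFrame({"group": label, "value": xs, "ecdf": fs}))
    shift = ShiftResult(
        label_a=labels[0],
        label_b=labels[1],
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        delta_median=float(np.median(a) - np.median(b)),
        statistic=res.statistic,
        p_value=res.p_value,
    )
    return shift, pd.concat(frames, ignore_index=True)


def rtqpcr_relative_expression(
    ct_target_test: float,
    ct_reference_test: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """Relative expression by 2^-ddCt against an internal control gene.

    dCt = Ct_target - Ct_reference within each sample; ddCt is the test
    sample's dCt minus the calibrator sample's.
    """
    for v in (ct_target_test, ct_reference_test, ct_target_calibrator, ct_reference_calibrator):
        if not np.isfinite(v):
            raise ValidationError("Ct values must be finite")
    ddct = (ct_target_test - ct_reference_test) - (ct_target_calibrator - ct_reference_calibrator)
    return float(2.0 ** (-ddct))
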