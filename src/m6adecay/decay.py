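"""ERCC-calibrated absolute quantification and first-order half-life estimation.

During transcription shutoff total mRNA shrinks, so within-library relative
normalization is invalid; constant external spike-ins anchor each library to
the absolute (attomole) scale.  Per library, log10(known spike amount) is
regressed on log10(spike CPM) and the fit converts gene CPM to attomole.
Decay then follows the first-order model dC/dt = -K C, i.e.
ln(C_t/C_0) = -K t, estimated from the 0/3/6 h design, and t1/2 = ln2/K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    AnalysisConfig,
    CountMatrix,
    SpikeInReference,
    ValidationError,
    cpm_normalize,
)
from .stats import RankSumResult, rank_sum_test

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CalibrationFit:
    """Per-library CPM -> attomole conversion (log-log OLS by default)."""

    sample_id: str
    slope: float
    intercept: float
    r_squared: float
    n_spikes_used: int
    scale: str = "loglog"


@dataclass(frozen=True)
class HalfLifeShift:
    """Wilcoxon comparison of two half-life (or any) samples."""

    n_a: int
    n_b: int
    median_a: float
    median_b: float
    delta_median: float
    statistic: float
    p_value: float
    n_censored_a: int = 0
    n_censored_b: int = 0


def fit_spikein_calibration(
    m: CountMatrix, ref: SpikeInReference, scale: str = "loglog"
) -> dict[str, CalibrationFit]:
    """OLS calibration per library over spikes detected in that library."""
    if scale not in ("loglog", "linear"):
        raise ValidationError("scale must be 'loglog' or 'linear'")
    cpm = cpm_normalize(m)
    spike_ids = [s for s in ref.spike_ids if s in cpm.index]
    if len(spike_ids) < 3:
        raise ValidationError("fewer than 3 reference spikes present in the matrix")
    fits = {}
    for sid in m.sample_ids:
        v = cpm.loc[spike_ids, sid].to_numpy(dtype=float)
        amt = ref.amounts.loc[spike_ids].to_numpy(dtype=float)
        ok = v > 0
        if ok.sum() < 3:
            raise ValidationError(f"sample {sid!r}: fewer than 3 spikes with nonzero counts")
        if scale == "loglog":
            res = sps.linregress(np.log10(v[ok]), np.log10(amt[ok]))
        else:
            res = sps.linregress(v[ok], amt[ok])
        fits[sid] = CalibrationFit(
            sid, float(res.slope), float(res.intercept), float(res.rvalue**2), int(ok.sum()), scale
        )
    return fits


def cpm_to_attomole(cpm, fit: CalibrationFit):
    """Convert CPM to attomole through a calibration fit.

    Non-positive CPM (gene undetected) maps to NaN, the censoring marker.
    Accepts scalars or arrays.
    """
    arr = np.asarray(cpm, dtype=float)
    if fit.scale == "loglog":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(arr > 0, 10.0 ** (fit.slope * np.log10(np.clip(arr, 1e-300, None)) + fit.intercept), np.nan)
    else:
        out = np.where(arr > 0, fit.slope * arr + fit.intercept, np.nan)
    if np.isscalar(cpm):
        return float(out)
    return out


def estimate_kdecay(abundances, timepoints_h, averaging: str = "rate") -> tuple[float, int]:
    """First-order decay rate from a per-timepoint abundance trajectory.

    For each t > 0 with positive abundance, K_t = -ln(C_t/C_0)/t.  The
    returned rate is the arithmetic mean of the K_t ("rate" averaging) or
    ln2 over the mean of the per-timepoint half-lives ("halflife"
    averaging); both are exact for a true exponential.  Also returns the
    number of post-shutoff timepoints used.  NaN marks an inestimable gene
    (C0 missing/non-positive or no usable later timepoint).
    """
    c = np.asarray(abundances, dtype=float)
    t = np.asarray(timepoints_h, dtype=float)
    if c.shape != t.shape:
        raise ValidationError("abundances and timepoints must align")
    order = np.argsort(t)
    c, t = c[order], t[order]
    if t[0] != 0:
        raise ValidationError("timepoints must include t = 0")
    c0 = c[0]
    if not np.isfinite(c0) or c0 <= 0:
        return float("nan"), 0
    later = (t > 0) & np.isfinite(c) & (c > 0)
    if not later.any():
        return float("nan"), 0
    k_t = -np.log(c[later] / c0) / t[later]
    if averaging == "rate":
        k = float(np.mean(k_t))
    elif averaging == "halflife":
        # mean of per-timepoint half-lives, defined only if every K_t > 0
        if np.any(k_t <= 0):
            k = float(np.mean(k_t))  # fall back: censoring handled downstream
        else:
            k = LN2 / float(np.mean(LN2 / k_t))
    else:
        raise ValidationError("averaging must be 'rate' or 'halflife'")
    return k, int(later.sum())


def half_life(kdecay_per_h: float) -> float:
    """t1/2 = ln2/K for K > 0; NaN (censored) otherwise."""
    if np.isfinite(kdecay_per_h) and kdecay_per_h > 0:
        return LN2 / kdecay_per_h
    return float("nan")


def estimate_half_lives(
    m: CountMatrix,
    ref: SpikeInReference,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full decay pipeline: calibrate, average replicates, fit K per gene.

    Replicate libraries are averaged on the attomole scale per
    (condition, timepoint) before rate estimation.  Returns one row per
    gene x condition with C0, K, half-life, censoring flag and the number
    of timepoints used.
    """
    if config is None:
        config = AnalysisConfig()
    fits = fit_spikein_calibration(m, ref, scale=config.calibration_scale)
    cpm = cpm_normalize(m)
    gene_ids = m.feature_kind.index[m.feature_kind != "spikein"]
    atto = pd.DataFrame(
        {sid: cpm_to_attomole(cpm.loc[gene_ids, sid].to_numpy(), fits[sid]) for sid in m.sample_ids},
        index=gene_ids,
    )

    meta = m.meta_frame()
    conditions = sorted(meta["condition"].unique())
    timepoints = sorted(set(float(t) for t in meta["timepoint_h"].dropna()))
    rows = []
    for cond in conditions:
        profile = np.empty((len(gene_ids), len(timepoints)))
        for j, t in enumerate(timepoints):
            cols = meta.index[(meta["condition"] == cond) & (meta["timepoint_h"] == t)]
            if len(cols) == 0:
                raise ValidationError(f"no samples for condition {cond!r} at t={t}")
            profile[:, j] = np.nanmean(atto[list(cols)].to_numpy(), axis=1)
        for i, gid in enumerate(gene_ids):
            k, n_used = estimate_kdecay(profile[i], timepoints, config.halflife_averaging)
            hl = half_life(k)
            rows.append(
                {
                    "gene_id": gid,
                    "condition": cond,
                    "c0_attomole": profile[i, 0],
                    "k_per_h": k,
                    "halflife_h": hl,
                    "censored": not np.isfinite(hl),
                    "n_timepoints_used": n_used,
                }
            )
    return pd.DataFrame(rows)


def compare_half_life_groups(values_a, values_b) -> HalfLifeShift:
    """Two-sided Wilcoxon rank-sum comparison of two half-life samples.

    NaN (censored) entries are excluded and their counts reported.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    cens_a, cens_b = int(np.isnan(a).sum()), int(np.isnan(b).sum())
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 uncensored half-lives per group")
    res: RankSumResult = rank_sum_test(a, b)
    return HalfLifeShift(
        n_a=a.size,
        n_b=b.size,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        delta_median=float(np.median(a) - np.median(b)),
        statistic=res.statistic,
        p_value=res.p_value,
        n_censored_a=cens_a,
        n_censored_b=cens_b,
    )
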