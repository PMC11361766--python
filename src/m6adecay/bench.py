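"""Bench-assay quantifications: LC-MS m6A/A ratio and the proteomic screen.

The mass-spec ratio is computed from channel signals calibrated against
per-analyte standard curves (signal = slope * concentration + intercept).
The proteomic screen filters proteins by missingness, optionally divides
each batch by its designated control sample, z-scores each protein across
all retained samples, and compares groups by Wilcoxon rank-sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ValidationError, bh_adjust
from .stats import rank_sum_test


@dataclass(frozen=True)
class StandardCurve:
    analyte: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def invert(self, signal: float) -> float:
        if self.slope == 0:
            raise ValidationError(f"{self.analyte}: zero-slope curve is not invertible")
        return (signal - self.intercept) / self.slope


def fit_standard_curve(points, analyte: str = "") -> StandardCurve:
    """OLS of measured signal on known concentration.

    ``points``: iterable of (concentration, signal) pairs; needs >= 3
    distinct concentrations.  A flat (zero-signal-variance) series still
    fits, with slope 0 and r² reported as 0.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 (concentration, signal) points")
    conc, sig = pts[:, 0], pts[:, 1]
    if np.unique(conc).size < 3:
        raise ValidationError("need >= 3 distinct concentrations")
    if (conc <= 0).any():
        raise ValidationError("concentrations must be strictly positive")
    if np.allclose(sig, sig[0]):
        return StandardCurve(analyte, 0.0, float(sig[0]), 0.0, pts.shape[0])
    res = sps.linregress(conc, sig)
    return StandardCurve(
        analyte, float(res.slope), float(res.intercept), float(res.rvalue**2), pts.shape[0]
    )


def m6a_ratio(
    signal_m6a: float, signal_a: float, curve_m6a: StandardCurve, curve_a: StandardCurve
) -> float:
    """Methylation stoichiometry: calibrated [m6A] over calibrated [A]."""
    conc_m6a = curve_m6a.invert(signal_m6a)
    conc_a = curve_a.invert(signal_a)
    if conc_m6a <= 0 or conc_a <= 0:
        raise ValidationError(
            f"calibrated concentration non-positive (m6A={conc_m6a:g}, A={conc_a:g}); "
            "signal below curve range"
        )
    return float(conc_m6a / conc_a)


def proteomics_screen(
    matrix: pd.DataFrame,
    groups: pd.Series,
    max_missing: int = 4,
    batches: pd.Series | None = None,
    batch_controls: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Missingness-filtered, z-scored, Wilcoxon-tested protein screen.

    Returns (per-protein result frame, z-score matrix of retained and
    testable proteins).  Proteins absent in more than ``max_missing``
    samples are removed; zero-variance proteins are flagged and excluded
    from testing.  Batch normalization divides each batch's values by the
    batch-control sample, protein-wise.
    """
    if not set(matrix.columns) == set(groups.index):
        raise ValidationError("group labels must cover exactly the matrix samples")
    labels = set(groups.unique())
    if not labels <= {"control", "patient"}:
        raise ValidationError(f"group labels must be control/patient, got {sorted(labels)}")
    if len(labels) < 2:
        raise ValidationError("both groups must be nonempty")

    mat = matrix.copy().astype(float)
    if batches is not None:
        if batch_controls is None:
            raise ValidationError("batch normalization requested without batch_controls")
        for batch in batches.unique():
            if batch not in batch_controls:
                raise ValidationError(f"batch {batch!r} has no designated control sample")
            cols = batches.index[batches == batch]
            ctrl_col = batch_controls[batch]
            mat[cols] = mat[cols].div(mat[ctrl_col], axis=0)

    missing = mat.isna().sum(axis=1)
    kept = mat.loc[missing <= max_missing]

    mean = kept.mean(axis=1, skipna=True)
    sd = kept.std(axis=1, ddof=1, skipna=True)
    zero_var = (sd == 0) | sd.isna()
    z = kept.loc[~zero_var].sub(mean[~zero_var], axis=0).div(sd[~zero_var], axis=0)

    ctrl_cols = [c for c in mat.columns if groups[c] == "control"]
    pat_cols = [c for c in mat.columns if groups[c] == "patient"]
    rows = []
    for pid, zrow in z.iterrows():
        a = zrow[pat_cols].dropna().to_numpy()
        b = zrow[ctrl_cols].dropna().to_numpy()
        if a.size < 1 or b.size < 1:
            continue
        res = rank_sum_test(a, b)
        rows.append(
            {
                "protein_id": pid,
                "n_missing": int(missing[pid]),
                "mean_z_control": float(np.mean(b)),
                "mean_z_patient": float(np.mean(a)),
                "delta_z": float(np.mean(a) - np.mean(b)),
                "p": res.p_value,
            }
        )
    out = pd.DataFrame(rows).set_index("protein_id")
    if len(out):
        out["padj"] = bh_adjust(out["p"])
    flagged = kept.index[zero_var].tolist()
    out.attrs["zero_variance_flagged"] = flagged
    out.attrs["n_removed_missing"] = int((missing > max_missing).sum())
    return out, z
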