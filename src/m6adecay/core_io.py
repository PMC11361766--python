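"""Data model, tabular I/O and normalization/filtering primitives.

Counts are carried as a :class:`CountMatrix` — an integer feature-by-sample
matrix plus per-sample metadata — which every downstream stage consumes.
Normalized (CPM, size-factor-scaled) values are always returned as separate
real-valued frames; raw counts are never overwritten in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

VALID_ASSAYS = frozenset({"input", "IP", "RIP"})
VALID_FEATURE_KINDS = frozenset({"gene", "peak", "spikein"})


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequencing library.

    timepoint_h is the hours after transcription shutoff for decay
    time-course libraries and None for steady-state libraries.
    """

    sample_id: str
    condition: str
    assay: str
    timepoint_h: float | None = None
    replicate: int = 1
    batch: str | None = None

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValidationError(
                f"sample {self.sample_id!r}: assay {self.assay!r} not in {sorted(VALID_ASSAYS)}"
            )
        if self.timepoint_h is not None and self.timepoint_h < 0:
            raise ValidationError(f"sample {self.sample_id!r}: negative timepoint_h")
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id!r}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Feature-by-sample read counts with aligned sample metadata.

    counts: DataFrame indexed by feature id, columns are sample ids, integer
    dtype unless ``real_valued`` (noiseless simulation mode).
    feature_kind: per-feature label in {gene, peak, spikein}.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    feature_kind: pd.Series | None = None
    real_valued: bool = False

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.feature_kind is None:
            kinds = [
                "spikein" if str(f).startswith("ERCC-") else "gene"
                for f in self.counts.index
            ]
            self.feature_kind = pd.Series(kinds, index=self.counts.index)
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample_id in metadata")
        if list(self.counts.columns) != ids:
            raise ValidationError("count matrix columns do not match sample metadata order")
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dup[:5]}")
        keys = [(s.condition, s.assay, s.timepoint_h, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("(condition, assay, timepoint_h, replicate) not jointly unique")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric counts")
        if np.any(~np.isfinite(arr)) or np.any(arr < 0):
            r, c = np.argwhere(~(np.isfinite(arr) & (arr >= 0)))[0]
            raise ValidationError(
                f"invalid count at feature {self.counts.index[r]!r}, "
                f"sample {self.counts.columns[c]!r}: {arr[r, c]}"
            )
        if not self.real_valued and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at feature {self.counts.index[r]!r}, "
                    f"sample {self.counts.columns[c]!r}: {arr[r, c]}"
                )
            self.counts = self.counts.astype(np.int64)
        bad = set(self.feature_kind.unique()) - VALID_FEATURE_KINDS
        if bad:
            raise ValidationError(f"unknown feature kinds: {sorted(bad)}")
        if not self.feature_kind.index.equals(self.counts.index):
            raise ValidationError("feature_kind index does not match counts index")

    # ------------------------------------------------------------------ #
    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "condition": [s.condition for s in self.samples],
                "assay": [s.assay for s in self.samples],
                "timepoint_h": [s.timepoint_h for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "batch": [s.batch for s in self.samples],
            }
        ).set_index("sample_id", drop=False)

    def select_samples(
        self,
        condition: str | None = None,
        assay: str | None = None,
        timepoint_h: float | None = None,
    ) -> "CountMatrix":
        keep = [
            s
            for s in self.samples
            if (condition is None or s.condition == condition)
            and (assay is None or s.assay == assay)
            and (timepoint_h is None or s.timepoint_h == timepoint_h)
        ]
        if not keep:
            raise ValidationError(
                f"no samples match condition={condition!r} assay={assay!r} timepoint_h={timepoint_h!r}"
            )
        cols = [s.sample_id for s in keep]
        return CountMatrix(
            self.counts[cols], keep, self.feature_kind.copy(), real_valued=self.real_valued
        )

    def select_features(self, feature_ids: Sequence[str]) -> "CountMatrix":
        sub = self.counts.loc[list(feature_ids)]
        return CountMatrix(
            sub, list(self.samples), self.feature_kind.loc[list(feature_ids)],
            real_valued=self.real_valued,
        )

    def select_kind(self, kind: str) -> "CountMatrix":
        ids = self.feature_kind.index[self.feature_kind == kind]
        return self.select_features(list(ids))


@dataclass(frozen=True)
class SpikeInReference:
    """Known absolute amounts (attomole) of external spike-in controls."""

    amounts: pd.Series  # index spike_id, values attomole

    def __post_init__(self) -> None:
        if self.amounts.index.has_duplicates:
            raise ValidationError("duplicate spike ids in reference")
        if (self.amounts <= 0).any():
            raise ValidationError("spike amounts must be strictly positive")

    @property
    def spike_ids(self) -> list[str]:
        return list(self.amounts.index)


@dataclass
class AnalysisConfig:
    """Thresholds and options shared across pipeline stages.

    fdr_methylation: FDR cut for calling a feature hypo/hyper methylated.
    padj_targets: adjusted-p cut for reader (RIP) target calling.
    min_count / min_samples: expression filter (counts >= min_count in
    >= min_samples libraries).
    pseudocount: Haldane–Anscombe correction added wherever a log-ratio
    is formed.
    """

    fdr_methylation: float = 0.01
    padj_targets: float = 0.05
    min_count: int = 10
    min_samples: int = 3
    pseudocount: float = 0.5
    seed: int = 0
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0)
    halflife_averaging: str = "rate"  # "rate": mean of per-timepoint K; "halflife": mean of per-timepoint t1/2
    calibration_scale: str = "loglog"  # or "linear"
    exclude_hyper_from_background: bool = False

    def __post_init__(self) -> None:
        for name in ("fdr_methylation", "padj_targets"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        tp = tuple(float(t) for t in self.timepoints_h)
        if tp != tuple(sorted(tp)) or tp[0] != 0.0:
            raise ValidationError("timepoints_h must be sorted ascending and start at 0")
        self.timepoints_h = tp
        if self.halflife_averaging not in ("rate", "halflife"):
            raise ValidationError("halflife_averaging must be 'rate' or 'halflife'")
        if self.calibration_scale not in ("loglog", "linear"):
            raise ValidationError("calibration_scale must be 'loglog' or 'linear'")


# ---------------------------------------------------------------------- #
# Tabular I/O.  Single dialect: UTF-8 TSV, '#' comment lines ignored.
# ---------------------------------------------------------------------- #

def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_count_matrix(path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a count TSV (first column feature ids) plus its metadata sidecar."""
    raw = _read_tsv(path)
    raw = raw.set_index(raw.columns[0])
    meta = _read_tsv(meta_path)
    if "sample_id" not in meta.columns:
        raise ValidationError(f"{meta_path}: missing sample_id column")
    meta = meta.set_index("sample_id", drop=False)
    missing = [c for c in raw.columns if c != "feature_kind" and c not in meta.index]
    if missing:
        raise ValidationError(f"samples without metadata rows: {missing}")

    kind = None
    if "feature_kind" in raw.columns:
        kind = raw.pop("feature_kind")

    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            f = vals.index[vals.isna()][0]
            raise ValidationError(f"non-numeric count at feature {f!r}, sample {col!r}")
        if (vals < 0).any():
            f = vals.index[vals < 0][0]
            raise ValidationError(f"negative count at feature {f!r}, sample {col!r}")
        counts[col] = vals

    def _opt(row, key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)) or v in ("", "NA", "None"):
            return None
        return v

    samples = []
    for sid in counts.columns:
        row = meta.loc[sid]
        tp = _opt(row, "timepoint_h")
        batch = _opt(row, "batch")
        samples.append(
            SampleMeta(
                sample_id=sid,
                condition=str(row["condition"]),
                assay=str(row["assay"]),
                timepoint_h=None if tp is None else float(tp),
                replicate=int(row["replicate"]) if _opt(row, "replicate") else 1,
                batch=None if batch is None else str(batch),
            )
        )
    return CountMatrix(counts, samples, kind)


def write_count_matrix(m: CountMatrix, path: str | Path, meta_path: str | Path) -> None:
    out = m.counts.copy()
    out.insert(0, "feature_id", out.index)
    out["feature_kind"] = m.feature_kind
    out.to_csv(path, sep="\t", index=False)
    m.meta_frame().to_csv(meta_path, sep="\t", index=False, na_rep="")


def read_spikein_reference(path: str | Path) -> SpikeInReference:
    df = _read_tsv(path)
    if not {"spike_id", "amount_attomole"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns spike_id, amount_attomole")
    s = pd.Series(
        pd.to_numeric(df["amount_attomole"]).to_numpy(),
        index=df["spike_id"].to_numpy(),
        name="amount_attomole",
    )
    return SpikeInReference(s)


def write_spikein_reference(ref: SpikeInReference, path: str | Path) -> None:
    pd.DataFrame(
        {"spike_id": ref.amounts.index, "amount_attomole": ref.amounts.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------- #
# Normalization / filtering primitives
# ---------------------------------------------------------------------- #

def cpm_normalize(m: CountMatrix) -> pd.DataFrame:
    """Counts per million per library (columns sum to 1e6)."""
    totals = m.counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero sample(s): {zero}")
    return m.counts / totals * 1e6


def filter_low_expression(m: CountMatrix, min_count: int = 10, min_samples: int = 3) -> CountMatrix:
    """Keep features with >= min_count reads in >= min_samples libraries."""
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    if min_samples > len(m.samples):
        raise ValidationError("min_samples exceeds number of samples")
    keep = (m.counts >= min_count).sum(axis=1) >= min_samples
    return m.select_features(list(m.counts.index[keep]))


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios depth factors against a geometric-mean reference.

    Only features with nonzero counts in every library contribute to the
    reference, mirroring the standard median-of-ratios construction.
    """
    arr = m.counts.to_numpy(dtype=float)
    expressed = (arr > 0).all(axis=1)
    if not expressed.any():
        raise ValidationError(
            "no feature has nonzero counts in every sample; "
            "median-of-ratios undefined — consider CPM normalization instead"
        )
    sub = arr[expressed]
    log_ref = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def bh_adjust(p: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    arr = np.asarray(list(p), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
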