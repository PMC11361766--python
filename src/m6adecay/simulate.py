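"""Ground-truth simulator for the full study design.

Generates, with known per-gene truth, the four count datasets the pipeline
analyses:

* MeRIP libraries (input + antibody IP, two conditions) whose IP enrichment
  grows with the gene's methylation level m;
* a transcription-shutoff decay time course (0/3/6 h) on the absolute
  attomole scale with constant ERCC spike-ins, sequenced at per-library
  depths so that only spike-in calibration recovers the decay;
* reader RIP libraries whose pulldown enrichment marks m6A-bound targets;
* a proteomic abundance matrix with missingness and a down-shifted subset.

The generative model: a fraction of genes is unmethylated (m = 0), the rest
draw m from a Beta distribution.  In the patient condition a fraction f of
methylated genes is hypomethylated (m -> delta * m).  Decay follows
K = K0 + beta * m for reader-bound genes (methylation accelerates decay via
the reader) and K = K0 otherwise, so hypomethylated reader targets are
stabilized; steady-state baselines scale as 1/K, which propagates the
stabilization into upregulated expression.  Counts are negative binomial
with a shared dispersion around depth-scaled expected proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CountMatrix, SampleMeta, SpikeInReference, ValidationError


@dataclass
class SimulationParams:
    """Generative settings; defaults are the study-shaped conditions."""

    n_genes: int = 2000
    n_spikes: int = 92
    replicates_per_condition: int = 3
    depth_mean: float = 2e6
    depth_cv: float = 0.15  # lognormal sigma of per-library depth
    dispersion: float = 0.05  # NB dispersion phi (var = mu + phi mu^2)
    unmethylated_fraction: float = 0.4
    methylation_beta: tuple[float, float] = (5.0, 2.0)
    ip_gain: float = 8.0  # alpha: IP mean ∝ C0 (1 + alpha m)
    hypo_fraction: float = 0.3  # f: fraction of methylated genes hypomethylated in patient
    hypo_effect: float = 0.4  # delta: m_patient = delta * m_control for hypo genes
    decay_base: float = 0.12  # K0 (1/h)
    decay_coupling: float = 0.15  # beta (1/h per unit m, reader targets only)
    reader_gain: float = 6.0  # RIP mean ∝ C0 (1 + reader_gain m) for targets
    reader_target_prob: float = 0.6  # P(reader target | methylated)
    baseline_sigma: float = 1.0  # lognormal sigma of baseline attomole
    spike_mass_fraction: float = 0.03  # spike mass relative to transcriptome
    timepoints_h: tuple[float, ...] = (0.0, 3.0, 6.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_spikes < 3 or self.replicates_per_condition < 1:
            raise ValidationError("n_genes, n_spikes, replicates must be positive (spikes >= 3)")
        for name in ("depth_mean", "ip_gain", "decay_base", "decay_coupling", "reader_gain"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.hypo_fraction <= 1:
            raise ValidationError("hypo_fraction must lie in [0, 1]")
        if not 0 < self.hypo_effect <= 1:
            raise ValidationError("hypo_effect must lie in (0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        tp = tuple(float(t) for t in self.timepoints_h)
        if 0.0 not in tp:
            raise ValidationError("timepoints_h must include 0")
        self.timepoints_h = tp


CONTROL, PATIENT = "control", "patient"


def _gene_ids(n: int) -> list[str]:
    return [f"gene{i:05d}" for i in range(n)]


def spikein_reference(p: SimulationParams) -> SpikeInReference:
    """Fixed geometric series of spike amounts spanning five decades.

    Total spike mass is scaled to ``spike_mass_fraction`` of the expected
    transcriptome mass so simulated libraries devote a realistic few percent
    of reads to the spikes.
    """
    amounts = np.logspace(-2.5, 2.5, p.n_spikes)
    transcriptome_mass = p.n_genes * np.exp(p.baseline_sigma**2 / 2)
    amounts *= p.spike_mass_fraction * transcriptome_mass / amounts.sum()
    ids = [f"ERCC-{i:05d}" for i in range(p.n_spikes)]
    return SpikeInReference(pd.Series(amounts, index=ids, name="amount_attomole"))


def simulate_transcriptome(p: SimulationParams) -> pd.DataFrame:
    """Draw per-gene ground truth; deterministic given ``p.seed``.

    Returns a frame indexed by gene id with columns m_control, m_patient,
    is_hypo, is_reader_target, k_control, k_patient, c0_control, c0_patient
    (attomole).
    """
    rng = np.random.default_rng(p.seed)
    n = p.n_genes
    ids = _gene_ids(n)

    n_unmeth = int(round(p.unmethylated_fraction * n))
    unmeth = np.zeros(n, dtype=bool)
    unmeth[rng.choice(n, size=n_unmeth, replace=False)] = True
    m_control = np.where(
        unmeth, 0.0, rng.beta(*p.methylation_beta, size=n)
    )

    methylated = np.flatnonzero(~unmeth)
    n_hypo = int(round(p.hypo_fraction * methylated.size))
    is_hypo = np.zeros(n, dtype=bool)
    if n_hypo and p.hypo_effect < 1:
        is_hypo[rng.choice(methylated, size=n_hypo, replace=False)] = True
    m_patient = np.where(is_hypo, p.hypo_effect * m_control, m_control)

    is_target = np.zeros(n, dtype=bool)
    is_target[methylated] = rng.random(methylated.size) < p.reader_target_prob

    k_control = p.decay_base + p.decay_coupling * m_control * is_target
    k_patient = p.decay_base + p.decay_coupling * m_patient * is_target

    c0_control = rng.lognormal(mean=0.0, sigma=p.baseline_sigma, size=n)
    # first-order steady state: abundance ∝ synthesis / K
    c0_patient = c0_control * k_control / k_patient

    return pd.DataFrame(
        {
            "m_control": m_control,
            "m_patient": m_patient,
            "is_hypo": is_hypo,
            "is_reader_target": is_target,
            "k_control": k_control,
            "k_patient": k_patient,
            "c0_control": c0_control,
            "c0_patient": c0_patient,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def _nb_counts(rng: np.ndarray, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws with var = mu + phi mu^2 (Poisson at phi=0)."""
    mean = np.clip(mean, 1e-12, None)
    if phi == 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def _library(rng, amounts: np.ndarray, depth_mean: float, depth_cv: float, phi: float,
             noiseless: bool = False) -> np.ndarray:
    """One sequencing library: counts proportional to amounts at drawn depth."""
    if noiseless:
        depth = depth_mean
        return depth * amounts / amounts.sum()
    depth = depth_mean * rng.lognormal(0.0, depth_cv)
    mu = depth * amounts / amounts.sum()
    return _nb_counts(rng, mu, phi)


def simulate_merip_counts(gt: pd.DataFrame, p: SimulationParams) -> CountMatrix:
    """Input + IP libraries for both conditions.

    Input mean ∝ C0; IP mean ∝ C0 (1 + alpha m), renormalized to the IP
    library's own depth, so enrichment is only recoverable relative to the
    input after depth normalization — as in the real assay.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
    cols, metas = {}, []
    for cond in (CONTROL, PATIENT):
        c0 = gt[f"c0_{cond}"].to_numpy()
        m = gt[f"m_{cond}"].to_numpy()
        for assay, amounts in (("input", c0), ("IP", c0 * (1 + p.ip_gain * m))):
            for r in range(1, p.replicates_per_condition + 1):
                sid = f"{cond}_{assay}_rep{r}"
                cols[sid] = _library(rng, amounts, p.depth_mean, p.depth_cv, p.dispersion)
                metas.append(SampleMeta(sid, cond, assay, None, r))
    counts = pd.DataFrame(cols, index=gt.index)
    return CountMatrix(counts, metas, pd.Series("gene", index=gt.index))


def simulate_decay_timecourse(
    gt: pd.DataFrame,
    p: SimulationParams,
    ref: SpikeInReference | None = None,
    noiseless: bool = False,
) -> tuple[CountMatrix, SpikeInReference]:
    """Transcription-shutoff time course with constant ERCC spikes.

    Gene abundance decays as C(t) = C0 exp(-K t); the same spike amounts are
    added to every library.  In ``noiseless`` mode counts are the exact
    expected values (real-valued) at a fixed common depth, so the kinetic
    chain can be verified as a closed loop.
    """
    if ref is None:
        ref = spikein_reference(p)
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 2]))
    spike = ref.amounts.to_numpy()
    cols, metas = {}, []
    for cond in (CONTROL, PATIENT):
        c0 = gt[f"c0_{cond}"].to_numpy()
        k = gt[f"k_{cond}"].to_numpy()
        for t in p.timepoints_h:
            amounts = np.concatenate([c0 * np.exp(-k * t), spike])
            for r in range(1, p.replicates_per_condition + 1):
                sid = f"{cond}_t{t:g}_rep{r}"
                cols[sid] = _library(
                    rng, amounts, p.depth_mean, p.depth_cv, p.dispersion, noiseless
                )
                metas.append(SampleMeta(sid, cond, "input", float(t), r))
    index = pd.Index(list(gt.index) + list(ref.amounts.index), name="feature_id")
    kind = pd.Series(
        ["gene"] * len(gt.index) + ["spikein"] * len(ref.amounts), index=index
    )
    counts = pd.DataFrame(cols, index=index)
    return CountMatrix(counts, metas, kind, real_valued=noiseless), ref


def simulate_rip_counts(gt: pd.DataFrame, p: SimulationParams) -> CountMatrix:
    """Reader pulldown (RIP) + input libraries in the control condition.

    RIP mean ∝ C0 (1 + reader_gain * m) for reader targets and ∝ C0
    otherwise, renormalized to library depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 3]))
    c0 = gt["c0_control"].to_numpy()
    m = gt["m_control"].to_numpy()
    bound = c0 * (1 + p.reader_gain * m * gt["is_reader_target"].to_numpy())
    cols, metas = {}, []
    for assay, amounts in (("input", c0), ("RIP", bound)):
        for r in range(1, p.replicates_per_condition + 1):
            sid = f"{CONTROL}_{assay}_rep{r}"
            cols[sid] = _library(rng, amounts, p.depth_mean, p.depth_cv, p.dispersion)
            metas.append(SampleMeta(sid, CONTROL, assay, None, r))
    counts = pd.DataFrame(cols, index=gt.index)
    return CountMatrix(counts, metas, pd.Series("gene", index=gt.index))


def simulate_proteomics(
    p: SimulationParams,
    n_proteins: int = 800,
    missing_rate: float = 0.05,
    n_down: int = 80,
    downshift_log2: float = 1.0,
    samples_per_group: int = 6,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Log-normal protein abundances with a patient-down-shifted subset.

    Returns (matrix with NaN for missing values, sample->group labels,
    protein->is_downshifted truth).  Missingness is independent Bernoulli.
    """
    if not 0 <= missing_rate < 1:
        raise ValidationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([p.seed, 4]))
    prot = [f"prot{i:04d}" for i in range(n_proteins)]
    sids = [f"{g}_s{r}" for g in (CONTROL, PATIENT) for r in range(1, samples_per_group + 1)]
    groups = pd.Series(
        [CONTROL] * samples_per_group + [PATIENT] * samples_per_group, index=sids, name="group"
    )
    base = rng.lognormal(mean=8.0, sigma=1.0, size=n_proteins)
    log2_vals = np.log2(base)[:, None] + rng.normal(0.0, 0.35, size=(n_proteins, 2 * samples_per_group))
    down = np.zeros(n_proteins, dtype=bool)
    if n_down:
        down[rng.choice(n_proteins, size=min(n_down, n_proteins), replace=False)] = True
    patient_cols = np.array([groups[s] == PATIENT for s in sids])
    log2_vals[np.ix_(down, patient_cols)] -= downshift_log2
    vals = 2.0 ** log2_vals
    if missing_rate:
        vals[rng.random(vals.shape) < missing_rate] = np.nan
    mat = pd.DataFrame(vals, index=pd.Index(prot, name="protein_id"), columns=sids)
    return mat, groups, pd.Series(down, index=mat.index, name="is_downshifted")
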