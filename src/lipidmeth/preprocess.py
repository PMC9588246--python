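"""Sample/probe exclusions, lipid transforms, zygosity calling and
cell/batch adjustment, producing analysis-ready matrices.

Probe filters follow the array-QC conventions for 450K/EPIC data: a probe is
dropped if its detection p-value exceeds 0.05 in more than 1% of samples, if
its bead count is below 3 in more than 5% of samples, if it is a non-CpG or
multi-hit probe, overlaps a SNP with MAF > 0.05, or sits on a sex
chromosome.  Filters are applied in that order and each removed probe is
reported once, under the first filter that removes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import TwinCohort

FILTER_ORDER = (
    "detection",
    "beads",
    "non_cpg",
    "multi_hit",
    "snp_maf_gt_005",
    "sex_chromosome",
)


@dataclass
class ProbeQC:
    """Per-probe QC inputs: detection p-values and bead counts per sample,
    plus annotation flags (non_cpg, multi_hit, snp_maf_gt_005,
    sex_chromosome)."""

    detection_p: pd.DataFrame
    bead_counts: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        dp = self.detection_p.to_numpy()
        if np.nanmin(dp) < 0 or np.nanmax(dp) > 1:
            raise ValueError("detection p-values must lie in [0, 1]")
        bc = self.bead_counts.to_numpy()
        if (bc < 0).any() or not np.allclose(bc, np.round(bc)):
            raise ValueError("bead counts must be non-negative integers")


@dataclass
class FilterThresholds:
    detection_p: float = 0.05
    detection_frac: float = 0.01
    bead_min: int = 3
    bead_frac: float = 0.05


def apply_probe_filters(
    beta: pd.DataFrame,
    qc: ProbeQC,
    thresholds: FilterThresholds | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Drop failing probes; return the filtered matrix and a per-filter report."""
    thresholds = thresholds or FilterThresholds()
    mismatch = set(beta.index).symmetric_difference(qc.detection_p.index)
    if mismatch:
        raise ValueError(
            f"beta and QC probe sets differ by {len(mismatch)} probes: "
            f"{sorted(mismatch)[:10]}"
        )
    probes = beta.index
    det = qc.detection_p.loc[probes]
    beads = qc.bead_counts.loc[probes]
    flags = qc.flags.loc[probes]
    fails = {
        "detection": (det > thresholds.detection_p).mean(axis=1) > thresholds.detection_frac,
        "beads": (beads < thresholds.bead_min).mean(axis=1) > thresholds.bead_frac,
        "non_cpg": flags["non_cpg"].astype(bool),
        "multi_hit": flags["multi_hit"].astype(bool),
        "snp_maf_gt_005": flags["snp_maf_gt_005"].astype(bool),
        "sex_chromosome": flags["sex_chromosome"].astype(bool),
    }
    report: dict[str, list[str]] = {}
    removed = pd.Series(False, index=probes)
    for name in FILTER_ORDER:
        hit = fails[name] & ~removed
        report[name] = list(probes[hit])
        removed |= fails[name]
    return beta.loc[~removed], report


class ProbeQCFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`apply_probe_filters`."""

    def __init__(self, thresholds: FilterThresholds | None = None):
        self.thresholds = thresholds

    def fit(self, beta: pd.DataFrame, qc: ProbeQC):
        _, self.report_ = apply_probe_filters(beta, qc, self.thresholds)
        self.removed_ = sorted(set().union(*self.report_.values()))
        return self

    def transform(self, beta: pd.DataFrame) -> pd.DataFrame:
        return beta.drop(index=[p for p in self.removed_ if p in beta.index])


def exclude_samples(cohort: TwinCohort) -> tuple[TwinCohort, dict[str, int]]:
    """Remove medicated participants, samples with missing lipids, and
    flagged sex-mismatch samples; count removals per reason.

    A lipid-lowering-medication flag removes every specimen of that
    participant; a missing lipid removes the affected specimen only.
    """
    samples = cohort.samples
    report = {"medication": 0, "missing_lipid": 0, "sex_mismatch": 0}
    medicated = set(samples.loc[samples["lipid_med"].astype(bool), "participant"])
    drop = samples["participant"].isin(medicated)
    report["medication"] = int(drop.sum())
    missing = cohort.lipids.isna().any(axis=1) & ~drop
    report["missing_lipid"] = int(missing.sum())
    drop |= missing
    if "sex_mismatch" in samples.columns:
        mism = samples["sex_mismatch"].astype(bool) & ~drop
        report["sex_mismatch"] = int(mism.sum())
        drop |= mism
    return cohort.subset(samples.index[~drop]), report


def log_transform_and_trim(
    lipids: pd.DataFrame, sd_threshold: float = 3.0
) -> tuple[pd.DataFrame, dict[str, list]]:
    """Set raw-scale outliers beyond ``sd_threshold`` SDs to missing, then
    natural-log the remaining values.

    Means and SDs (sample SD, ddof=1) are computed once per lipid on the raw
    scale — a single pass, not re-estimated after trimming.
    """
    out = lipids.copy().astype(float)
    report: dict[str, list] = {}
    for col in out.columns:
        x = out[col]
        if (x <= 0).any():
            bad = x.index[x <= 0][0]
            raise ValueError(f"non-positive {col} value at sample {bad!r}")
        mean, sd = x.mean(), x.std(ddof=1)
        outlier = (x - mean).abs() > sd_threshold * sd
        report[col] = list(x.index[outlier.fillna(False)])
        out.loc[outlier, col] = np.nan
        out[col] = np.log(out[col])
    return out, report


def call_zygosity(
    snp_beta: pd.DataFrame, pair_ids, cutoff: float = 0.90
) -> pd.Series:
    """Per-pair zygosity from co-twin Pearson correlation of SNP-probe betas.

    ``snp_beta`` is probes x samples; ``pair_ids`` gives the pair of each
    column.  Pairs with r > ``cutoff`` are called MZ, otherwise DZ;
    singleton pairs (or zero-variance vectors) are 'unknown'.
    """
    if len(snp_beta) < 2:
        raise ValueError("need at least 2 SNP probes")
    pair_ids = pd.Series(np.asarray(pair_ids), index=snp_beta.columns)
    calls = {}
    for pair, cols in pair_ids.groupby(pair_ids).groups.items():
        if len(cols) != 2:
            calls[pair] = "unknown"
            continue
        a = snp_beta[cols[0]].to_numpy(float)
        b = snp_beta[cols[1]].to_numpy(float)
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"zero variance in SNP betas for pair {pair}; zygosity unknown")
            calls[pair] = "unknown"
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        calls[pair] = "MZ" if r > cutoff else "DZ"
    return pd.Series(calls, name="zygosity")


def adjust_cell_and_batch(
    beta: pd.DataFrame, cell_proportions: pd.DataFrame, batch
) -> pd.DataFrame:
    """Remove cell-composition and batch structure from a beta matrix.

    Per probe, the least-squares fit on (centered) cell proportions is
    subtracted, keeping the intercept; then, per batch, values are
    standardized probe-wise to the pooled mean and SD.  Probe-wise pooled
    means are preserved.
    """
    if list(cell_proportions.index) != list(beta.columns):
        raise ValueError("cell proportion rows must match beta columns")
    batch = pd.Series(np.asarray(batch), index=beta.columns)
    counts = batch.value_counts()
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"batches with fewer than 3 samples: {small}")

    b = beta.to_numpy(float)
    p = cell_proportions.to_numpy(float)
    pc = p - p.mean(axis=0)
    # drop dependent columns (proportions sum to ~1) via pinv
    coef = b @ pc @ np.linalg.pinv(pc.T @ pc)
    adj = b - coef @ pc.T

    pooled_mean = adj.mean(axis=1, keepdims=True)
    pooled_sd = adj.std(axis=1, ddof=1, keepdims=True)
    out = np.empty_like(adj)
    for lev in counts.index:
        cols = (batch == lev).to_numpy()
        sub = adj[:, cols]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        scale = np.divide(pooled_sd, sd, out=np.zeros_like(sd), where=sd > 0)
        out[:, cols] = pooled_mean + (sub - mu) * scale
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


class CellBatchAdjuster(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`adjust_cell_and_batch`."""

    def fit(self, beta, cell_proportions=None, batch=None):
        self.cell_proportions_ = cell_proportions
        self.batch_ = batch
        return self

    def transform(self, beta: pd.DataFrame) -> pd.DataFrame:
        return adjust_cell_and_batch(beta, self.cell_proportions_, self.batch_)


def preprocess_cohort(
    cohort: TwinCohort,
    qc: ProbeQC | None = None,
    zygosity_cutoff: float = 0.90,
    sd_threshold: float = 3.0,
) -> tuple[TwinCohort, dict]:
    """Full preprocessing pass: probe filters (if QC given), sample
    exclusions, lipid trim + log transform, zygosity calling from SNP probes.

    Returns the processed cohort (lipids on the natural-log scale) and a
    report dict.  The adjusted beta matrix for the CLPM phase is produced
    separately by :func:`adjust_cell_and_batch`.
    """
    report: dict = {}
    beta = cohort.beta
    if qc is not None:
        beta, report["probe_filters"] = apply_probe_filters(beta, qc)
        cohort = TwinCohort(cohort.samples, cohort.lipids, beta, cohort.snp_beta)
    cohort, report["sample_exclusions"] = exclude_samples(cohort)
    lipids, report["lipid_outliers"] = log_transform_and_trim(
        cohort.lipids, sd_threshold=sd_threshold
    )
    samples = cohort.samples.copy()
    if cohort.snp_beta is not None and cohort.snp_beta.shape[1] > 0:
        pair_of_col = samples.loc[cohort.snp_beta.columns, "pair_id"]
        calls = call_zygosity(cohort.snp_beta, pair_of_col, cutoff=zygosity_cutoff)
        samples["zygosity"] = samples["pair_id"].map(calls).fillna("unknown")
        report["zygosity_counts"] = calls.value_counts().to_dict()
    out = TwinCohort(samples, lipids, cohort.beta, cohort.snp_beta)
    return out, report
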