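"""Per-CpG mixed-model EWAS of methylation against blood lipids.

Each CpG's beta-value is regressed on one log-lipid with a random intercept
per twin pair (REML), adjusting for age, sex, smoking, alcohol, batch and
cell proportions (Model 1) and additionally BMI (Model 2); replication-style
runs also adjust fasting status.  Inflation is summarized by the
median-based genomic inflation factor and multiplicity by Benjamini–
Hochberg FDR within one lipid x model run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cohort import TwinCohort
from .config import LIPIDS
from .lmm import LmmFit, fit_lmm_batch

logger = logging.getLogger(__name__)

_CHI2_MEDIAN = stats.chi2.ppf(0.5, 1)  # ~0.4549


@dataclass
class EwasModelSpec:
    """Which lipid, which covariate set.

    Model 1: age, sex, smoking, alcohol, batch and cell-proportion
    covariates.  Model 2 adds BMI.  ``replication=True`` adds fasting
    status.  The twin-pair random intercept is controlled by
    ``random_effect``.
    """

    lipid: str = "TG"
    model: int = 1
    replication: bool = False
    random_effect: bool = True
    visit: str = "baseline"

    def __post_init__(self) -> None:
        if self.lipid not in LIPIDS:
            raise ValueError(f"unknown lipid {self.lipid!r}")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")


@dataclass
class EwasResult:
    """Per-CpG association output for one lipid/model run."""

    table: pd.DataFrame  # index cpg; columns beta, se, p, p_adj
    lipid: str
    model: int
    lambda_: float
    n_failed: int = 0
    n_samples: int = 0


def build_design(
    samples: pd.DataFrame, log_lipid: pd.Series, spec: EwasModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Covariate matrix with the lipid term in column 1 (after intercept at 0)."""
    parts = {
        "intercept": np.ones(len(samples)),
        "lipid": log_lipid.to_numpy(float),
        "age": samples["age"].to_numpy(float),
        "sex_male": (samples["sex"] == "male").astype(float).to_numpy(),
    }
    for var in ("smoking", "alcohol"):
        for lev in ("former", "current"):
            parts[f"{var}_{lev}"] = (samples[var] == lev).astype(float).to_numpy()
    if spec.model == 2:
        parts["bmi"] = samples["bmi"].to_numpy(float)
    if spec.replication:
        parts["fasting_lt8h"] = (samples["fasting"] == "lt8h").astype(float).to_numpy()
    batches = sorted(samples["batch"].unique())
    for lev in batches[1:]:
        parts[f"batch_{lev}"] = (samples["batch"] == lev).astype(float).to_numpy()
    cells = [c for c in samples.columns if c.startswith("cell_")]
    for c in cells[:-1]:  # drop one: proportions sum to ~1
        parts[c] = samples[c].to_numpy(float)
    X = np.column_stack(list(parts.values()))
    keep = [0, 1] + [
        j for j in range(2, X.shape[1]) if np.std(X[:, j]) > 0
    ]
    names = list(parts.keys())
    return X[:, keep], [names[j] for j in keep]


def run_ewas(cohort: TwinCohort, spec: EwasModelSpec) -> EwasResult:
    """One mixed-model fit per CpG; lambda and BH adjustment over the run.

    Expects a preprocessed cohort (lipids on the natural-log scale; trimmed
    outliers are missing and their specimens are dropped for this lipid).
    """
    mask = cohort.visit_mask(spec.visit) & cohort.lipids[spec.lipid].notna()
    samples = cohort.samples[mask]
    if samples.empty:
        raise ValueError(f"no usable {spec.visit} samples for {spec.lipid}")
    log_lipid = cohort.lipids.loc[samples.index, spec.lipid]
    X, names = build_design(samples, log_lipid, spec)
    lipid_col = names.index("lipid")
    clusters = (
        samples["pair_id"].to_numpy()
        if spec.random_effect
        else np.arange(len(samples))
    )
    Y = cohort.beta[samples.index].to_numpy(float).T  # samples x cpgs
    fits = fit_lmm_batch(X, Y, clusters)
    rows, failed = [], 0
    for cpg, fit in zip(cohort.beta.index, fits):
        if not isinstance(fit, LmmFit):
            logger.warning("EWAS fit failed for %s: %s", cpg, fit)
            failed += 1
            continue
        rows.append(
            (cpg, fit.coef[lipid_col], fit.se[lipid_col], fit.pvalues[lipid_col])
        )
    table = pd.DataFrame(rows, columns=["cpg", "beta", "se", "p"]).set_index("cpg")
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    lam = genomic_inflation(table["p"].to_numpy())
    return EwasResult(
        table=table,
        lipid=spec.lipid,
        model=spec.model,
        lambda_=lam,
        n_failed=failed,
        n_samples=len(samples),
    )


class LipidEwas(BaseEstimator):
    """Estimator wrapper: ``LipidEwas(lipid='TG', model=1).fit(cohort)``."""

    def __init__(self, lipid: str = "TG", model: int = 1, replication: bool = False):
        self.lipid = lipid
        self.model = model
        self.replication = replication

    def fit(self, cohort: TwinCohort, y=None):
        spec = EwasModelSpec(
            lipid=self.lipid, model=self.model, replication=self.replication
        )
        res = run_ewas(cohort, spec)
        self.results_ = res.table
        self.lambda_ = res.lambda_
        self.n_failed_ = res.n_failed
        self.result_ = res
        return self


def genomic_inflation(pvals) -> float:
    """Median-based genomic inflation factor.

    lambda = median(qchisq(1 - p, df=1)) / qchisq(0.5, df=1).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 clipped to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / _CHI2_MEDIAN)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_stage_replication(
    discovery, replication, alpha: float = 0.05
) -> pd.DataFrame:
    """Associations FDR-significant in discovery, carried into replication.

    ``discovery`` and ``replication`` are :class:`EwasResult` or sequences
    of them (one per lipid).  An association replicates iff its
    ``p_adj < alpha`` in both stages with coefficient signs agreeing; CpGs
    absent from replication count as not replicated.  Rows are sorted by
    discovery ``p_adj``.
    """

    def as_map(res):
        if isinstance(res, EwasResult):
            res = [res]
        return {r.lipid: r.table for r in res}

    disc, repl = as_map(discovery), as_map(replication)
    rows = []
    for lipid, dtab in disc.items():
        sig = dtab[dtab["p_adj"] < alpha]
        rtab = repl.get(lipid)
        for cpg, row in sig.iterrows():
            entry = {
                "cpg": cpg,
                "lipid": lipid,
                "beta_disc": row["beta"],
                "p_adj_disc": row["p_adj"],
                "beta_rep": np.nan,
                "p_adj_rep": np.nan,
            }
            if rtab is None or cpg not in rtab.index:
                entry["replicated"] = False
                entry["reason"] = "absent_in_replication"
            else:
                rrow = rtab.loc[cpg]
                entry["beta_rep"] = rrow["beta"]
                entry["p_adj_rep"] = rrow["p_adj"]
                if rrow["p_adj"] >= alpha:
                    entry["replicated"] = False
                    entry["reason"] = "not_significant_in_replication"
                elif np.sign(rrow["beta"]) != np.sign(row["beta"]):
                    entry["replicated"] = False
                    entry["reason"] = "direction_inconsistent"
                else:
                    entry["replicated"] = True
                    entry["reason"] = ""
            rows.append(entry)
    cols = [
        "cpg", "lipid", "beta_disc", "p_adj_disc",
        "beta_rep", "p_adj_rep", "replicated", "reason",
    ]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("p_adj_disc", kind="stable").reset_index(drop=True)
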