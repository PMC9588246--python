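"""Covariate-free residuals of lipids, methylation and BMI for the
cross-lagged phase.

Each variable is adjusted per visit for age, sex, smoking and alcohol as
fixed effects with a twin-pair random intercept; the *marginal* residual
(observed minus fixed-effect fit) is carried forward, leaving the pair
correlation to the cross-lagged model's cluster-robust inference.
Methylation residuals (computed on the cell/batch-adjusted matrix) are
additionally Z-transformed within visit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import TwinCohort
from .config import LIPIDS
from .lmm import PairRandomInterceptLMM, RotatedDesign, fit_lmm_batch

_CLPM_COVARIATES = ("age", "sex", "smoking", "alcohol")


def covariate_design(samples: pd.DataFrame) -> np.ndarray:
    """Intercept + age + sex + smoking/alcohol dummies (constant columns dropped)."""
    cols = [np.ones(len(samples)), samples["age"].to_numpy(float)]
    cols.append((samples["sex"] == "male").to_numpy(float))
    for var in ("smoking", "alcohol"):
        for lev in ("former", "current"):
            cols.append((samples[var] == lev).to_numpy(float))
    X = np.column_stack(cols)
    keep = [0] + [j for j in range(1, X.shape[1]) if np.std(X[:, j]) > 0]
    return X[:, keep]


def residualize_lipid(lipid, covariates: pd.DataFrame, pair_ids) -> np.ndarray:
    """Marginal mixed-model residuals of one (log) lipid at one visit."""
    y = np.asarray(lipid, dtype=float)
    X = covariate_design(covariates)
    fit = PairRandomInterceptLMM().fit(X, y, np.asarray(pair_ids))
    return fit.result_.resid(y)


def residualize_methylation(
    beta_adjusted: pd.DataFrame, covariates: pd.DataFrame, pair_ids
) -> pd.DataFrame:
    """Z-scored marginal residuals of adjusted beta-values at one visit.

    ``beta_adjusted`` is probes x samples (already cell/batch adjusted).
    Raises if any probe's residuals are constant, naming the CpG.
    """
    X = covariate_design(covariates)
    Y = beta_adjusted.to_numpy(float).T
    fits = fit_lmm_batch(X, Y, np.asarray(pair_ids))
    out = np.empty_like(Y)
    for j, (cpg, fit) in enumerate(zip(beta_adjusted.index, fits)):
        if isinstance(fit, Exception):
            raise RuntimeError(f"residualization failed for {cpg}: {fit}")
        r = Y[:, j] - X @ fit.coef
        sd = r.std(ddof=1)
        if sd <= 1e-10 * (1.0 + abs(r.mean())):
            raise ValueError(f"zero residual variance for CpG {cpg}")
        out[:, j] = (r - r.mean()) / sd
    return pd.DataFrame(
        out.T, index=beta_adjusted.index, columns=beta_adjusted.columns
    )


class Residualizer(BaseEstimator):
    """Builds two-wave residual panels from a preprocessed cohort.

    ``fit(cohort, beta_adjusted, cpgs=...)`` computes, per visit: residuals
    of each log-lipid and of BMI, and Z-scored residuals of the requested
    CpGs.  :meth:`panel` then assembles the complete-case two-wave panel for
    one (CpG, lipid) pair, and :meth:`mediation_panel` the six-column
    BMI/CpG/lipid panel.
    """

    def fit(self, cohort: TwinCohort, beta_adjusted: pd.DataFrame, cpgs=None):
        cpgs = list(cpgs) if cpgs is not None else list(beta_adjusted.index)
        self.resid_ = {}
        self.meta_ = {}
        for visit in ("baseline", "followup"):
            mask = cohort.visit_mask(visit)
            samples = cohort.samples[mask]
            if samples.empty:
                raise ValueError(f"no samples at visit {visit!r}")
            pair_ids = samples["pair_id"].to_numpy()
            block = {}
            for lip in LIPIDS:
                vals = cohort.lipids.loc[samples.index, lip]
                ok = vals.notna()
                r = residualize_lipid(vals[ok], samples[ok], pair_ids[ok.to_numpy()])
                block[lip] = pd.Series(r, index=samples.index[ok])
            r_bmi = residualize_lipid(samples["bmi"], samples, pair_ids)
            block["bmi"] = pd.Series(r_bmi, index=samples.index)
            meth = residualize_methylation(
                beta_adjusted.loc[cpgs, samples.index], samples, pair_ids
            )
            for cpg in cpgs:
                block[cpg] = meth.loc[cpg]
            self.resid_[visit] = block
            self.meta_[visit] = samples[["participant", "pair_id", "zygosity"]]
        self.cpgs_ = cpgs
        return self

    def _wave(self, var: str, visit: str) -> pd.Series:
        s = self.resid_[visit][var].copy()
        s.index = self.meta_[visit].loc[s.index, "participant"]
        return s

    def panel(self, cpg: str, lipid: str) -> pd.DataFrame:
        """Complete-case (lipid_b, meth_b, lipid_f, meth_f) panel, indexed by
        participant, with pair_id and zygosity attached."""
        df = pd.DataFrame(
            {
                "lipid_b": self._wave(lipid, "baseline"),
                "meth_b": self._wave(cpg, "baseline"),
                "lipid_f": self._wave(lipid, "followup"),
                "meth_f": self._wave(cpg, "followup"),
            }
        ).dropna()
        return self._attach_meta(df)

    def mediation_panel(self, mediator_cpg: str, lipid: str) -> pd.DataFrame:
        """Complete-case (X, M, Y) two-wave panel with X=BMI, M=CpG, Y=lipid."""
        df = pd.DataFrame(
            {
                "X_b": self._wave("bmi", "baseline"),
                "M_b": self._wave(mediator_cpg, "baseline"),
                "Y_b": self._wave(lipid, "baseline"),
                "X_f": self._wave("bmi", "followup"),
                "M_f": self._wave(mediator_cpg, "followup"),
                "Y_f": self._wave(lipid, "followup"),
            }
        ).dropna()
        return self._attach_meta(df)

    def bmi_panel(self, trait: str) -> pd.DataFrame:
        """Two-wave (BMI, trait) panel for the exposure-screening CLPMs;
        ``trait`` is a lipid name or a CpG id."""
        df = pd.DataFrame(
            {
                "lipid_b": self._wave("bmi", "baseline"),
                "meth_b": self._wave(trait, "baseline"),
                "lipid_f": self._wave("bmi", "followup"),
                "meth_f": self._wave(trait, "followup"),
            }
        ).dropna()
        return self._attach_meta(df)

    def _attach_meta(self, df: pd.DataFrame) -> pd.DataFrame:
        meta = self.meta_["baseline"].set_index("participant")
        df = df.join(meta[["pair_id", "zygosity"]])
        return df

    def to_long(self) -> pd.DataFrame:
        """Long-format export: participant, pair, zygosity, visit, variable, residual."""
        rows = []
        for visit, block in self.resid_.items():
            meta = self.meta_[visit]
            for var, series in block.items():
                for sid, val in series.items():
                    rows.append(
                        {
                            "participant": meta.loc[sid, "participant"],
                            "pair_id": meta.loc[sid, "pair_id"],
                            "zygosity": meta.loc[sid, "zygosity"],
                            "visit": visit,
                            "variable": var,
                            "residual": val,
                        }
                    )
        return pd.DataFrame(rows)
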