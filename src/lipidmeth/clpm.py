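"""Two-variable, two-wave cross-lagged panel model (CLPM) with
twin-cluster-robust inference and SRMR/CFI fit indices.

The CLPM regresses each follow-up variable on both baseline variables:
autoregressions plus the cross-lagged paths rho1 (lipid_b -> meth_f) and
rho2 (meth_b -> lipid_f).  With freely correlated baseline variables and
freely correlated disturbances the model is saturated (zero degrees of
freedom), and the maximum-likelihood path estimates coincide exactly with
per-equation least squares — which is how they are computed here.  Standard
errors are cluster-robust (CR0 by default) over twin pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .ewas import bh_fdr

PANEL_COLUMNS = ("lipid_b", "meth_b", "lipid_f", "meth_f")

_ZERO_TOL = 1e-9  # discrepancy values below this are numerical noise


def fml_discrepancy(sample_cov: np.ndarray, model_cov: np.ndarray) -> float:
    """Maximum-likelihood discrepancy F_ML(S, Sigma)."""
    p = sample_cov.shape[0]
    sign, logdet_m = np.linalg.slogdet(model_cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("model covariance is singular")
    _, logdet_s = np.linalg.slogdet(sample_cov)
    return float(logdet_m - logdet_s + np.trace(sample_cov @ np.linalg.inv(model_cov)) - p)


def _srmr(sample_cov: np.ndarray, model_cov: np.ndarray) -> float:
    p = sample_cov.shape[0]
    d = np.sqrt(np.outer(np.diag(sample_cov), np.diag(sample_cov)))
    resid = (sample_cov - model_cov) / d
    tri = np.tril_indices(p)
    return float(np.sqrt(np.mean(resid[tri] ** 2)))


def safe_fit_indices(sample_cov, model_cov, n, df_model) -> tuple[float, float]:
    """Like :func:`fit_indices` but returns (SRMR, NaN) when the implied
    covariance is singular (e.g. a noiseless panel), instead of raising."""
    try:
        return fit_indices(sample_cov, model_cov, n, df_model)
    except np.linalg.LinAlgError:
        return _srmr(np.asarray(sample_cov, float), np.asarray(model_cov, float)), float("nan")


def fit_indices(
    sample_cov, model_cov, n: int, df_model: int
) -> tuple[float, float]:
    """SRMR and CFI of a covariance-structure fit.

    SRMR is the root mean square of standardized covariance residuals over
    the unique lower triangle (diagonal included).  CFI compares
    ``T = n * F_ML`` against the diagonal (independence) baseline model:
    ``CFI = 1 - max(T_m - df_m, 0) / max(T_b - df_b, T_m - df_m, 0)``.
    Discrepancies below numerical noise are treated as exact fit.
    """
    s = np.asarray(sample_cov, dtype=float)
    m = np.asarray(model_cov, dtype=float)
    if s.shape != m.shape or s.shape[0] != s.shape[1]:
        raise ValueError("covariance matrices must be square and same order")
    if not (np.allclose(s, s.T) and np.allclose(m, m.T)):
        raise ValueError("covariance matrices must be symmetric")
    p = s.shape[0]
    srmr = _srmr(s, m)

    t_model = n * fml_discrepancy(s, m)
    t_base = n * fml_discrepancy(s, np.diag(np.diag(s)))
    df_base = p * (p - 1) // 2
    num = max(t_model - df_model, 0.0)
    if num < _ZERO_TOL:
        num = 0.0
    denom = max(t_base - df_base, num, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - num / denom
    return srmr, float(np.clip(cfi, 0.0, 1.0))


def _cluster_sandwich(xb: np.ndarray, resid: np.ndarray, clusters: np.ndarray, cr1: bool):
    """Cluster-robust covariance of per-equation OLS path estimates.

    ``xb``: n x k shared regressors; ``resid``: n x q equation residuals.
    Coefficient order: equation-major ([eq1 coefs, eq2 coefs, ...]).
    """
    n, k = xb.shape
    q = resid.shape[1]
    bread1 = np.linalg.inv(xb.T @ xb)
    bread = np.kron(np.eye(q), bread1)
    codes, _ = pd.factorize(clusters)
    g = codes.max() + 1
    scores = np.empty((g, q * k))
    for c in range(g):
        idx = codes == c
        xc = xb[idx]
        scores[c] = (xc.T @ resid[idx]).T.reshape(-1)  # equation-major
    meat = scores.T @ scores
    if cr1:
        meat = meat * g / (g - 1)
    return bread @ meat @ bread, g


@dataclass
class ClpmFit:
    """Point estimates, cluster-robust inference and fit of one CLPM."""

    auto_lipid: float
    auto_meth: float
    rho1: float
    rho2: float
    se: dict
    pvalues: dict
    srmr: float
    cfi: float
    n: int
    n_clusters: int


class CrossLaggedPanelModel(BaseEstimator):
    """Two-wave CLPM estimated by per-equation least squares.

    Parameters
    ----------
    se_type : 'cr0' (default) cluster-robust sandwich without small-sample
        correction, 'cr1' with the G/(G-1) correction, or 'classical'.
    min_clusters : minimum number of twin-pair clusters required.
    """

    def __init__(self, se_type: str = "cr0", min_clusters: int = 10):
        self.se_type = se_type
        self.min_clusters = min_clusters

    def fit(self, panel, clusters=None):
        if isinstance(panel, pd.DataFrame):
            data = panel[list(PANEL_COLUMNS)].to_numpy(float)
            if clusters is None and "pair_id" in panel.columns:
                clusters = panel["pair_id"].to_numpy()
        else:
            data = np.asarray(panel, dtype=float)
        n = data.shape[0]
        if clusters is None:
            clusters = np.arange(n)  # singletons are their own cluster
        clusters = np.asarray(clusters)
        n_clusters = len(pd.unique(clusters))
        if n_clusters < self.min_clusters:
            raise ValueError(
                f"need at least {self.min_clusters} clusters, got {n_clusters}"
            )
        n_params = 4
        if n_clusters < n_params:
            raise ValueError("fewer clusters than parameters")

        centered = data - data.mean(axis=0)
        xb, fw = centered[:, :2], centered[:, 2:]
        sxx = xb.T @ xb
        if np.linalg.cond(sxx) > 1e10:
            raise ValueError("collinear baseline variables")
        coefs = np.linalg.solve(sxx, xb.T @ fw)  # k x q; column j = equation j
        bmat = coefs.T  # rows: (lipid_f, meth_f) on (lipid_b, meth_b)
        resid = fw - xb @ coefs

        vcov, g = _cluster_sandwich(xb, resid, clusters, cr1=self.se_type == "cr1")
        k = 2
        dof = n - k
        sig = (resid**2).sum(axis=0) / dof
        classical = np.kron(np.diag(sig), np.linalg.inv(sxx))
        if self.se_type == "classical":
            vcov = classical

        # theta order (equation-major): eq lipid_f: (auto_lipid, rho2); eq meth_f: (rho1, auto_meth)
        theta = coefs.T.reshape(-1)
        se = np.sqrt(np.diag(vcov))
        z = theta / se
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        names = ["auto_lipid", "rho2", "rho1", "auto_meth"]
        self.params_ = pd.Series(theta, index=names)[
            ["auto_lipid", "auto_meth", "rho1", "rho2"]
        ]
        self.se_ = pd.Series(se, index=names)[self.params_.index]
        self.pvalues_ = pd.Series(pvals, index=names)[self.params_.index]
        self.se_classical_ = pd.Series(np.sqrt(np.diag(classical)), index=names)[
            self.params_.index
        ]
        self.vcov_ = vcov
        self.path_matrix_ = bmat
        self.n_, self.n_clusters_ = n, n_clusters

        s = centered.T @ centered / n
        phi = s[:2, :2]
        psi = resid.T @ resid / n
        implied = np.block(
            [[phi, phi @ bmat.T], [bmat @ phi, bmat @ phi @ bmat.T + psi]]
        )
        self.sample_cov_ = s
        self.implied_cov_ = implied
        self.df_model_ = 0
        self.srmr_, self.cfi_ = safe_fit_indices(s, implied, n, self.df_model_)
        return self


def fit_clpm(panel, cluster=None, se_type: str = "cr0") -> ClpmFit:
    """Functional wrapper over :class:`CrossLaggedPanelModel`."""
    m = CrossLaggedPanelModel(se_type=se_type).fit(panel, clusters=cluster)
    return ClpmFit(
        auto_lipid=float(m.params_["auto_lipid"]),
        auto_meth=float(m.params_["auto_meth"]),
        rho1=float(m.params_["rho1"]),
        rho2=float(m.params_["rho2"]),
        se=m.se_.to_dict(),
        pvalues=m.pvalues_.to_dict(),
        srmr=m.srmr_,
        cfi=m.cfi_,
        n=m.n_,
        n_clusters=m.n_clusters_,
    )


def clpm_panel_screen(
    associations: pd.DataFrame,
    residualizer,
    strata=("all",),
    alpha: float = 0.05,
    se_type: str = "cr0",
    fdr_scope: str = "stratum",
) -> pd.DataFrame:
    """Fit a CLPM per validated (CpG, lipid) pair, per zygosity stratum.

    ``associations`` needs columns ``cpg`` and ``lipid`` (e.g. the
    replicated rows of :func:`lipidmeth.ewas.two_stage_replication`).
    BH adjustment is applied across all (CpG, lipid, direction) hypotheses
    within a stratum (``fdr_scope='stratum'``) or per lipid
    (``fdr_scope='lipid'``).  Strata with fewer than 10 pairs are skipped
    with a warning.
    """
    rows = []
    for stratum in strata:
        stratum_rows = []
        for _, assoc in associations.iterrows():
            panel = residualizer.panel(assoc["cpg"], assoc["lipid"])
            if stratum != "all":
                panel = panel[panel["zygosity"] == stratum.upper()]
            n_pairs = panel["pair_id"].nunique() if len(panel) else 0
            if n_pairs < 10:
                warnings.warn(
                    f"stratum {stratum!r}: only {n_pairs} pairs for "
                    f"{assoc['cpg']}x{assoc['lipid']}; skipped"
                )
                continue
            m = CrossLaggedPanelModel(se_type=se_type).fit(panel)
            stratum_rows.append(
                {
                    "stratum": stratum,
                    "cpg": assoc["cpg"],
                    "lipid": assoc["lipid"],
                    **{f"{k}": v for k, v in m.params_.items()},
                    **{f"se_{k}": v for k, v in m.se_.items()},
                    "p_rho1": m.pvalues_["rho1"],
                    "p_rho2": m.pvalues_["rho2"],
                    "srmr": m.srmr_,
                    "cfi": m.cfi_,
                    "n": m.n_,
                    "n_clusters": m.n_clusters_,
                }
            )
        if not stratum_rows:
            continue
        sdf = pd.DataFrame(stratum_rows)
        if fdr_scope == "lipid":
            for lip, idx in sdf.groupby("lipid").groups.items():
                pv = np.concatenate([sdf.loc[idx, "p_rho1"], sdf.loc[idx, "p_rho2"]])
                adj = bh_fdr(pv)
                half = len(idx)
                sdf.loc[idx, "p_adj_rho1"] = adj[:half]
                sdf.loc[idx, "p_adj_rho2"] = adj[half:]
        else:
            pv = np.concatenate([sdf["p_rho1"], sdf["p_rho2"]])
            adj = bh_fdr(pv)
            half = len(sdf)
            sdf["p_adj_rho1"] = adj[:half]
            sdf["p_adj_rho2"] = adj[half:]
        rows.append(sdf)
    if not rows:
        return pd.DataFrame()
    return pd.concat(rows, ignore_index=True)
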