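"""Three-variable, two-wave cross-lagged mediation of BMI -> methylation -> lipid.

The structural system (X exposure, M mediator, Y outcome; b = baseline,
f = follow-up):

    X_f = beta_X X_b + eps_Xf
    M_f = beta_M M_b + a X_b + eps_Mf
    Y_f = beta_Y Y_b + b M_b + c' X_b + eps_Yf

Indirect effect = a*b, direct = c', total = a*b + c'; the mediation
proportion is a*b / (a*b + c'), reported only when indirect and total share
sign (consistent mediation).  Estimation is per-equation least squares with
cluster-robust (twin-pair) sandwich covariance across all six path
parameters; indirect/proportion inference uses the delta method, with a
cluster bootstrap available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .clpm import CrossLaggedPanelModel, safe_fit_indices

MEDIATION_COLUMNS = ("X_b", "M_b", "Y_b", "X_f", "M_f", "Y_f")

#: per-equation regressor sets (indices into the centered baseline block)
_EQUATIONS = (
    ("X_f", ("X_b",)),
    ("M_f", ("M_b", "X_b")),
    ("Y_f", ("Y_b", "M_b", "X_b")),
)
_PARAM_OF = {
    ("X_f", "X_b"): "beta_x",
    ("M_f", "M_b"): "beta_m",
    ("M_f", "X_b"): "a",
    ("Y_f", "Y_b"): "beta_y",
    ("Y_f", "M_b"): "b",
    ("Y_f", "X_b"): "c_prime",
}
_TOTAL_TOL = 1e-10


@dataclass
class MediationFit:
    """Path coefficients and effect decomposition of one mediation CLPM."""

    params: dict
    se: dict
    pvalues: dict
    indirect: float
    direct: float
    total: float
    proportion_mediated: float  # NaN for inconsistent/degenerate mediation
    indirect_se: float
    total_se: float
    proportion_se: float
    srmr: float
    cfi: float
    n: int
    n_clusters: int
    degenerate_indirect: bool = False
    bootstrap_ci: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert abs(self.indirect + self.direct - self.total) < 1e-12


class MediationCLPM(BaseEstimator):
    """Two-wave mediation path model (sklearn-style).

    ``fit`` accepts a DataFrame with columns X_b, M_b, Y_b, X_f, M_f, Y_f
    (plus optional pair_id used as clusters) or an (n, 6) array.
    """

    def __init__(self, se_type: str = "cr0", min_clusters: int = 10):
        self.se_type = se_type
        self.min_clusters = min_clusters

    def fit(self, panel, clusters=None):
        if isinstance(panel, pd.DataFrame):
            data = panel[list(MEDIATION_COLUMNS)].to_numpy(float)
            if clusters is None and "pair_id" in panel.columns:
                clusters = panel["pair_id"].to_numpy()
        else:
            data = np.asarray(panel, dtype=float)
        n = data.shape[0]
        if clusters is None:
            clusters = np.arange(n)
        clusters = np.asarray(clusters)
        codes, _ = pd.factorize(clusters)
        g = codes.max() + 1
        if g < self.min_clusters:
            raise ValueError(f"need at least {self.min_clusters} clusters, got {g}")

        centered = data - data.mean(axis=0)
        cols = {c: centered[:, j] for j, c in enumerate(MEDIATION_COLUMNS)}
        s_bb = centered[:, :3].T @ centered[:, :3]
        if np.linalg.cond(s_bb) > 1e10:
            raise ValueError("collinear baseline triple")

        params: dict[str, float] = {}
        stack_names: list[str] = []
        breads, resids, xmats = [], [], []
        for yname, regs in _EQUATIONS:
            X = np.column_stack([cols[r] for r in regs])
            y = cols[yname]
            xtx = X.T @ X
            coef = np.linalg.solve(xtx, X.T @ y)
            for r, c in zip(regs, coef):
                params[_PARAM_OF[(yname, r)]] = float(c)
                stack_names.append(_PARAM_OF[(yname, r)])
            breads.append(np.linalg.inv(xtx))
            resids.append(y - X @ coef)
            xmats.append(X)

        # stacked cluster-robust sandwich over all six path parameters
        dims = [b.shape[0] for b in breads]
        bread = np.zeros((sum(dims), sum(dims)))
        ofs = np.cumsum([0] + dims)
        for j, b in enumerate(breads):
            bread[ofs[j] : ofs[j + 1], ofs[j] : ofs[j + 1]] = b
        scores = np.zeros((g, sum(dims)))
        for c in range(g):
            idx = codes == c
            parts = [xm[idx].T @ e[idx] for xm, e in zip(xmats, resids)]
            scores[c] = np.concatenate(parts)
        meat = scores.T @ scores
        if self.se_type == "cr1":
            meat = meat * g / (g - 1)
        vcov = bread @ meat @ bread
        if self.se_type == "classical":
            blocks = []
            for b, e, d in zip(breads, resids, dims):
                blocks.append(b * (e @ e) / (n - d))
            vcov = np.zeros_like(vcov)
            for j, blk in enumerate(blocks):
                vcov[ofs[j] : ofs[j + 1], ofs[j] : ofs[j + 1]] = blk

        self.params_ = pd.Series(params)
        self.vcov_ = pd.DataFrame(vcov, index=stack_names, columns=stack_names)
        se = np.sqrt(np.diag(vcov))
        self.se_ = pd.Series(se, index=stack_names)[self.params_.index]
        z = self.params_ / self.se_
        self.pvalues_ = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=z.index)
        self.n_, self.n_clusters_ = n, int(g)

        # effect decomposition + delta-method inference
        a, b_ = params["a"], params["b"]
        c_prime = params["c_prime"]
        v = self.vcov_
        va, vb, cab = v.loc["a", "a"], v.loc["b", "b"], v.loc["a", "b"]
        self.indirect_ = a * b_
        self.direct_ = c_prime
        self.total_ = self.indirect_ + self.direct_
        self.indirect_se_ = float(
            np.sqrt(max(b_**2 * va + a**2 * vb + 2 * a * b_ * cab, 0.0))
        )
        grad_t = np.array([b_, a, 1.0])
        sub = v.loc[["a", "b", "c_prime"], ["a", "b", "c_prime"]].to_numpy()
        self.total_se_ = float(np.sqrt(max(grad_t @ sub @ grad_t, 0.0)))
        tot = self.total_
        if abs(tot) < _TOTAL_TOL or self.indirect_ * tot < 0:
            self.proportion_ = float("nan")
            self.proportion_se_ = float("nan")
        else:
            self.proportion_ = self.indirect_ / tot
            grad_p = np.array(
                [b_ * c_prime / tot**2, a * c_prime / tot**2, -a * b_ / tot**2]
            )
            self.proportion_se_ = float(np.sqrt(max(grad_p @ sub @ grad_p, 0.0)))
        self.degenerate_indirect_ = bool(abs(a) < 1e-10 and abs(b_) < 1e-10)

        # fit indices: free baseline covariances + free disturbance covariances
        s = centered.T @ centered / n
        bmat = np.array(
            [
                [params["beta_x"], 0.0, 0.0],
                [params["a"], params["beta_m"], 0.0],
                [params["c_prime"], params["b"], params["beta_y"]],
            ]
        )
        phi = s[:3, :3]
        emat = np.column_stack(resids)
        psi = emat.T @ emat / n
        implied = np.block(
            [[phi, phi @ bmat.T], [bmat @ phi, bmat @ phi @ bmat.T + psi]]
        )
        self.path_matrix_ = bmat
        self.sample_cov_, self.implied_cov_ = s, implied
        self.df_model_ = 3  # the omitted cross-paths
        self.srmr_, self.cfi_ = safe_fit_indices(s, implied, n, self.df_model_)
        self._centered, self._clusters = centered, clusters
        return self

    def bootstrap(self, n_boot: int = 1999, seed: int = 0) -> dict:
        """Percentile cluster-bootstrap CIs for indirect/total/proportion."""
        rng = np.random.default_rng(seed)
        codes, _ = pd.factorize(self._clusters)
        g = codes.max() + 1
        by_cluster = [np.flatnonzero(codes == c) for c in range(g)]
        stats_ = {"indirect": [], "total": [], "proportion": []}
        for _ in range(n_boot):
            pick = rng.integers(0, g, size=g)
            idx = np.concatenate([by_cluster[c] for c in pick])
            m = MediationCLPM(se_type="classical", min_clusters=2).fit(
                self._centered[idx]
            )
            stats_["indirect"].append(m.indirect_)
            stats_["total"].append(m.total_)
            stats_["proportion"].append(m.proportion_)
        out = {}
        for key, vals in stats_.items():
            arr = np.asarray(vals, dtype=float)
            arr = arr[np.isfinite(arr)]
            out[key] = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
        return out


def fit_mediation_clpm(
    X_b, X_f, M_b, M_f, Y_b, Y_f, cluster=None, se_type: str = "cr0"
) -> MediationFit:
    """Functional wrapper over :class:`MediationCLPM`."""
    panel = np.column_stack([X_b, M_b, Y_b, X_f, M_f, Y_f])
    m = MediationCLPM(se_type=se_type).fit(panel, clusters=cluster)
    return MediationFit(
        params=m.params_.to_dict(),
        se=m.se_.to_dict(),
        pvalues=m.pvalues_.to_dict(),
        indirect=m.indirect_,
        direct=m.direct_,
        total=m.total_,
        proportion_mediated=m.proportion_,
        indirect_se=m.indirect_se_,
        total_se=m.total_se_,
        proportion_se=m.proportion_se_,
        srmr=m.srmr_,
        cfi=m.cfi_,
        n=m.n_,
        n_clusters=m.n_clusters_,
        degenerate_indirect=m.degenerate_indirect_,
    )


def mediation_effects(fit: MediationFit) -> dict:
    """Direct/indirect/total effects with delta-method SEs and p-values."""

    def p_of(est, se):
        if se == 0 or not np.isfinite(se):
            return float("nan")
        return float(2.0 * stats.norm.sf(abs(est) / se))

    return {
        "direct": fit.direct,
        "direct_se": fit.se["c_prime"],
        "direct_p": fit.pvalues["c_prime"],
        "indirect": fit.indirect,
        "indirect_se": fit.indirect_se,
        "indirect_p": p_of(fit.indirect, fit.indirect_se),
        "total": fit.total,
        "total_se": fit.total_se,
        "total_p": p_of(fit.total, fit.total_se),
        "proportion_mediated": fit.proportion_mediated,
        "proportion_se": fit.proportion_se,
        "degenerate_indirect": fit.degenerate_indirect,
    }


def screen_mediators(
    screen_results: pd.DataFrame,
    residualizer,
    exposure: str = "bmi",
    alpha: float = 0.05,
    se_type: str = "cr0",
) -> pd.DataFrame:
    """Select mediator candidates from the CLPM screen and fit mediations.

    Candidates are CpGs whose methylation -> lipid path (rho2) passed
    ``p_adj < alpha`` in the 'all' stratum.  For each candidate the
    BMI <-> CpG and BMI <-> lipid CLPMs are fitted first; the mediation
    model is fitted only when both BMI -> trait paths are significant
    (raw p < alpha).
    """
    if screen_results.empty:
        return pd.DataFrame()
    allrows = screen_results[screen_results.get("stratum", "all") == "all"]
    cand = allrows[allrows["p_adj_rho2"] < alpha]
    out = []
    for _, row in cand.iterrows():
        cpg, lipid = row["cpg"], row["lipid"]
        bmi_cpg = CrossLaggedPanelModel(se_type=se_type).fit(residualizer.bmi_panel(cpg))
        bmi_lip = CrossLaggedPanelModel(se_type=se_type).fit(residualizer.bmi_panel(lipid))
        rec = {
            "cpg": cpg,
            "lipid": lipid,
            "bmi_to_cpg": bmi_cpg.params_["rho1"],
            "bmi_to_cpg_p": bmi_cpg.pvalues_["rho1"],
            "bmi_to_lipid": bmi_lip.params_["rho1"],
            "bmi_to_lipid_p": bmi_lip.pvalues_["rho1"],
        }
        eligible = rec["bmi_to_cpg_p"] < alpha and rec["bmi_to_lipid_p"] < alpha
        rec["mediation_attempted"] = bool(eligible)
        if eligible:
            panel = residualizer.mediation_panel(cpg, lipid)
            fit = fit_mediation_clpm(
                panel["X_b"], panel["X_f"], panel["M_b"], panel["M_f"],
                panel["Y_b"], panel["Y_f"],
                cluster=panel["pair_id"].to_numpy(), se_type=se_type,
            )
            rec.update(mediation_effects(fit))
            rec["srmr"], rec["cfi"] = fit.srmr, fit.cfi
            rec["n"] = fit.n
        out.append(rec)
    return pd.DataFrame(out)
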