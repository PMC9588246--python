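"""Random-intercept linear mixed models for twin-pair data.

The EWAS refits the same covariate design against tens of thousands of
methylation outcomes, so the fitter is built for that shape: the model
``y = X beta + Z u + e`` with one random intercept per twin pair is profiled
down to a one-dimensional REML search over the variance ratio
``gamma = var(u) / var(e)``.  An orthonormal (Helmert) rotation within each
cluster diagonalizes the marginal covariance — within-cluster contrasts keep
unit variance while each cluster-mean component has variance
``sigma2 * (1 + s * gamma)`` for cluster size ``s`` — so every REML
evaluation reduces to a weighted least-squares solve on cached per-size
cross-products.  Cross-products involving ``X`` alone are shared across all
outcomes fitted against the same design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_MAX_RATIO = 200.0
_BOUNDARY_EPS = 1e-5


def _helmert(s: int) -> np.ndarray:
    """Orthonormal s x s matrix whose first row is the scaled mean."""
    h = np.zeros((s, s))
    h[0] = 1.0 / np.sqrt(s)
    for r in range(1, s):
        h[r, :r] = 1.0
        h[r, r] = -r
        h[r] /= np.sqrt(r * (r + 1))
    return h


class RotatedDesign:
    """Cluster-rotated design with cached cross-products.

    After rotation, rows fall into weight classes: within-cluster contrasts
    (marginal variance ``sigma2``) and, per distinct cluster size ``s``, the
    cluster-mean rows (variance ``sigma2 * (1 + s * gamma)``).
    """

    def __init__(self, X: np.ndarray, clusters: np.ndarray):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise ValueError("design matrix is rank deficient")
        codes, _ = pd.factorize(np.asarray(clusters))
        order = np.argsort(codes, kind="stable")
        self._rows_by_cluster = order
        sizes = np.bincount(codes)
        self.n_clusters = len(sizes)
        self.all_singletons = bool((sizes == 1).all())

        # rotate cluster by cluster; collect contrast rows and mean rows by size
        helmerts = {s: _helmert(s) for s in np.unique(sizes)}
        contrast_rows, mean_rows = [], {}
        start = 0
        for c, s in enumerate(sizes):
            idx = order[start : start + s]
            start += s
            hx = helmerts[s] @ X[idx]
            mean_rows.setdefault(s, []).append(hx[0])
            if s > 1:
                contrast_rows.append(hx[1:])
        self._xc = (
            np.vstack(contrast_rows) if contrast_rows else np.empty((0, self.p))
        )
        self._xm = {s: np.asarray(rows) for s, rows in mean_rows.items()}
        self._n_mean = {s: len(rows) for s, rows in self._xm.items()}
        self.g_contrast = self._xc.T @ self._xc
        self.g_mean = {s: xm.T @ xm for s, xm in self._xm.items()}
        self._helmerts, self._sizes = helmerts, sizes

    def rotate_y(self, Y: np.ndarray):
        """Split outcomes into contrast components and per-size mean components.

        ``Y`` may be 1-D (one outcome) or 2-D ``(n, m)``.
        """
        Y = np.asarray(Y, dtype=float)
        squeeze = Y.ndim == 1
        Y = Y.reshape(self.n, -1)
        yc, ym = [], {s: [] for s in self._xm}
        start = 0
        order = self._rows_by_cluster
        for s in self._sizes:
            idx = order[start : start + s]
            start += s
            hy = self._helmerts[s] @ Y[idx]
            ym[s].append(hy[0])
            if s > 1:
                yc.append(hy[1:])
        yc = np.vstack(yc) if yc else np.empty((0, Y.shape[1]))
        ym = {s: np.asarray(v) for s, v in ym.items()}
        return yc, ym, squeeze

    def reml_components(self, yc, ym):
        """Sufficient statistics for one outcome's REML profile."""
        h0 = self._xc.T @ yc
        q0 = float(yc @ yc)
        hs = {s: self._xm[s].T @ ym[s] for s in self._xm}
        qs = {s: float(ym[s] @ ym[s]) for s in self._xm}
        return h0, q0, hs, qs

    def profile(self, gamma, h0, q0, hs, qs):
        a = self.g_contrast.copy()
        b = h0.copy()
        q = q0
        for s in self._xm:
            w = 1.0 / (1.0 + s * gamma)
            a += w * self.g_mean[s]
            b = b + w * hs[s]
            q += w * qs[s]
        beta = np.linalg.solve(a, b)
        rss = max(q - float(b @ beta), 1e-300)
        return a, beta, rss

    def neg2_reml(self, gamma, h0, q0, hs, qs):
        a, _, rss = self.profile(gamma, h0, q0, hs, qs)
        dof = self.n - self.p
        sigma2 = rss / dof
        logdet_v = sum(
            self._n_mean[s] * np.log1p(s * gamma) for s in self._xm
        )
        _, logdet_a = np.linalg.slogdet(a)
        return dof * np.log(sigma2) + logdet_v + logdet_a


@dataclass
class LmmFit:
    """One random-intercept fit: coefficients with Wald (normal) inference."""

    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    sigma2_resid: float
    sigma2_pair: float
    ratio: float
    boundary: bool
    ols_fallback: bool
    cov_params: np.ndarray
    fitted: np.ndarray | None = None
    perfect_fit: bool = False

    def resid(self, y) -> np.ndarray:
        """Marginal residuals: observed minus fixed-effect fit."""
        return np.asarray(y, float) - self.fitted


class PairRandomInterceptLMM(BaseEstimator):
    """REML random-intercept-per-pair regression (sklearn-style).

    Parameters
    ----------
    max_ratio : upper bound of the profiled variance-ratio search.
    xatol : absolute tolerance of the 1-D bounded optimization.
    """

    def __init__(self, max_ratio: float = _MAX_RATIO, xatol: float = 1e-7):
        self.max_ratio = max_ratio
        self.xatol = xatol

    def fit(self, X, y, clusters):
        design = X if isinstance(X, RotatedDesign) else RotatedDesign(np.asarray(X), clusters)
        res = _fit_one(design, np.asarray(y, float), self.max_ratio, self.xatol)
        X_arr = None if isinstance(X, RotatedDesign) else np.asarray(X, float)
        if X_arr is not None:
            res.fitted = X_arr @ res.coef
        self.result_ = res
        self.coef_ = res.coef
        self.se_ = res.se
        self.pvalues_ = res.pvalues
        self.ratio_ = res.ratio
        self.sigma2_resid_ = res.sigma2_resid
        self.sigma2_pair_ = res.sigma2_pair
        return self


def _fit_one(design: RotatedDesign, y: np.ndarray, max_ratio: float, xatol: float) -> LmmFit:
    yc, ym, _ = design.rotate_y(y)
    yc = yc[:, 0]
    ym = {s: v[:, 0] for s, v in ym.items()}
    return _fit_components(design, yc, ym, max_ratio, xatol)


def _fit_components(design, yc, ym, max_ratio=_MAX_RATIO, xatol=1e-7) -> LmmFit:
    comp = design.reml_components(yc, ym)
    dof = design.n - design.p
    if design.all_singletons:
        logger.info("all pairs are singletons; reducing to ordinary least squares")
        gamma, boundary, ols = 0.0, False, True
    else:
        obj = lambda g: design.neg2_reml(g, *comp)
        res = minimize_scalar(
            obj, bounds=(0.0, max_ratio), method="bounded", options={"xatol": xatol}
        )
        gamma = float(res.x)
        boundary, ols = False, False
        if gamma < _BOUNDARY_EPS and obj(0.0) <= res.fun:
            gamma, boundary = 0.0, True
        elif gamma > max_ratio - _BOUNDARY_EPS:
            boundary = True
    a, beta, rss = design.profile(gamma, *comp)
    h0, q0, hs, qs = comp
    scale = max(q0 + sum(qs.values()), 1e-300)
    perfect = rss <= 1e-12 * scale
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(a)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.nan)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LmmFit(
        coef=beta,
        se=se,
        zvalues=z,
        pvalues=p,
        sigma2_resid=sigma2,
        sigma2_pair=gamma * sigma2,
        ratio=gamma,
        boundary=boundary,
        ols_fallback=ols,
        cov_params=cov,
        perfect_fit=perfect,
    )


def fit_lmm_single(y, design, pair_ids, term: int = 0):
    """Fit the pair-random-intercept model and report one coefficient.

    ``design`` is the covariate matrix including the term of interest in
    column ``term`` (the lipid term in the EWAS).  Returns
    ``(coef, se, p)`` for that column, Wald z-test.
    """
    model = PairRandomInterceptLMM().fit(np.asarray(design, float), y, pair_ids)
    r = model.result_
    if r.perfect_fit:
        raise ValueError(
            "rank deficiency: residual variance is zero "
            "(response lies in the span of the design)"
        )
    return float(r.coef[term]), float(r.se[term]), float(r.pvalues[term])


def fit_lmm_batch(X, Y, clusters, max_ratio: float = _MAX_RATIO, xatol: float = 1e-7):
    """Fit one model per column of ``Y`` against a shared design.

    Returns a list of :class:`LmmFit` (without fitted values, which are
    rarely needed in the screening loop).  Failures are returned as the
    raised exception in place of the fit.
    """
    design = RotatedDesign(np.asarray(X, float), clusters)
    Y = np.asarray(Y, float).reshape(design.n, -1)
    yc_all, ym_all, _ = design.rotate_y(Y)
    fits = []
    for j in range(Y.shape[1]):
        yc = yc_all[:, j]
        ym = {s: v[:, j] for s, v in ym_all.items()}
        try:
            fits.append(_fit_components(design, yc, ym, max_ratio, xatol))
        except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
            fits.append(err)
    return fits
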