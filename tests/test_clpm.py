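"""Cross-lagged panel model: oracle equivalence, fit indices, inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lipidmeth import (
    ClpmParams,
    CrossLaggedPanelModel,
    clpm_panel_screen,
    fit_clpm,
    fit_indices,
    simulate_clpm_panel,
)
from tests.conftest import random_panel


def ols_oracle(panel):
    """Per-equation least squares on centered data via normal equations."""
    d = panel[["lipid_b", "meth_b", "lipid_f", "meth_f"]].to_numpy(float)
    d = d - d.mean(axis=0)
    X, F = d[:, :2], d[:, 2:]
    return np.linalg.lstsq(X, F, rcond=None)[0].T  # rows (lipid_f, meth_f)


class TestEstimation:
    def test_noiseless_panel_exact_recovery(self):
        pars = ClpmParams(rho1=0.54, rho2=-0.032, resid_sd_lipid=1e-12, resid_sd_meth=1e-12)
        panel = simulate_clpm_panel(pars, 200, seed=1)
        m = CrossLaggedPanelModel().fit(panel)
        assert m.params_["rho1"] == pytest.approx(0.54, abs=1e-8)
        assert m.params_["rho2"] == pytest.approx(-0.032, abs=1e-8)
        assert m.params_["auto_lipid"] == pytest.approx(0.6, abs=1e-8)

    def test_equals_least_squares_oracle_on_random_panels(self, rng):
        for _ in range(100):
            panel = random_panel(rng, n=int(rng.integers(20, 80)))
            m = CrossLaggedPanelModel().fit(panel)
            b = ols_oracle(panel)
            est = np.array(
                [
                    [m.params_["auto_lipid"], m.params_["rho2"]],
                    [m.params_["rho1"], m.params_["auto_meth"]],
                ]
            )
            assert np.abs(est - b).max() < 1e-8

    def test_equals_numerical_fiml_oracle(self, rng):
        """Concentrated multivariate-normal ML over the path matrix equals OLS."""
        for seed in range(3):
            panel = random_panel(np.random.default_rng(seed), n=60)
            d = panel.to_numpy() - panel.to_numpy().mean(axis=0)
            X, F = d[:, :2], d[:, 2:]

            def nll(theta):
                resid = F - X @ theta.reshape(2, 2)
                _, logdet = np.linalg.slogdet(resid.T @ resid / len(d))
                return logdet

            start = np.zeros(4)
            res = minimize(nll, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
            m = CrossLaggedPanelModel().fit(panel)
            ml = res.x.reshape(2, 2).T
            est = np.array(
                [
                    [m.params_["auto_lipid"], m.params_["rho2"]],
                    [m.params_["rho1"], m.params_["auto_meth"]],
                ]
            )
            assert np.abs(est - ml).max() < 1e-5

    def test_large_sample_recovery_of_planted_paths(self):
        pars = ClpmParams(rho1=0.54, rho2=0.0)
        panel = simulate_clpm_panel(pars, 100_000, seed=9)
        m = CrossLaggedPanelModel().fit(panel)
        assert m.params_["rho1"] == pytest.approx(0.54, abs=0.02)
        assert m.params_["rho2"] == pytest.approx(0.0, abs=0.02)

    @pytest.mark.parametrize("rho1,rho2", [(-0.5, 0.0), (0.0, 0.0), (0.5, 0.0),
                                           (0.0, -0.5), (0.0, 0.5)])
    def test_mean_recovery_over_replicates(self, rho1, rho2):
        pars = ClpmParams(rho1=rho1, rho2=rho2)
        ests1, ests2 = [], []
        for rep in range(200):
            panel = simulate_clpm_panel(pars, 288, seed=hash((rho1, rho2, rep)) % 2**31)
            m = CrossLaggedPanelModel().fit(panel)
            ests1.append(m.params_["rho1"])
            ests2.append(m.params_["rho2"])
        for ests, truth in ((ests1, rho1), (ests2, rho2)):
            mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
            assert abs(np.mean(ests) - truth) <= 3 * mc_se

    def test_errors(self, rng):
        panel = random_panel(rng, n=5)
        with pytest.raises(ValueError, match="clusters"):
            CrossLaggedPanelModel().fit(panel)
        bad = random_panel(rng, n=50)
        bad["meth_b"] = bad["lipid_b"]
        with pytest.raises(ValueError, match="collinear"):
            CrossLaggedPanelModel().fit(bad)


class TestSaturatedFit:
    def test_always_perfect_indices(self, rng):
        for _ in range(100):
            panel = random_panel(rng, n=int(rng.integers(15, 100)))
            m = CrossLaggedPanelModel().fit(panel)
            assert m.cfi_ == 1.0
            assert m.srmr_ < 1e-8


class TestFitIndices:
    def test_identical_matrices_perfect_fit(self, rng):
        panel = random_panel(rng, n=50)
        s = np.cov(panel.to_numpy().T)
        srmr, cfi = fit_indices(s, s, 50, 0)
        assert srmr == pytest.approx(0.0, abs=1e-12)
        assert cfi == 1.0

    def test_baseline_model_gives_cfi_zero(self, rng):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        srmr, cfi = fit_indices(s, np.diag(np.diag(s)), 100, 1)
        assert cfi == 0.0

    def test_hand_computed_two_by_two(self):
        s = np.array([[1.0, 0.5], [0.5, 1.0]])
        m = np.eye(2)
        srmr, cfi = fit_indices(s, m, 100, 0)
        assert srmr == pytest.approx(np.sqrt(0.25 / 3), abs=1e-10)  # 0.2887
        assert cfi == 0.0
        # F_ML oracle: log det I - log det S + tr(S) - 2 = -log(0.75)
        from lipidmeth.clpm import fml_discrepancy

        assert fml_discrepancy(s, m) == pytest.approx(-np.log(0.75), abs=1e-12)

    def test_singular_model_cov_rejected(self):
        s = np.eye(2)
        with pytest.raises(np.linalg.LinAlgError):
            fit_indices(s, np.zeros((2, 2)), 10, 0)


class TestClusterRobustSEs:
    def test_robust_geq_classical_under_pair_correlation(self):
        # both regressors and disturbances share a strong pair component
        wins, total = 0, 0
        n_reps = 40
        for seed in range(n_reps):
            rng = np.random.default_rng(1000 + seed)
            g = 100
            base = (
                np.repeat(rng.standard_normal((g, 2)), 2, axis=0) * 0.85
                + rng.standard_normal((2 * g, 2)) * 0.5
            )
            dist = (
                np.repeat(rng.standard_normal((g, 2)), 2, axis=0) * 0.9
                + rng.standard_normal((2 * g, 2)) * 0.4
            )
            fw = base @ np.array([[0.5, 0.1], [0.1, 0.5]]) + dist
            df = pd.DataFrame(
                np.hstack([base, fw]),
                columns=["lipid_b", "meth_b", "lipid_f", "meth_f"],
            )
            df["pair_id"] = np.repeat(np.arange(g), 2)
            m = CrossLaggedPanelModel().fit(df)
            wins += (m.se_.to_numpy() >= m.se_classical_.to_numpy() - 1e-12).sum()
            total += 4
        assert wins >= 0.95 * total

    def test_singletons_form_own_clusters(self, rng):
        panel = random_panel(rng, n=40)
        m1 = CrossLaggedPanelModel().fit(panel)
        m2 = CrossLaggedPanelModel().fit(panel, clusters=np.arange(40))
        assert np.allclose(m1.se_.to_numpy(), m2.se_.to_numpy())

    def test_cr1_inflates_cr0(self, rng):
        panel = random_panel(rng, n=50)
        m0 = CrossLaggedPanelModel(se_type="cr0").fit(panel)
        m1 = CrossLaggedPanelModel(se_type="cr1").fit(panel)
        assert (m1.se_.to_numpy() > m0.se_.to_numpy()).all()


class _StubResidualizer:
    def __init__(self, panels):
        self.panels = panels

    def panel(self, cpg, lipid):
        return self.panels[(cpg, lipid)]


def _pairify(df, n_pairs, zyg=None):
    df = df.copy()
    df["pair_id"] = [f"p{j // 2}" for j in range(len(df))]
    df["zygosity"] = (
        np.repeat(zyg, 2)[: len(df)] if zyg is not None else "MZ"
    )
    return df


class TestPanelScreen:
    def test_null_panels_yield_no_hits(self):
        rng = np.random.default_rng(3)
        panels = {}
        assoc = []
        for j in range(23):
            pars = ClpmParams()
            df = simulate_clpm_panel(pars, 120, seed=rng)
            panels[(f"cg{j}", "TG")] = _pairify(df, 60)
            assoc.append({"cpg": f"cg{j}", "lipid": "TG"})
        screen = clpm_panel_screen(
            pd.DataFrame(assoc), _StubResidualizer(panels)
        )
        hits = ((screen["p_adj_rho1"] < 0.05) | (screen["p_adj_rho2"] < 0.05)).sum()
        assert hits <= 1

    def test_planted_rho2_flagged_with_direction(self):
        rng = np.random.default_rng(4)
        panels, assoc = {}, []
        for j in range(8):
            pars = ClpmParams(rho2=-0.6 if j == 0 else 0.0)
            df = simulate_clpm_panel(pars, 200, seed=rng)
            panels[(f"cg{j}", "HDL_C")] = _pairify(df, 100)
            assoc.append({"cpg": f"cg{j}", "lipid": "HDL_C"})
        screen = clpm_panel_screen(pd.DataFrame(assoc), _StubResidualizer(panels))
        sig = screen[screen["p_adj_rho2"] < 0.05]
        assert sig["cpg"].tolist() == ["cg0"]
        assert sig["rho2"].iloc[0] < 0

    def test_mz_only_signal_found_in_mz_stratum(self):
        rng = np.random.default_rng(5)
        mz = simulate_clpm_panel(ClpmParams(rho2=-0.7), 150, seed=rng)
        dz = simulate_clpm_panel(ClpmParams(), 150, seed=rng)
        panel = pd.concat(
            [
                _pairify(mz, 75, zyg=["MZ"] * 75),
                _pairify(dz, 75, zyg=["DZ"] * 75).assign(
                    pair_id=[f"q{j // 2}" for j in range(150)]
                ),
            ],
            ignore_index=True,
        )
        panels = {("cgX", "TG"): panel}
        assoc = pd.DataFrame([{"cpg": "cgX", "lipid": "TG"}])
        screen = clpm_panel_screen(
            assoc, _StubResidualizer(panels), strata=("mz", "dz")
        )
        by = screen.set_index("stratum")
        assert by.loc["mz", "p_adj_rho2"] < 0.05
        assert by.loc["dz", "p_adj_rho2"] > 0.05

    def test_small_stratum_skipped_with_warning(self):
        rng = np.random.default_rng(6)
        df = _pairify(simulate_clpm_panel(ClpmParams(), 12, seed=rng), 6)
        panels = {("cgY", "TG"): df}
        assoc = pd.DataFrame([{"cpg": "cgY", "lipid": "TG"}])
        with pytest.warns(UserWarning, match="skipped"):
            screen = clpm_panel_screen(assoc, _StubResidualizer(panels))
        assert len(screen) == 0


def test_fit_clpm_wrapper_mirrors_estimator(rng):
    panel = random_panel(rng, n=60)
    fit = fit_clpm(panel)
    m = CrossLaggedPanelModel().fit(panel)
    assert fit.rho1 == pytest.approx(m.params_["rho1"])
    assert fit.cfi == 1.0
    assert fit.srmr < 1e-8
    assert fit.n == 60
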