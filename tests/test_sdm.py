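import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phc_spaceff.sdm import SdmSpec, fit_sdm, hausman_screen, impacts, lr_tests, vif
from phc_spaceff.synthetic_data import SyntheticScenario, lattice_weights, simulate_sdm_panel


def within_ols(panel, cols, dep="y"):
    d = panel.copy()
    for c in [dep, *cols]:
        d[c] = d[c] - d.groupby("unit_id")[c].transform("mean")
    X = d[list(cols)].to_numpy()
    return np.linalg.lstsq(X, d[dep].to_numpy(), rcond=None)[0]


@pytest.fixture(scope="module")
def null_panel(lattice_w31):
    sc = SyntheticScenario(N=31, T=5, rho=0.0, theta=(0.0, 0.0), seed=4)
    panel, truth = simulate_sdm_panel(lattice_w31, sc)
    return panel, truth


class TestFitSdm:
    def test_null_rho_within_2se(self, null_panel, sdm_spec31):
        panel, _ = null_panel
        fit = fit_sdm(panel, sdm_spec31)
        rho_se = fit.params_se()[-1]
        assert abs(fit.rho) < 2 * rho_se

    def test_reduction_to_within_ols_when_imposed(self, null_panel, sdm_spec31):
        panel, _ = null_panel
        fit = fit_sdm(panel, sdm_spec31, model="slm", rho_fixed=0.0)
        b = within_ols(panel, ("x1", "x2"))
        np.testing.assert_allclose(fit.beta, b, atol=1e-6)

    def test_loglik_at_maximizer(self, lattice_w31, sdm_spec31):
        for s in (0, 1, 2):
            sc = SyntheticScenario(N=31, T=5, rho=0.3, seed=200 + s)
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            free = fit_sdm(panel, sdm_spec31)
            fixed = fit_sdm(panel, sdm_spec31, rho_fixed=0.0)
            assert free.loglik >= fixed.loglik - 1e-9

    def test_recovery_quick(self, lattice_w31, sdm_spec31):
        rhos, b1s = [], []
        for s in range(40):
            sc = SyntheticScenario(N=31, T=5, rho=0.4, seed=1000 + s)
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            fit = fit_sdm(panel, sdm_spec31)
            rhos.append(fit.rho)
            b1s.append(fit.beta[0])
        assert abs(np.mean(rhos) - 0.4) < 0.06
        assert abs(np.mean(b1s) - 1.0) < 0.05

    def test_rho_inside_interval(self, lattice_w31, sdm_spec31):
        for s in range(5):
            sc = SyntheticScenario(N=31, T=5, rho=0.7, seed=300 + s)
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            fit = fit_sdm(panel, sdm_spec31)
            lo, hi = fit.rho_bounds
            assert lo < fit.rho < hi

    def test_collinear_regressors_error(self, null_panel, lattice_w31):
        panel, _ = null_panel
        panel = panel.assign(x3=panel.x1)
        spec = SdmSpec("y", ("x1", "x2", "x3"), lattice_w31, "unit")
        with pytest.raises(np.linalg.LinAlgError):
            fit_sdm(panel, spec)

    def test_spec_validation(self, lattice_w31):
        with pytest.raises(ValueError, match="dependent"):
            SdmSpec("y", ("y", "x1"), lattice_w31)
        with pytest.raises(ValueError, match="fixed_effects"):
            SdmSpec("y", ("x1",), lattice_w31, "both")
        raw = lattice_weights(31, standardization="none")
        with pytest.raises(ValueError, match="row-standardized"):
            SdmSpec("y", ("x1",), raw)

    def test_fixed_effects_modes_run(self, null_panel, lattice_w31):
        panel, _ = null_panel
        for fe in ("unit", "time", "two_way", "none"):
            fit = fit_sdm(panel, SdmSpec("y", ("x1", "x2"), lattice_w31, fe))
            assert fit.sigma2 > 0
            assert np.isfinite(fit.loglik)

    def test_lee_yu_sigma2_scaling(self, lattice_w31, sdm_spec31):
        sc = SyntheticScenario(N=31, T=5, rho=0.4, seed=17)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        plain = fit_sdm(panel, sdm_spec31)
        corrected = fit_sdm(panel, sdm_spec31, lee_yu=True)
        # transformed likelihood divides the same residual sum by N(T-1)
        assert corrected.sigma2 > plain.sigma2

    def test_sem_runs_and_beta_sane(self, lattice_w31):
        sc = SyntheticScenario(N=31, T=5, rho=0.0, theta=(0.0, 0.0), seed=23)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        fit = fit_sdm(panel, SdmSpec("y", ("x1", "x2"), lattice_w31, "unit"), model="sem")
        assert fit.model == "sem"
        np.testing.assert_allclose(fit.beta, [1.0, -0.5], atol=0.2)


class TestImpacts:
    def test_rho_zero_theta_zero_identity(self, null_panel, sdm_spec31, lattice_w31):
        panel, _ = null_panel
        fit = fit_sdm(panel, sdm_spec31, model="slm", rho_fixed=0.0)
        eff = impacts(fit, lattice_w31, n_sims=50, seed=0)
        np.testing.assert_allclose(eff.direct, fit.beta, atol=1e-12)
        np.testing.assert_allclose(eff.indirect, 0.0, atol=1e-12)
        np.testing.assert_allclose(eff.total, fit.beta, atol=1e-12)

    def test_rho_zero_indirect_equals_theta(self, null_panel, sdm_spec31, lattice_w31):
        panel, _ = null_panel
        fit = fit_sdm(panel, sdm_spec31, rho_fixed=0.0)
        eff = impacts(fit, lattice_w31, n_sims=50, seed=0)
        # row-standardized W has unit row sums and zero diagonal:
        # indirect = theta exactly when rho = 0
        np.testing.assert_allclose(eff.indirect, fit.theta_lag, atol=1e-10)

    def test_dense_matrix_oracle_n5(self):
        ids = tuple("abcde")
        rng = np.random.default_rng(3)
        w = rng.uniform(0, 1, (5, 5))
        np.fill_diagonal(w, 0)
        from phc_spaceff.panel_io import SpatialWeights

        W = SpatialWeights(ids, w).row_standardized()
        rho, beta, theta = 0.3, np.array([1.2, -0.4]), np.array([0.5, 0.1])
        from phc_spaceff.sdm import _impact_point

        d, ind, tot = _impact_point(rho, beta, theta, W.matrix)
        A = np.linalg.inv(np.eye(5) - rho * W.matrix)
        for k in range(2):
            S = A @ (beta[k] * np.eye(5) + theta[k] * W.matrix)
            assert d[k] == pytest.approx(np.diag(S).mean(), abs=1e-12)
            assert tot[k] == pytest.approx(S.sum() / 5, abs=1e-12)
            assert ind[k] == pytest.approx(tot[k] - d[k], abs=1e-12)

    def test_additivity(self, lattice_w31, sdm_spec31):
        sc = SyntheticScenario(N=31, T=5, rho=0.4, seed=31)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        fit = fit_sdm(panel, sdm_spec31)
        eff = impacts(fit, lattice_w31, n_sims=200, seed=2)
        np.testing.assert_allclose(eff.total, eff.direct + eff.indirect, atol=1e-9)
        frame = eff.as_frame()
        assert set(frame.effect) == {"direct", "indirect", "total"}
        assert (frame.se > 0).all()


class TestLrTests:
    def test_nesting_loglik(self, lattice_w31, sdm_spec31):
        sc = SyntheticScenario(N=31, T=5, rho=0.4, seed=50)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        f_sdm = fit_sdm(panel, sdm_spec31)
        f_slm = fit_sdm(panel, sdm_spec31, model="slm")
        f_sem = fit_sdm(panel, sdm_spec31, model="sem")
        assert f_sdm.loglik >= f_slm.loglik - 1e-8
        table = lr_tests(f_sdm, f_slm, f_sem)
        assert (table.lr >= -1e-8).all()
        assert (table.df == 2).all()

    def test_power_against_large_theta(self, lattice_w31, sdm_spec31):
        rejections = 0
        for s in range(30):
            sc = SyntheticScenario(N=31, T=5, rho=0.4, theta=(0.8, 0.0), seed=600 + s)
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            f_sdm = fit_sdm(panel, sdm_spec31, lee_yu=True)
            f_slm = fit_sdm(panel, sdm_spec31, model="slm", lee_yu=True)
            lr = 2 * (f_sdm.loglik - f_slm.loglik)
            if stats.chi2.sf(max(lr, 0), 2) < 0.05:
                rejections += 1
        assert rejections > 0.8 * 30

    def test_wrong_order_rejected(self, lattice_w31, sdm_spec31):
        sc = SyntheticScenario(N=31, T=5, seed=60)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        f_sdm = fit_sdm(panel, sdm_spec31)
        with pytest.raises(ValueError, match="sdm, slm, sem"):
            lr_tests(f_sdm, f_sdm, f_sdm)


class TestHausman:
    def test_size_under_re_consistency(self, lattice_w31, sdm_spec31):
        rej = 0
        for s in range(100):
            sc = SyntheticScenario(
                N=31, T=5, rho=0.0, theta=(0.0, 0.0), sigma_mu=0.3, seed=40000 + s
            )
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            if hausman_screen(panel, sdm_spec31)["p"] < 0.05:
                rej += 1
        assert 0 <= rej <= 13  # nominal 5 of 100

    def test_power_when_effects_correlate_with_x(self, lattice_w31, sdm_spec31):
        rej = 0
        for s in range(50):
            sc = SyntheticScenario(
                N=31, T=5, rho=0.0, theta=(0.0, 0.0), fe_x_corr=0.9, sigma_mu=0.5,
                seed=50000 + s,
            )
            panel, _ = simulate_sdm_panel(lattice_w31, sc)
            if hausman_screen(panel, sdm_spec31)["p"] < 0.05:
                rej += 1
        assert rej > 45

    def test_output_contract(self, lattice_w31, sdm_spec31):
        sc = SyntheticScenario(N=31, T=5, seed=3)
        panel, _ = simulate_sdm_panel(lattice_w31, sc)
        res = hausman_screen(panel, sdm_spec31)
        assert res["statistic"] >= 0
        assert res["df"] == 2
        assert 0 <= res["p"] <= 1
        assert isinstance(res["pinv_fallback"], bool)


class TestVif:
    def test_orthogonal_columns_unity(self):
        X = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1], "c": [1.0, -1, -1, 1]})
        np.testing.assert_allclose(vif(X).to_numpy(), 1.0, atol=1e-12)

    def test_near_collinear_large(self, rng):
        x1 = rng.normal(size=200)
        X = pd.DataFrame({"x1": x1, "x2": x1 + rng.normal(0, 1e-3, 200), "x3": rng.normal(size=200)})
        v = vif(X)
        assert v["x1"] > 10
        assert v["x2"] > 10

    def test_matches_independent_regression(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=["a", "b", "c"])
        X["b"] += 0.5 * X["a"]
        v = vif(X)
        for k in X.columns:
            others = X.drop(columns=k).to_numpy()
            others = np.column_stack([np.ones(len(X)), others])
            yk = X[k].to_numpy()
            bh, *_ = np.linalg.lstsq(others, yk, rcond=None)
            r2 = 1 - ((yk - others @ bh) ** 2).sum() / ((yk - yk.mean()) ** 2).sum()
            assert v[k] == pytest.approx(1 / (1 - r2), rel=1e-9)

    def test_perfect_collinearity_inf(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        assert np.isinf(vif(X)).all()

    def test_needs_two_columns(self):
        with pytest.raises(ValueError):
            vif(pd.DataFrame({"a": [1.0, 2]}))
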