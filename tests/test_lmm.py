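"""Tests of the REML/BLUP fitter against closed forms and independent oracles."""

import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import dynmix as dm
from dynmix.lmm import default_wishart_df, fit_core


def toy_frame(rng, n_clinics=5, n_per=6, tau0=0.8, tau1=0.0, sigma=0.6):
    """A tiny clustered dataset with known generating values."""
    rows = []
    for cid in range(n_clinics):
        b0 = rng.normal(0, tau0)
        b1 = rng.normal(0, tau1) if tau1 else 0.0
        x1 = rng.normal(size=n_per)
        y = 0.3 + b0 + (1.0 + b1) * x1 + rng.normal(0, sigma, size=n_per)
        for j in range(n_per):
            rows.append({"clinic_id": cid, "patient_id": j + 1, "x1": x1[j], "y": y[j]})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# independent dense oracle: same penalized restricted likelihood, computed
# from full n x n covariance matrices (no per-group statistics, no Woodbury)
# ----------------------------------------------------------------------

def _dense_fit(data, spec):
    from dynmix.lmm import _lambda_from_theta, design_matrices

    X, Z, _ = design_matrices(data, spec)
    y = data["y"].to_numpy(dtype=float)
    groups = data["clinic_id"].to_numpy()
    labels, codes = np.unique(groups, return_inverse=True)
    n, p = X.shape
    q = Z.shape[1]
    m = labels.size
    # expanded random-effects design: one block of q columns per cluster
    Zg = np.zeros((n, q * m))
    for i in range(n):
        Zg[i, codes[i] * q:(codes[i] + 1) * q] = Z[i]
    coef = default_wishart_df(q) - q - 1.0

    def neg2(theta):
        L = _lambda_from_theta(theta, q)
        Psi = L @ L.T
        V0 = np.eye(n) + Zg @ np.kron(np.eye(m), Psi) @ Zg.T
        Vinv = np.linalg.inv(V0)
        Sxx = X.T @ Vinv @ X
        beta = np.linalg.solve(Sxx, X.T @ Vinv @ y)
        r = y - X @ beta
        rss = float(r @ Vinv @ r)
        sigma2 = rss / (n - p)
        val = (
            np.linalg.slogdet(V0)[1]
            + np.linalg.slogdet(Sxx)[1]
            + (n - p) * (math.log(2 * math.pi) + math.log(sigma2))
            + rss / sigma2
        )
        val -= coef * (q * math.log(sigma2) + 2 * float(np.log(np.diag(L)).sum()))
        return val

    n_par = 1 if q == 1 else 3
    best = None
    for start in ([0.0] * n_par, [math.log(3)] + [0.0] * (n_par - 1)):
        res = minimize(neg2, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        if best is None or res.fun < best.fun:
            best = res
    L = _lambda_from_theta(best.x, q)
    Psi = L @ L.T
    V0 = np.eye(n) + Zg @ np.kron(np.eye(m), Psi) @ Zg.T
    Vinv = np.linalg.inv(V0)
    Sxx = X.T @ Vinv @ X
    beta = np.linalg.solve(Sxx, X.T @ Vinv @ y)
    r = y - X @ beta
    sigma2 = float(r @ Vinv @ r) / (n - p)
    return beta, sigma2 * Psi, sigma2


class TestOracleEquivalence:
    @pytest.mark.parametrize("spec_fn", [dm.random_intercept, dm.random_intercept_slope])
    def test_reml_matches_dense_oracle(self, spec_fn):
        """Sufficient-statistics REML equals brute-force dense maximization
        of the same penalized restricted likelihood on tiny instances."""
        rng = np.random.default_rng(31)
        data = toy_frame(rng, n_clinics=5, n_per=6, tau1=0.4)
        spec = spec_fn()
        fit = dm.ClusteredLMM(data, spec).fit()
        beta_o, G_o, s2_o = _dense_fit(data, spec)
        np.testing.assert_allclose(fit.fe_params, beta_o, atol=1e-3)
        np.testing.assert_allclose(fit.cov_re, G_o, atol=1e-3)
        assert fit.scale == pytest.approx(s2_o, abs=1e-3)

    @pytest.mark.parametrize("spec_fn", [dm.random_intercept, dm.random_intercept_slope])
    def test_unpenalized_reml_matches_statsmodels(self, spec_fn, base_population, base_training):
        """With the covariance penalty disabled, estimates agree with
        statsmodels MixedLM REML (an entirely independent implementation)."""
        import statsmodels.formula.api as smf

        _, train = base_training
        spec = spec_fn()
        q = len(spec.random)
        fit = dm.ClusteredLMM(train, spec).fit(wishart_df=q + 1)
        re_formula = "1" if q == 1 else "1 + x1"
        sm_fit = smf.mixedlm(
            "y ~ x1", train, groups=train["clinic_id"], re_formula=re_formula
        ).fit(reml=True)
        np.testing.assert_allclose(fit.fe_params, sm_fit.fe_params.values, atol=1e-3)
        np.testing.assert_allclose(fit.scale, sm_fit.scale, atol=1e-3)
        np.testing.assert_allclose(fit.cov_re, sm_fit.cov_re.values, atol=2e-3)

    def test_penalty_influence_vanishes_with_data(self):
        """The weak Wishart penalty must not move estimates on large samples."""
        rng = np.random.default_rng(5)
        data = toy_frame(rng, n_clinics=150, n_per=40, tau1=0.4)
        spec = dm.random_intercept_slope()
        pen = dm.ClusteredLMM(data, spec).fit()
        plain = dm.ClusteredLMM(data, spec).fit(wishart_df=3.0)
        assert np.abs(pen.cov_re - plain.cov_re).max() < 0.02
        assert np.abs(pen.fe_params - plain.fe_params).max() < 1e-3


class TestDegenerateAndFixedFits:
    def test_intercept_only_constant_outcome(self):
        data = pd.DataFrame({"clinic_id": [0, 0, 1, 1], "x1": [0.1, -0.2, 0.3, 0.4],
                             "y": [2.5] * 4})
        fit = dm.ClusteredLMM(data, dm.intercept_only()).fit()
        assert fit.fe_params[0] == pytest.approx(2.5)
        assert fit.scale == pytest.approx(0.0, abs=1e-12)

    def test_ols_path_matches_lstsq(self):
        rng = np.random.default_rng(0)
        data = toy_frame(rng)
        fit = dm.ClusteredLMM(data, dm.linear()).fit()
        X = np.column_stack([np.ones(len(data)), data["x1"]])
        beta, *_ = np.linalg.lstsq(X, data["y"].to_numpy(), rcond=None)
        np.testing.assert_allclose(fit.fe_params, beta, atol=1e-10)

    def test_blup_shrinkage_closed_form(self):
        """With known variance components, the random-intercept BLUP is
        n_i tau^2 / (n_i tau^2 + sigma^2) times the mean within-clinic
        residual (the classical shrinkage estimator)."""
        rng = np.random.default_rng(2)
        data = toy_frame(rng, n_clinics=3, n_per=8)
        tau_sq, sigma_sq = 0.7, 0.4
        fit = dm.ClusteredLMM(data, dm.random_intercept()).fit(
            cov_re=np.array([[tau_sq]]), scale=sigma_sq
        )
        X = np.column_stack([np.ones(len(data)), data["x1"]])
        resid = data["y"].to_numpy() - X @ fit.fe_params
        for cid, grp in data.groupby("clinic_id"):
            n_i = len(grp)
            expected = n_i * tau_sq / (n_i * tau_sq + sigma_sq) * resid[grp.index].mean()
            assert fit.random_effects[cid][0] == pytest.approx(expected, abs=1e-10)

    def test_shrinkage_ordering(self):
        """|BLUP| decreases as sigma^2/n_i grows, at a fixed mean residual."""
        shr = lambda n, tau_sq, sigma_sq: n * tau_sq / (n * tau_sq + sigma_sq)
        vals = [shr(n, 0.7, 0.4) for n in (2, 5, 20, 100)]
        assert vals == sorted(vals)
        # same monotonicity out of the fitter itself: a large anchor clinic
        # on y = x1 pins the fixed effects near (0, 1), so the four test
        # clinics (y = 1 + x1) share the same mean residual ~ +1
        rng = np.random.default_rng(9)
        x_anchor = rng.normal(size=2000)
        frames = [pd.DataFrame({"clinic_id": 99, "patient_id": np.arange(2000),
                                "x1": x_anchor, "y": x_anchor})]
        for cid, n_i in enumerate((2, 5, 20, 100)):
            x1 = rng.normal(size=n_i)
            frames.append(pd.DataFrame({
                "clinic_id": cid, "patient_id": np.arange(n_i),
                "x1": x1, "y": 1.0 + x1,
            }))
        data = pd.concat(frames, ignore_index=True)
        fit = dm.ClusteredLMM(data, dm.random_intercept()).fit(
            cov_re=np.array([[0.7]]), scale=0.4
        )
        blups = [fit.random_effects[cid][0] for cid in range(4)]
        assert all(b2 > b1 > 0 for b1, b2 in zip(blups, blups[1:]))

    def test_nesting_zero_variance_equals_ols(self):
        """Forcing the random-effect variances to zero reproduces the
        fixed-effects-only predictions exactly."""
        rng = np.random.default_rng(3)
        data = toy_frame(rng)
        ols = dm.ClusteredLMM(data, dm.linear()).fit()
        forced = dm.ClusteredLMM(data, dm.random_intercept_slope()).fit(
            cov_re=np.zeros((2, 2)), scale=ols.scale
        )
        np.testing.assert_allclose(forced.predict(data), ols.predict(data), atol=1e-10)
        np.testing.assert_allclose(forced.fe_params, ols.fe_params, atol=1e-10)

    def test_determinism(self, base_training):
        _, train = base_training
        a = dm.ClusteredLMM(train, dm.random_intercept_slope()).fit()
        b = dm.ClusteredLMM(train, dm.random_intercept_slope()).fit()
        assert np.array_equal(a.fe_params, b.fe_params)
        assert np.array_equal(a.cov_re, b.cov_re)
        assert a.scale == b.scale


class TestPrediction:
    def test_novel_clinic_uses_fixed_part_only(self):
        data = pd.DataFrame({
            "clinic_id": [0, 0, 1, 1], "x1": [0.0, 1.0, 2.0, 3.0],
            "y": [0.0, 1.0, 2.0, 3.0],  # exactly y = x1
        })
        fit = dm.ClusteredLMM(data, dm.linear()).fit()
        new = pd.DataFrame({"clinic_id": [999], "x1": [2.0]})
        assert fit.predict(new)[0] == pytest.approx(2.0, abs=1e-10)

    def test_known_clinic_adds_blup(self):
        rng = np.random.default_rng(4)
        data = toy_frame(rng)
        fit = dm.ClusteredLMM(data, dm.random_intercept()).fit()
        at_zero = fit.predict(pd.DataFrame({"clinic_id": [2], "x1": [0.0]}))[0]
        assert at_zero == pytest.approx(
            fit.fe_params[0] + fit.random_effects[2][0], abs=1e-12
        )

    def test_shrinkage_vanishes_for_large_clinic(self):
        """As n_i grows, cluster-specific predictions approach the private
        within-clinic least-squares line."""
        rng = np.random.default_rng(6)
        big_n = 10_000
        x_big = rng.normal(size=big_n)
        y_big = 0.5 + 1.3 * x_big + rng.normal(0, 0.6, size=big_n)
        frames = [pd.DataFrame({"clinic_id": 0, "patient_id": np.arange(big_n),
                                "x1": x_big, "y": y_big})]
        for cid in range(1, 6):
            x = rng.normal(size=15)
            y = rng.normal(0, 0.8) + (1 + rng.normal(0, 0.5)) * x + rng.normal(0, 0.6, 15)
            frames.append(pd.DataFrame({"clinic_id": cid, "patient_id": np.arange(15),
                                        "x1": x, "y": y}))
        data = pd.concat(frames, ignore_index=True)
        fit = dm.ClusteredLMM(data, dm.random_intercept_slope()).fit()
        grid = pd.DataFrame({"clinic_id": 0, "x1": np.linspace(-2, 2, 9)})
        pred = fit.predict(grid)
        Xb = np.column_stack([np.ones(big_n), x_big])
        beta_within, *_ = np.linalg.lstsq(Xb, y_big, rcond=None)
        within = beta_within[0] + beta_within[1] * grid["x1"].to_numpy()
        np.testing.assert_allclose(pred, within, atol=0.02)

    def test_unseen_quintile_level_uses_reference(self):
        rng = np.random.default_rng(8)
        data = toy_frame(rng, n_clinics=8, n_per=10)
        data["quintile"] = 1 + data["clinic_id"] % 4  # level 5 never observed
        fit = dm.ClusteredLMM(data, dm.linear(quintile=True)).fit()
        names = fit.model.fe_names
        assert fit.fe_params[names.index("quintile_5")] == 0.0
        ref = pd.DataFrame({"clinic_id": [99], "x1": [0.7], "quintile": [1]})
        unseen = pd.DataFrame({"clinic_id": [99], "x1": [0.7], "quintile": [5]})
        assert fit.predict(unseen)[0] == pytest.approx(fit.predict(ref)[0])

    def test_parameter_recovery_within_3se(self, base_training):
        _, train = base_training
        fit = dm.ClusteredLMM(train, dm.random_intercept_slope()).fit()
        i = fit.model.fe_names.index("x1")
        assert abs(fit.fe_params[i] - 1.0) < 3 * fit.bse[i]
        assert fit.converged


class TestTrueModel:
    def test_returns_stored_conditional_mean(self, small_population):
        sample = small_population.patients.sample(50, random_state=0)
        np.testing.assert_array_equal(
            dm.true_model_predict(small_population, sample), sample["mu_true"]
        )

    def test_unknown_patient_rejected(self, small_population):
        ghost = pd.DataFrame({"clinic_id": [0], "patient_id": [10**9]})
        with pytest.raises(KeyError):
            dm.true_model_predict(small_population, ghost)

    def test_true_model_mae_is_folded_normal_mean(self, base_population):
        # MAE of the true model = E|eps| = sigma_eps * sqrt(2/pi) = 0.5984
        pat = base_population.patients
        assert np.abs(pat["eps"]).mean() == pytest.approx(0.5984, abs=0.01)


class TestResultsSurface:
    def test_summary_and_json(self, small_population, small_training_ids):
        train = small_population.patients_of(small_training_ids)
        fit = dm.ClusteredLMM(train, dm.random_intercept()).fit()
        text = fit.summary()
        assert "random_intercept" in text and "sigma^2" in text
        payload = json.loads(fit.to_json())
        assert payload["n_clusters"] == 20
        assert len(payload["random_effects"]) == 20
        np.testing.assert_allclose(payload["fe_params"], fit.fe_params)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            dm.ModelSpec("bad", fixed=("x9",))
        with pytest.raises(ValueError):
            dm.ModelSpec("bad", random=("x1",))  # slope without intercept

    def test_mixed_spec_needs_two_clusters(self):
        data = pd.DataFrame({"clinic_id": [0] * 5, "x1": np.arange(5.0), "y": np.arange(5.0)})
        with pytest.raises(ValueError, match="2 clusters"):
            dm.ClusteredLMM(data, dm.random_intercept()).fit()
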