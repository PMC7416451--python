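import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from gravimet.association import (
    CovariateModel,
    bh_fdr,
    bootstrap_se,
    build_design,
    fit_mixture,
    fit_ols,
)


def _subjects(n, rng):
    return pd.DataFrame(
        {
            "map": rng.normal(85, 8, n),
            "age": rng.normal(29, 5, n),
            "gest_age": rng.normal(27.7, 1.6, n),
            "field_centre": rng.choice(["c1", "c2"], n),
            "newborn_sex": rng.choice(["F", "M"], n),
            "storage_weeks": rng.uniform(1, 6, n),
            "bmi": rng.normal(27, 5, n),
            "parity": rng.poisson(1, n),
        },
        index=[f"S{i}" for i in range(n)],
    )


class TestCovariateModels:
    def test_nested_model_definitions(self):
        m1 = CovariateModel(1)
        assert set(m1.covariates) == {"map", "age", "gest_age", "field_centre", "newborn_sex", "storage_weeks"}
        assert set(CovariateModel(2).covariates) == set(m1.covariates) | {"bmi"}
        assert set(CovariateModel(3).covariates) == set(m1.covariates) | {"parity"}
        assert set(CovariateModel(4).covariates) == set(m1.covariates) | {"bmi", "parity"}

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            CovariateModel(5)

    def test_design_expands_categoricals_with_reference(self):
        rng = np.random.default_rng(0)
        d = build_design(_subjects(50, rng), CovariateModel(1).covariates)
        assert "intercept" in d.columns
        assert any(c.startswith("field_centre_") for c in d.columns)
        assert any(c.startswith("newborn_sex_") for c in d.columns)
        # one reference level absorbed per categorical
        assert sum(c.startswith("field_centre_") for c in d.columns) == 1


class TestOLS:
    def test_exact_linear_signal(self):
        rng = np.random.default_rng(1)
        sub = _subjects(100, rng)
        x = pd.Series(rng.normal(0, 1, 100), index=sub.index, name="met")
        y = 2.0 * x + 1e-8 * rng.normal(size=100)
        res = fit_ols(y, x, sub, CovariateModel(1))
        assert res.beta == pytest.approx(2.0, abs=1e-6)
        assert res.p < 1e-50
        assert res.method == "ols" and res.n_missing == 0

    def test_permutation_null_rarely_significant(self):
        rng = np.random.default_rng(2)
        sub = _subjects(500, rng)
        y = pd.Series(rng.normal(0, 1, 500), index=sub.index)
        hits = 0
        for _ in range(50):
            x = pd.Series(rng.permutation(y.to_numpy()), index=sub.index, name="met")
            res = fit_ols(y, x, sub, CovariateModel(1))
            hits += abs(res.beta / res.se) >= 3
        assert hits <= 2  # |z|>=3 in at most ~1% of permutations, allow slack

    def test_model4_recovery_of_planted_effect(self):
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(100):
            sub = _subjects(200, rng)
            x = pd.Series(rng.normal(0, 1, 200), index=sub.index, name="met")
            y = -0.3 * x + 0.01 * sub["bmi"] + rng.normal(0, 0.5, 200)
            res = fit_ols(y, x, sub, CovariateModel(4))
            errs.append(res.beta + 0.3)
        mean_err = np.mean(errs)
        mc_se = np.std(errs, ddof=1) / np.sqrt(len(errs))
        assert abs(mean_err) < 3 * mc_se

    def test_rank_deficiency_names_collinear_column(self):
        rng = np.random.default_rng(4)
        sub = _subjects(50, rng)
        sub["bmi"] = sub["map"]  # exact collinearity
        x = pd.Series(rng.normal(size=50), index=sub.index, name="met")
        y = pd.Series(rng.normal(size=50), index=sub.index)
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(y, x, sub, CovariateModel(2))

    def test_too_few_complete_cases(self):
        rng = np.random.default_rng(5)
        sub = _subjects(10, rng)
        x = pd.Series([np.nan] * 8 + [1.0, 2.0], index=sub.index, name="met")
        y = pd.Series(rng.normal(size=10), index=sub.index)
        with pytest.raises(ValueError, match="complete cases"):
            fit_ols(y, x, sub, CovariateModel(1))


class TestMixture:
    def _mixture_data(self, n, beta, censor_frac, rng):
        """Draw from the two-part model itself: presence is a logistic draw
        independent of the abundance given the design (self-consistency)."""
        from scipy.special import expit, logit

        sub = _subjects(n, rng)
        pheno = pd.Series(rng.normal(0, 1, n), index=sub.index, name="index")
        latent = 5.0 + beta * pheno + 0.02 * sub["age"] + rng.normal(0, 1.0, n)
        y = latent.copy()
        if censor_frac > 0:
            pi = expit(logit(1.0 - censor_frac) + 0.5 * pheno.to_numpy())
            y[rng.random(n) >= pi] = np.nan
        return pd.Series(y, index=sub.index, name="nt_met"), sub, pheno

    def test_zero_censoring_degenerates_to_ols(self):
        rng = np.random.default_rng(6)
        y, sub, pheno = self._mixture_data(300, -0.4, 0.0, rng)
        model = CovariateModel(1)
        fit, res = fit_mixture(y, sub, pheno, model)
        # same regression with metabolite as outcome, phenotype as predictor
        design = build_design(sub, model.covariates)
        X = pd.concat([pheno.rename("_pheno"), design], axis=1)
        coef, *_ = np.linalg.lstsq(X.to_numpy(float), y.to_numpy(float), rcond=None)
        ols_beta = coef[list(X.columns).index("_pheno")]
        assert res.beta == pytest.approx(ols_beta, rel=1e-6)
        assert fit.gamma_disc is None and res.n_missing == 0

    def test_all_censored_is_error(self):
        rng = np.random.default_rng(7)
        y, sub, pheno = self._mixture_data(50, 0.0, 0.0, rng)
        y[:] = np.nan
        with pytest.raises(ValueError):
            fit_mixture(y, sub, pheno, CovariateModel(1))

    def test_presence_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(8)
        y, sub, pheno = self._mixture_data(400, -0.4, 0.3, rng)
        fit, res = fit_mixture(y, sub, pheno, CovariateModel(1))
        assert fit.converged
        assert np.all(fit.pi > 0) and np.all(fit.pi < 1)
        assert fit.sigma > 0
        assert res.method == "mixture"
        assert res.n_obs + res.n_missing == 400

    def test_recovers_planted_beta_under_censoring(self):
        rng = np.random.default_rng(9)
        est = []
        for _ in range(60):
            y, sub, pheno = self._mixture_data(300, -0.4, 0.3, rng)
            _, res = fit_mixture(y, sub, pheno, CovariateModel(1))
            est.append(res.beta)
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) + 0.4) < 3 * mc_se


class TestBootstrap:
    def test_ols_bootstrap_matches_analytic_se(self):
        rng = np.random.default_rng(10)
        n = 400
        x = rng.normal(0, 1, n)
        y = 0.5 * x + rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), x])

        def fitter(idx):
            coef, *_ = np.linalg.lstsq(X[idx], y[idx], rcond=None)
            return coef[1]

        se, n_failed = bootstrap_se(fitter, n, B=500, seed=0)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = resid @ resid / (n - 2)
        analytic = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert n_failed == 0
        assert abs(se[0] - analytic) / analytic < 0.15

    def test_b_floor(self):
        with pytest.raises(ValueError):
            bootstrap_se(lambda idx: 0.0, 10, B=0)

    def test_single_subject_pool_gives_zero_se(self):
        se, _ = bootstrap_se(lambda idx: 1.23, 1, B=50, seed=0)
        assert se[0] == 0.0

    def test_seed_reproducible(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=100)
        fitter = lambda idx: y[idx].mean()
        a, _ = bootstrap_se(fitter, 100, B=100, seed=5)
        b, _ = bootstrap_se(fitter, 100, B=100, seed=5)
        assert a[0] == b[0]

    def test_unstable_fit_raises(self):
        calls = {"n": 0}

        def flaky(idx):
            calls["n"] += 1
            if calls["n"] % 2:
                raise RuntimeError("boom")
            return 1.0

        with pytest.raises(RuntimeError, match="unstable"):
            bootstrap_se(flaky, 10, B=100, seed=0)


class TestBHFDR:
    def test_hand_computed_fixture(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity_and_all_ones(self):
        assert bh_fdr([0.05])[0] == pytest.approx(0.05)
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_order_invariance_and_monotonicity(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.001, 1.0, 30)
        q = bh_fdr(p)
        perm = rng.permutation(30)
        assert np.allclose(bh_fdr(p[perm]), q[perm])
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.0001, 1.0, 50)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), ref)

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.5], [np.nan, 0.5], []])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


def test_type_one_error_near_nominal():
    """Null OLS metabolite test holds its 5% size (vectorised replicates)."""
    rng = np.random.default_rng(14)
    n, reps = 120, 1000
    from scipy import stats as sps

    hits = 0
    for _ in range(reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p = 2 * sps.t.sf(abs(coef[1] / se), n - 2)
        hits += p < 0.05
    rate = hits / reps
    ci_half = 1.96 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < ci_half + 1e-9
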