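"""Per-metabolite association with the insulin-sensitivity index.

Fully observed (targeted/clinical) metabolites use ordinary least
squares with the index as outcome and the metabolite as exposure.
Left-censored non-targeted metabolites use a two-part mixture
likelihood in the metabomxtr style: a logistic model for the
presence/absence of the metabolite in each sample and, when present, a
normal model for its (log2) abundance, both on a shared design that
carries the phenotype term plus covariates.  The joint log-likelihood

    sum_obs [ln pi_i + ln N(y_i; x_i' beta, sigma^2)] + sum_cens ln(1 - pi_i),
    logit(pi_i) = x_i' gamma,

is maximised numerically.  It is separable in (beta, sigma) and gamma,
so the optimum coincides with logistic regression on the presence
indicator plus OLS on the observed cells; at zero censoring the
logistic part saturates and the continuous part reduces exactly to OLS.
Standard errors of mixture betas come from subject-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "CovariateModel",
    "AssociationResult",
    "MixtureFit",
    "build_design",
    "fit_ols",
    "fit_mixture",
    "bootstrap_se",
    "bh_fdr",
]

_MODEL_COVARIATES = {
    1: ("map", "age", "gest_age", "field_centre", "newborn_sex", "storage_weeks"),
    2: ("map", "age", "gest_age", "field_centre", "newborn_sex", "storage_weeks", "bmi"),
    3: ("map", "age", "gest_age", "field_centre", "newborn_sex", "storage_weeks", "parity"),
    4: ("map", "age", "gest_age", "field_centre", "newborn_sex", "storage_weeks", "parity", "bmi"),
}

CATEGORICAL_COVARIATES = ("field_centre", "newborn_sex")


@dataclass(frozen=True)
class CovariateModel:
    """One of the four nested covariate adjustment sets.

    Model 1: mean arterial pressure, maternal age, gestational age,
    field centre, newborn sex and sample storage time; model 2 adds BMI,
    model 3 adds parity, model 4 adds both.
    """

    model_id: int
    covariates: tuple = ()

    def __post_init__(self):
        if self.model_id not in _MODEL_COVARIATES:
            raise ValueError("model_id must be 1, 2, 3 or 4")
        if not self.covariates:
            object.__setattr__(self, "covariates", _MODEL_COVARIATES[self.model_id])
        elif tuple(self.covariates) != _MODEL_COVARIATES[self.model_id]:
            raise ValueError("covariate list inconsistent with model_id")


@dataclass
class AssociationResult:
    """Per-metabolite (or per-SNP) effect estimate."""

    metabolite: str
    timepoint: str
    beta: float
    se: float
    p: float
    n_obs: int
    n_missing: int
    method: str
    model_id: int
    fdr_q: float | None = None


@dataclass
class MixtureFit:
    """Fitted two-part censored-abundance model."""

    beta_cont: pd.Series
    gamma_disc: pd.Series | None
    sigma: float
    pi: np.ndarray = field(repr=False, default=None)
    loglik: float = np.nan
    converged: bool = False
    n_restarts: int = 0
    bootstrap_B: int = 0


def build_design(subjects: pd.DataFrame, covariates, drop_constant: bool = True) -> pd.DataFrame:
    """Covariate design matrix with intercept and dummy-coded categoricals.

    Categorical covariates are expanded against a reference level;
    within-stratum constant columns (e.g. field centre in single-centre
    strata) are dropped when ``drop_constant``.
    """
    cols = {}
    frames = [pd.Series(1.0, index=subjects.index, name="intercept")]
    for c in covariates:
        if c not in subjects.columns:
            raise ValueError(f"covariate {c!r} missing from subjects table")
        if c in CATEGORICAL_COVARIATES or subjects[c].dtype == object:
            dummies = pd.get_dummies(subjects[c].astype(str), prefix=c, drop_first=True, dtype=float)
            frames.append(dummies)
        else:
            frames.append(subjects[c].astype(float))
    design = pd.concat(frames, axis=1)
    if drop_constant:
        nunique = design.nunique()
        keep = (nunique > 1) | (design.columns == "intercept")
        design = design.loc[:, keep]
    return design


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        _, r = np.linalg.qr(arr)
        bad = [X.columns[j] for j in range(arr.shape[1]) if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _ols(y: np.ndarray, X: np.ndarray):
    """Plain OLS: coefficients, SEs, t-based p-values, residual variance."""
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - p
    s2 = resid @ resid / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return coef, se, pvals, s2


def fit_ols(
    y: pd.Series,
    x: pd.Series,
    subjects: pd.DataFrame,
    model: CovariateModel,
    timepoint: str = "fasting",
) -> AssociationResult:
    """OLS of the index outcome on one metabolite plus model covariates.

    Complete cases only; requires at least ``p + 2`` of them.  The
    reported beta/SE/p belong to the metabolite term (two-sided t test).
    """
    design = build_design(subjects, model.covariates)
    df = pd.concat([y.rename("_y"), x.rename("_x"), design], axis=1).dropna()
    n_total = len(y)
    if len(df) < design.shape[1] + 3:
        raise ValueError("too few complete cases for the requested model")
    X = df.drop(columns="_y")
    _check_full_rank(X)
    coef, se, pvals, _ = _ols(df["_y"].to_numpy(), X.to_numpy(dtype=float))
    j = list(X.columns).index("_x")
    return AssociationResult(
        metabolite=str(x.name),
        timepoint=timepoint,
        beta=float(coef[j]),
        se=float(se[j]),
        p=float(pvals[j]),
        n_obs=len(df),
        n_missing=n_total - len(df),
        method="ols",
        model_id=model.model_id,
    )


def _mixture_nll_grad(params, X, y_obs, obs_mask, fit_disc):
    """Joint negative log-likelihood and gradient."""
    n, p = X.shape
    beta = params[:p]
    log_sigma = params[p]
    sigma = np.exp(log_sigma)
    nll = 0.0
    grad = np.zeros_like(params)
    Xo = X[obs_mask]
    r = y_obs - Xo @ beta
    nll += np.sum(0.5 * np.log(2 * np.pi) + log_sigma + 0.5 * (r / sigma) ** 2)
    grad[:p] = -(Xo.T @ r) / sigma**2
    grad[p] = np.sum(1.0 - (r / sigma) ** 2)
    if fit_disc:
        gamma = params[p + 1 :]
        eta = X @ gamma
        # -[obs * log pi + cens * log(1-pi)]
        nll += np.sum(np.logaddexp(0.0, -eta)[obs_mask])
        nll += np.sum(np.logaddexp(0.0, eta)[~obs_mask])
        pi = special.expit(eta)
        grad[p + 1 :] = X.T @ (pi - obs_mask.astype(float))
    return nll, grad


def fit_mixture(
    y_metabolite: pd.Series,
    subjects: pd.DataFrame,
    phenotype: pd.Series,
    model: CovariateModel,
    timepoint: str = "fasting",
    max_restarts: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[MixtureFit, AssociationResult]:
    """Censored-abundance mixture fit for one non-targeted metabolite.

    ``y_metabolite`` holds observed log2 abundances with NaN at censored
    cells; the design is phenotype + model covariates (the metabolite is
    the outcome, following the mixture formulation).  Requires >= 10
    observed cells; with zero censored cells the logistic part is
    saturated and skipped.  The returned AssociationResult carries the
    continuous-part phenotype coefficient with its observed-cell OLS SE;
    bootstrap SEs are obtained via :func:`bootstrap_se`.
    """
    design = build_design(subjects, model.covariates)
    frame = pd.concat([phenotype.rename("_pheno"), design], axis=1)
    complete = frame.notna().all(axis=1)
    frame = frame.loc[complete]
    y = y_metabolite.reindex(frame.index)
    obs_mask = y.notna().to_numpy()
    n_obs = int(obs_mask.sum())
    n_cens = int((~obs_mask).sum())
    if n_obs < 10:
        raise ValueError(f"needs >=10 observed values, got {n_obs}")
    if n_obs == 0:
        raise ValueError("all cells censored; nothing to fit continuously")
    X = frame.to_numpy(dtype=float)
    _check_full_rank(frame.iloc[obs_mask.nonzero()[0]])
    y_obs = y.to_numpy(dtype=float)[obs_mask]
    p = X.shape[1]
    fit_disc = n_cens > 0

    coef0, _, _, s2 = _ols(y_obs, X[obs_mask])
    frac = n_obs / len(obs_mask)
    gamma0 = np.zeros(p)
    gamma0[list(frame.columns).index("intercept")] = special.logit(min(max(frac, 1e-3), 1 - 1e-3)) if fit_disc else 0.0
    x0 = np.concatenate([coef0, [0.5 * np.log(max(s2, 1e-12))], gamma0 if fit_disc else []])

    rng = rng or np.random.default_rng(0)
    best, n_restarts = None, 0
    start = x0
    for attempt in range(max_restarts + 1):
        res = optimize.minimize(
            _mixture_nll_grad,
            start,
            args=(X, y_obs, obs_mask, fit_disc),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
        n_restarts += 1
        start = x0 + rng.normal(0.0, 0.1, size=x0.shape)
    converged = bool(best.success)

    beta = pd.Series(best.x[:p], index=frame.columns)
    sigma = float(np.exp(best.x[p]))
    gamma = pd.Series(best.x[p + 1 :], index=frame.columns) if fit_disc else None
    pi = special.expit(X @ gamma.to_numpy()) if fit_disc else np.ones(len(X))
    fit = MixtureFit(
        beta_cont=beta,
        gamma_disc=gamma,
        sigma=sigma,
        pi=pi,
        loglik=-float(best.fun),
        converged=converged,
        n_restarts=n_restarts,
    )
    # analytic SE of the continuous part = OLS SE on observed cells
    _, se_obs, p_obs, _ = _ols(y_obs, X[obs_mask])
    j = list(frame.columns).index("_pheno")
    result = AssociationResult(
        metabolite=str(y_metabolite.name),
        timepoint=timepoint,
        beta=float(beta.iloc[j]),
        se=float(se_obs[j]),
        p=float(p_obs[j]),
        n_obs=n_obs,
        n_missing=n_cens,
        method="mixture",
        model_id=model.model_id,
    )
    return fit, result


def bootstrap_se(fitter, n_subjects: int, B: int, seed=None) -> tuple[np.ndarray, int]:
    """Nonparametric subject-level bootstrap SE of a fitted statistic.

    ``fitter`` maps an integer index array (a resample of
    ``range(n_subjects)`` with replacement) to a coefficient vector;
    replicates that raise or return non-finite values are dropped and
    counted.  Requires ``B >= 50``; errors if more than 20% of
    replicates fail.  Returns (SE per coefficient, n_failed).
    """
    if B < 50:
        raise ValueError("bootstrap needs B >= 50 replicates")
    rng = np.random.default_rng(seed)
    estimates, n_failed = [], 0
    for _ in range(B):
        idx = rng.integers(0, n_subjects, n_subjects)
        try:
            est = np.atleast_1d(np.asarray(fitter(idx), dtype=float))
        except Exception:
            n_failed += 1
            continue
        if not np.all(np.isfinite(est)):
            n_failed += 1
            continue
        estimates.append(est)
    if n_failed > 0.2 * B:
        raise RuntimeError(f"unstable fit: {n_failed}/{B} bootstrap replicates failed")
    arr = np.vstack(estimates)
    return arr.std(axis=0, ddof=1), n_failed


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1, returned in the input order.  Inputs must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
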