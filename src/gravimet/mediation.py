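"""Product-of-coefficients mediation: SNP -> metabolite -> index.

With all-linear paths and shared covariates the structural-equation
estimates coincide with a two-regression decomposition:

    mediator ~ snp + covariates          gives path a
    outcome  ~ snp + mediator + covariates   gives paths c (direct) and b

indirect = a * b, total = a * b + c, and the identity total = indirect
+ direct equals the coefficient of the reduced regression outcome ~ snp
+ covariates to float tolerance (asserted on every fit).  Path SEs are
normal-theory; SE(indirect) uses the Sobel delta formula
sqrt(a^2 se_b^2 + b^2 se_a^2); the proportion mediated indirect/total
gets percentile-bootstrap CIs because ratio distributions are
non-normal, and is only meaningful under genuine mediation (not under
suppression, where the indirect path opposes the direct one).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MediationResult", "fit_mediation", "bootstrap_mediation", "classify_effect"]


@dataclass
class MediationResult:
    """Paths, composite effects and their uncertainties."""

    a: float
    b: float
    c: float
    indirect: float
    total: float
    se_a: float
    se_b: float
    se_c: float
    se_indirect: float
    p_a: float
    p_b: float
    p_c: float
    p_indirect: float
    proportion_mediated: float
    suppression: bool
    n: int
    ci_indirect: tuple | None = None
    ci_total: tuple | None = None
    ci_proportion: tuple | None = None
    se_indirect_boot: float | None = None
    n_unstable: int = 0
    classification: str | None = None


def _lstsq_with_se(y: np.ndarray, X: np.ndarray):
    n, p = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("collinear design in mediation fit")
    resid = y - X @ coef
    dof = n - p
    s2 = resid @ resid / dof
    se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
    return coef, se, dof


def _paths(snp, mediator, outcome, C):
    """Core two-regression decomposition on aligned numpy arrays."""
    Xa = np.column_stack([snp, C])
    a_coef, a_se, a_dof = _lstsq_with_se(mediator, Xa)
    Xb = np.column_stack([snp, mediator, C])
    b_coef, b_se, b_dof = _lstsq_with_se(outcome, Xb)
    a, se_a = a_coef[0], a_se[0]
    c, se_c = b_coef[0], b_se[0]
    b, se_b = b_coef[1], b_se[1]
    return a, b, c, se_a, se_b, se_c, a_dof, b_dof


def fit_mediation(
    snp: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    total_tol: float = 1e-8,
) -> MediationResult:
    """Fit the mediation triangle on complete cases.

    Asserts the linear identity total = indirect + direct against an
    independent reduced regression of the outcome on the SNP and
    covariates alone; a violation beyond ``total_tol`` (relative) is a
    programming error and raises.
    """
    frames = [snp.rename("_snp"), mediator.rename("_med"), outcome.rename("_out")]
    if covariates is not None:
        frames.append(covariates)
    df = pd.concat(frames, axis=1).dropna()
    n = len(df)
    ncov = 0 if covariates is None else covariates.shape[1]
    if n < ncov + 5:
        raise ValueError("too few complete cases for mediation")
    C = np.column_stack([np.ones(n)] + ([df.iloc[:, 3:].to_numpy(dtype=float)] if ncov else []))
    s = df["_snp"].to_numpy(dtype=float)
    m = df["_med"].to_numpy(dtype=float)
    y = df["_out"].to_numpy(dtype=float)
    if np.corrcoef(s, m)[0, 1] ** 2 > 0.99:
        raise ValueError("snp and mediator are nearly collinear")
    a, b, c, se_a, se_b, se_c, a_dof, b_dof = _paths(s, m, y, C)
    indirect = a * b
    total = indirect + c
    # independent check: reduced regression gives the total effect
    tot_coef, _, _ = _lstsq_with_se(y, np.column_stack([s, C]))
    if abs(tot_coef[0] - total) > total_tol * max(1.0, abs(total)):
        raise AssertionError("total-effect identity violated; decomposition is inconsistent")
    se_indirect = float(np.sqrt(a**2 * se_b**2 + b**2 * se_a**2))
    p_a = 2.0 * stats.t.sf(abs(a / se_a), a_dof)
    p_b = 2.0 * stats.t.sf(abs(b / se_b), b_dof)
    p_c = 2.0 * stats.t.sf(abs(c / se_c), b_dof)
    p_ind = 2.0 * stats.norm.sf(abs(indirect / se_indirect)) if se_indirect > 0 else 1.0
    suppression = abs(c) > abs(total) and np.sign(indirect) != np.sign(c) and indirect != 0
    return MediationResult(
        a=float(a),
        b=float(b),
        c=float(c),
        indirect=float(indirect),
        total=float(total),
        se_a=float(se_a),
        se_b=float(se_b),
        se_c=float(se_c),
        se_indirect=se_indirect,
        p_a=float(p_a),
        p_b=float(p_b),
        p_c=float(p_c),
        p_indirect=float(p_ind),
        proportion_mediated=float(indirect / total) if total != 0 else np.nan,
        suppression=bool(suppression),
        n=n,
    )


def bootstrap_mediation(
    snp: pd.Series,
    mediator: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    B: int = 1000,
    seed=None,
    total_floor: float = 1e-3,
) -> MediationResult:
    """Percentile-bootstrap CIs for indirect, total and proportion mediated.

    Subject-level resampling with replacement; requires ``B >= 200``.
    Replicates whose |total| falls below ``total_floor`` are excluded
    from the proportion CI (ratio instability guard) and counted; more
    than 10% exclusions attaches a warning count to the result.
    """
    if B < 200:
        raise ValueError("bootstrap_mediation needs B >= 200")
    point = fit_mediation(snp, mediator, outcome, covariates)
    frames = [snp.rename("_snp"), mediator.rename("_med"), outcome.rename("_out")]
    if covariates is not None:
        frames.append(covariates)
    df = pd.concat(frames, axis=1).dropna()
    n = len(df)
    ncov = 0 if covariates is None else covariates.shape[1]
    s = df["_snp"].to_numpy(dtype=float)
    m = df["_med"].to_numpy(dtype=float)
    y = df["_out"].to_numpy(dtype=float)
    Cfull = np.column_stack([np.ones(n)] + ([df.iloc[:, 3:].to_numpy(dtype=float)] if ncov else []))
    rng = np.random.default_rng(seed)
    ind, tot, prop = [], [], []
    n_unstable = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            a, b, c, *_ = _paths(s[idx], m[idx], y[idx], Cfull[idx])
        except (ValueError, np.linalg.LinAlgError):
            n_unstable += 1
            continue
        i_rep, t_rep = a * b, a * b + c
        ind.append(i_rep)
        tot.append(t_rep)
        if abs(t_rep) >= total_floor:
            prop.append(i_rep / t_rep)
        else:
            n_unstable += 1
    ind, tot = np.asarray(ind), np.asarray(tot)
    point.ci_indirect = tuple(np.percentile(ind, [2.5, 97.5]))
    point.ci_total = tuple(np.percentile(tot, [2.5, 97.5]))
    point.ci_proportion = tuple(np.percentile(prop, [2.5, 97.5])) if prop else None
    point.se_indirect_boot = float(ind.std(ddof=1))
    point.n_unstable = n_unstable
    point.classification = classify_effect(point)
    return point


def classify_effect(result: MediationResult) -> str:
    """Label a fitted triangle as mediation, suppression or none.

    "mediation" requires the indirect CI to exclude zero with the
    indirect and total effects sharing a sign; "suppression" requires
    the indirect CI to exclude zero with |direct| > |total| and opposed
    signs; anything else is "none".  Falls back to the delta-method
    normal CI when no bootstrap CI is attached.
    """
    ci = result.ci_indirect
    if ci is None:
        half = 1.959963984540054 * result.se_indirect
        ci = (result.indirect - half, result.indirect + half)
    excludes_zero = ci[0] > 0 or ci[1] < 0
    if not excludes_zero:
        return "none"
    if np.sign(result.indirect) == np.sign(result.total):
        return "mediation"
    if abs(result.c) > abs(result.total):
        return "suppression"
    return "none"
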