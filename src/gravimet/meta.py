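"""Cross-stratum pooling of association estimates.

Random-effects pooling uses the DerSimonian–Laird moment estimator of
the between-stratum variance tau^2 (REML optional); heterogeneity is
described by Cochran's Q with a chi-square(k-1) reference and by I^2.
Fixed-effects pooling supports both the inverse-variance convention and
the sample-size-weighted z-score convention common in GWAS
meta-analysis.

Two I^2 forms are reported: the tau^2-based form
100 * tau^2 / (tau^2 + v~) with v~ the typical within-stratum variance,
and the Higgins Q-based form 100 * max(0, (Q - df) / Q).  Both are zero
whenever Q <= k - 1 (which forces the DL tau^2 to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

__all__ = ["MetaResult", "cochran_q", "random_effects_dl", "random_effects_reml", "fixed_effects"]


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    beta_pooled: float
    se_pooled: float
    p: float
    tau2: float
    Q: float
    q_p: float
    i2: float
    i2_higgins: float
    k: int
    scheme: str


def _check(betas, ses):
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise ValueError("betas and ses must be 1-d arrays of equal length")
    if len(b) < 2:
        raise ValueError("meta-analysis needs at least two strata")
    if np.any(~np.isfinite(b)) or np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all SEs must be finite and positive")
    return b, s


def cochran_q(betas, ses) -> tuple[float, float]:
    """Cochran's heterogeneity statistic and its chi-square(k-1) p-value.

    Q = sum w_i (beta_i - beta_FE)^2 with w_i = 1/se_i^2 and beta_FE the
    inverse-variance pooled effect.
    """
    b, s = _check(betas, ses)
    w = 1.0 / s**2
    beta_fe = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta_fe) ** 2))
    q_p = float(stats.chi2.sf(q, df=len(b) - 1))
    return q, q_p


def _pool(b, s, tau2, scheme) -> MetaResult:
    q, q_p = cochran_q(b, s)
    k = len(b)
    w = 1.0 / s**2
    sw, sw2 = np.sum(w), np.sum(w**2)
    wstar = 1.0 / (s**2 + tau2)
    beta = float(np.sum(wstar * b) / np.sum(wstar))
    se = float(1.0 / np.sqrt(np.sum(wstar)))
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    v_typ = (k - 1) * sw / (sw**2 - sw2)  # typical within-stratum variance
    i2 = 100.0 * tau2 / (tau2 + v_typ) if tau2 > 0 else 0.0
    i2_h = 100.0 * max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    return MetaResult(beta, se, p, float(tau2), q, q_p, i2, i2_h, k, scheme)


def random_effects_dl(betas, ses) -> MetaResult:
    """DerSimonian–Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)); pooled
    effect uses weights 1/(se_i^2 + tau^2) and a two-sided normal p.
    """
    b, s = _check(betas, ses)
    q, _ = cochran_q(b, s)
    w = 1.0 / s**2
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (len(b) - 1)) / denom)
    return _pool(b, s, tau2, "random_dl")


def random_effects_reml(betas, ses, tol: float = 1e-10) -> MetaResult:
    """Restricted-maximum-likelihood tau^2 alternative to DL."""
    b, s = _check(betas, ses)

    def neg_restricted_ll(tau2):
        v = s**2 + tau2
        w = 1.0 / v
        mu = np.sum(w * b) / np.sum(w)
        return 0.5 * (np.sum(np.log(v)) + np.log(np.sum(w)) + np.sum(w * (b - mu) ** 2))

    upper = max(10.0 * np.var(b), 1.0)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper), method="bounded",
                                   options={"xatol": tol})
    return _pool(b, s, float(res.x), "random_reml")


def fixed_effects(betas, ses, ns=None, scheme: str = "fixed_iv") -> MetaResult:
    """Fixed-effects pooling.

    ``fixed_iv``: inverse-variance weights, pooled SE = 1/sqrt(sum w).
    ``fixed_samplesize``: the GWAS sample-size-weighted z convention —
    z_pooled = sum(sqrt(n_i) z_i) / sqrt(sum n_i) with z_i = beta_i/se_i;
    the p-value comes from z_pooled while the reported pooled beta/SE are
    the inverse-variance ones (a z-score scheme carries no effect scale).
    """
    b, s = _check(betas, ses)
    res = _pool(b, s, 0.0, "fixed_iv")
    if scheme == "fixed_iv":
        return res
    if scheme != "fixed_samplesize":
        raise ValueError(f"unknown fixed-effects scheme {scheme!r}")
    if ns is None:
        raise ValueError("sample sizes required for the sample-size-weighted scheme")
    n = np.asarray(ns, dtype=float)
    if n.shape != b.shape or np.any(n <= 0):
        raise ValueError("sample sizes must be positive, one per stratum")
    z = b / s
    z_pooled = float(np.sum(np.sqrt(n) * z) / np.sqrt(np.sum(n)))
    p = float(2.0 * stats.norm.sf(abs(z_pooled)))
    return replace(res, p=p, scheme="fixed_samplesize")
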