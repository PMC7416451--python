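"""Synthetic multi-ancestry pregnancy cohort generator.

Emulates the data structure of a multi-ancestry OGTT metabolomics +
genotyping study: four ancestry strata with stratum-specific allele
frequencies and intercepts, OGTT glucose/C-peptide measurements, a
two-timepoint metabolite panel split into fully observed targeted and
left-censored non-targeted arms, daily assay batches, and one focal SNP
whose effect on the (log) insulin-sensitivity index is partially
mediated by one metabolite.

The OGTT values are generated backwards: fasting glucose and C-peptide
are drawn from stratum log-normals and the 1 h values are solved (equal
multiplicative inflation on both) so that the realised composite index
equals the latent target exp(L).  With inflation r applied to both 1 h
values the index reduces to 2000 / (fpg * fcp * (1 + r)), so
r = 2000 / (I * fpg * fcp) - 1; draws with non-positive r are rejected
and redrawn, and the count is reported.

Randomness uses one master ``SeedSequence`` spawned into named
substreams in a fixed order (genotypes, covariates, ogtt, metabolites,
batches), so changing the metabolite panel does not perturb genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qc import METABOLITE_CLASSES, MetaboliteMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticCohort",
    "simulate_cohort",
    "mean_arterial_pressure",
]

STRATA = ("afro_caribbean", "northern_european", "mexican_american", "thai")

#: covariate effects on the latent log index (per unit of the centred scale)
COVARIATE_BETAS = {"bmi": -0.015, "age": -0.004}

FOCAL_SNP_ID = "rs1260326"


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """Mean arterial pressure, (SBP + 2*DBP) / 3, mmHg.

    Requires ``sbp >= dbp > 0``.
    """
    sbp_a, dbp_a = np.asarray(sbp, dtype=float), np.asarray(dbp, dtype=float)
    if np.any(dbp_a <= 0):
        raise ValueError("diastolic pressure must be positive")
    if np.any(dbp_a > sbp_a):
        raise ValueError("diastolic pressure exceeds systolic")
    out = (sbp_a + 2.0 * dbp_a) / 3.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Path coefficients follow the mediation triangle: ``path_a`` is the
    per-allele effect of the focal SNP dosage on the mediator metabolite
    (SD units), ``path_b`` the effect of the mediator on the log
    insulin-sensitivity index, and ``path_c`` the direct per-allele
    dosage effect on the log index.  The implied proportion mediated is
    ``a*b / (a*b + c)``.  Defaults echo the study's mediation triangle
    (a=-0.19, b=0.16, c=-0.19, proportion mediated ~= 13.8%).
    """

    n_per_stratum: int = 400
    n_genotyped_per_stratum: int = 1100
    n_strata: int = 4
    n_metabolites: int = 135
    n_nontargeted: int = 71
    n_snps: int = 100
    focal_snp_freqs: tuple = (0.15, 0.40, 0.35, 0.50)
    path_a: float = -0.19
    path_b: float = 0.16
    path_c: float = -0.19
    censor_quantile: float = 0.30
    sd_metabolite: float = 1.0
    sd_log_index: float = 0.18
    sd_batch: float = 0.15
    class_corr: float = 0.30
    mediator_name: str = "palmitoleic_acid"
    mediator_timepoint: str = "1h"
    batch_size: int = 22
    seed: int = 0

    def validate(self) -> None:
        if self.n_strata < 1 or len(self.focal_snp_freqs) != self.n_strata:
            raise ValueError("focal_snp_freqs must give one frequency per stratum")
        if not all(0.0 < f < 1.0 for f in self.focal_snp_freqs):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        if not (0.0 <= self.censor_quantile < 1.0):
            raise ValueError("censor_quantile must lie in [0, 1)")
        if min(self.sd_metabolite, self.sd_log_index, self.sd_batch) <= 0:
            raise ValueError("all residual SDs must be positive")
        if not (0.0 <= self.class_corr < 1.0):
            raise ValueError("class_corr must lie in [0, 1)")
        if self.n_nontargeted > self.n_metabolites:
            raise ValueError("n_nontargeted exceeds n_metabolites")
        if self.n_per_stratum > self.n_genotyped_per_stratum:
            raise ValueError("metabolomics subjects must be a subset of genotyped subjects")
        total = self.path_a * self.path_b + self.path_c
        if total != 0 and not math.isfinite(self.implied_proportion_mediated()):
            raise ValueError("implied proportion mediated is not finite")

    def implied_proportion_mediated(self) -> float:
        """(a*b) / (a*b + c); negative or >1 under suppression."""
        indirect = self.path_a * self.path_b
        total = indirect + self.path_c
        if total == 0:
            return math.nan
        return indirect / total


@dataclass
class GroundTruth:
    """Everything needed to recompute the injected effects."""

    path_a: float
    path_b: float
    path_c: float
    indirect: float
    total: float
    proportion_mediated: float
    covariate_betas: dict
    stratum_intercepts: dict
    focal_snp: str
    focal_snp_freqs: dict
    mediator_name: str
    mediator_timepoint: str
    censor_quantile: float
    n_ogtt_redraws: int
    latent_log_index: np.ndarray = field(repr=False, default=None)
    mediator_latent: np.ndarray = field(repr=False, default=None)
    detection_limits: dict = field(repr=False, default_factory=dict)

    def scalars(self) -> dict:
        """JSON-serialisable summary (arrays excluded)."""
        return {
            "path_a": self.path_a,
            "path_b": self.path_b,
            "path_c": self.path_c,
            "indirect": self.indirect,
            "total": self.total,
            "proportion_mediated": self.proportion_mediated,
            "covariate_betas": self.covariate_betas,
            "stratum_intercepts": self.stratum_intercepts,
            "focal_snp": self.focal_snp,
            "focal_snp_freqs": self.focal_snp_freqs,
            "mediator_name": self.mediator_name,
            "mediator_timepoint": self.mediator_timepoint,
            "censor_quantile": self.censor_quantile,
            "n_ogtt_redraws": self.n_ogtt_redraws,
        }


@dataclass
class SyntheticCohort:
    """Simulated cohort: subjects, genotypes, metabolites and ground truth."""

    subjects: pd.DataFrame
    dosages: pd.DataFrame
    snp_meta: pd.DataFrame
    fasting: MetaboliteMatrix
    one_hour: MetaboliteMatrix
    truth: GroundTruth

    @property
    def metabolomics_ids(self) -> pd.Index:
        return self.subjects.index[self.subjects["has_metabolomics"]]


def _truncated_normal(rng, loc, scale, size, lower=-np.inf, upper=np.inf):
    out = rng.normal(loc, scale, size)
    bad = (out < lower) | (out > upper)
    while bad.any():
        out[bad] = rng.normal(loc, scale, bad.sum())
        bad = (out < lower) | (out > upper)
    return out


def _simulate_genotypes(rng, cfg: SimulationConfig, strata: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(strata)
    snp_ids = [FOCAL_SNP_ID] + [f"snp{j:04d}" for j in range(1, cfg.n_snps)]
    base = rng.uniform(0.10, 0.90, cfg.n_snps)
    shift = rng.normal(0.0, 0.05, (cfg.n_strata, cfg.n_snps))
    freqs = np.clip(base[None, :] + shift, 0.02, 0.98)
    freqs[:, 0] = np.asarray(cfg.focal_snp_freqs, dtype=float)
    dos = np.empty((n, cfg.n_snps), dtype=float)
    for s in range(cfg.n_strata):
        rows = strata == s
        dos[rows] = rng.binomial(2, freqs[s], size=(rows.sum(), cfg.n_snps))
    snp_meta = pd.DataFrame(
        {
            "chrom": ["2"] + [str(1 + j % 22) for j in range(1, cfg.n_snps)],
            "pos": np.arange(1, cfg.n_snps + 1) * 10_000 + 27_000_000,
            "effect_allele": ["C"] + ["A"] * (cfg.n_snps - 1),
            "other_allele": ["T"] + ["G"] * (cfg.n_snps - 1),
        },
        index=pd.Index(snp_ids, name="snp"),
    )
    for s, name in enumerate(STRATA[: cfg.n_strata]):
        snp_meta[f"freq_{name}"] = freqs[s]
    return pd.DataFrame(dos, columns=snp_ids), snp_meta


def _simulate_covariates(rng, cfg: SimulationConfig, strata: np.ndarray) -> pd.DataFrame:
    n = len(strata)
    names = np.array(STRATA[: cfg.n_strata])[strata]
    age = _truncated_normal(rng, 29.0, 5.0, n, lower=18.0)
    bmi = _truncated_normal(rng, 27.0, 5.0, n, lower=15.0 + 1e-9)
    height = rng.normal(160.0, 7.0, n)
    gest_age = rng.normal(27.7, 1.6, n)
    parity = rng.poisson(1.0, n)
    smoking = rng.random(n) < 0.10
    alcohol = rng.random(n) < 0.15
    storage = rng.uniform(1.0, 6.0, n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    dbp = np.clip(rng.normal(70.0, 8.0, n), 45.0, None)
    sbp = dbp + np.abs(rng.normal(35.0, 8.0, n)) + 1.0
    # only the Northern European stratum is multi-centre
    centre = np.where(
        names == "northern_european",
        np.char.add("ne_centre_", rng.integers(1, 4, n).astype(str)),
        np.char.add(names.astype(str), "_centre"),
    )
    return pd.DataFrame(
        {
            "stratum": names,
            "field_centre": centre,
            "age": age,
            "bmi": bmi,
            "height": height,
            "gest_age": gest_age,
            "parity": parity,
            "smoking": smoking.astype(int),
            "alcohol": alcohol.astype(int),
            "storage_weeks": storage,
            "newborn_sex": sex,
            "sbp": sbp,
            "dbp": dbp,
            "map": mean_arterial_pressure(sbp, dbp),
        }
    )


def _metabolite_meta(cfg: SimulationConfig) -> pd.DataFrame:
    n_targeted = cfg.n_metabolites - cfg.n_nontargeted
    names, arms = [], []
    for j in range(cfg.n_metabolites):
        if j < n_targeted:
            arms.append("targeted")
            names.append(f"t_met{j:03d}")
        else:
            arms.append("nontargeted")
            names.append(f"nt_met{j - n_targeted:03d}")
    classes = [METABOLITE_CLASSES[j % len(METABOLITE_CLASSES)] for j in range(cfg.n_metabolites)]
    meta = pd.DataFrame(
        {"class": classes, "arm": arms}, index=pd.Index(names, name="metabolite")
    )
    # the mediator is a fully observed targeted metabolite (fatty acid)
    med_pos = min(2, n_targeted - 1)
    new_names = list(meta.index)
    new_names[med_pos] = cfg.mediator_name
    meta.index = pd.Index(new_names, name="metabolite")
    meta.loc[cfg.mediator_name, "class"] = "fatty acid"
    return meta


def _simulate_metabolites(
    rng, cfg: SimulationConfig, meta: pd.DataFrame, dosage_focal: np.ndarray, bmi: np.ndarray, strata: np.ndarray
) -> dict:
    """Latent (pre-censoring, pre-batch) metabolite values per timepoint.

    Unit-variance values with within-class equicorrelation class_corr;
    the mediator at the configured timepoint carries path_a per allele.
    """
    n, p = len(dosage_focal), len(meta)
    class_codes = meta["class"].astype("category").cat.codes.to_numpy()
    n_classes = class_codes.max() + 1
    rho = cfg.class_corr
    mu_stratum = rng.normal(0.0, 0.3, (cfg.n_strata, p))
    shift_1h = rng.normal(0.3, 0.3, p)
    out = {}
    med_col = meta.index.get_loc(cfg.mediator_name)
    for tp in ("fasting", "1h"):
        factors = rng.normal(0.0, 1.0, (n, n_classes))
        eps = rng.normal(0.0, 1.0, (n, p))
        lat = math.sqrt(rho) * factors[:, class_codes] + math.sqrt(1 - rho) * eps
        lat *= cfg.sd_metabolite
        lat += mu_stratum[strata]
        if tp == "1h":
            lat += shift_1h[None, :]
        if tp == cfg.mediator_timepoint:
            lat[:, med_col] += cfg.path_a * dosage_focal + 0.05 * (bmi - 27.0) / 5.0
        out[tp] = lat
    return out


def _invert_ogtt(rng, mu_log_index: np.ndarray, sd_noise: float) -> tuple[pd.DataFrame, np.ndarray, int]:
    """Draw fasting OGTT values and solve 1 h values to hit the index target.

    The index noise is drawn jointly with the fasting values and the
    triple (noise, fpg, fcp) is rejection-sampled until the implied
    inflation factor r is positive; rejections are counted.  The
    acceptance region covers essentially all of the noise distribution
    for realistic systematic components, so the realised latent index
    is at most negligibly truncated.
    """
    n = len(mu_log_index)
    eps = rng.normal(0.0, sd_noise, n)
    fpg = rng.lognormal(math.log(4.5), 0.10, n)
    fcp = rng.lognormal(math.log(1.7), 0.25, n)
    n_redraws = 0
    for _ in range(1000):
        r = 2000.0 / (np.exp(mu_log_index + eps) * fpg * fcp) - 1.0
        bad = r <= 0
        if not bad.any():
            break
        k = int(bad.sum())
        n_redraws += k
        eps[bad] = rng.normal(0.0, sd_noise, k)
        fpg[bad] = rng.lognormal(math.log(4.5), 0.10, k)
        fcp[bad] = rng.lognormal(math.log(1.7), 0.25, k)
    else:
        # stragglers with a tiny acceptance region: draw the noise from its
        # exact truncated conditional given the current fasting values
        upper = math.log(2000.0) - mu_log_index[bad] - np.log(fpg[bad] * fcp[bad])
        u = rng.uniform(0.0, 1.0, int(bad.sum()))
        q = np.clip(u * stats.norm.cdf(upper / sd_noise), 1e-300, 1 - 1e-16)
        eps[bad] = sd_noise * stats.norm.ppf(q)
        r = 2000.0 / (np.exp(mu_log_index + eps) * fpg * fcp) - 1.0
        if np.any(r <= 0):
            raise RuntimeError("OGTT inversion failed: latent index targets out of range")
    return (
        pd.DataFrame({"fpg": fpg, "g1h": r * fpg, "fcp": fcp, "cp1h": r * fcp}),
        mu_log_index + eps,
        n_redraws,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config``.

    Reproducible given ``config.seed``; see module docstring for the
    generative model and the backwards OGTT construction.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_geno, rng_cov, rng_ogtt, rng_met, rng_batch = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    strata = np.repeat(np.arange(config.n_strata), config.n_genotyped_per_stratum)
    n_total = len(strata)
    has_met = np.zeros(n_total, dtype=bool)
    for s in range(config.n_strata):
        start = s * config.n_genotyped_per_stratum
        has_met[start : start + config.n_per_stratum] = True

    dosages, snp_meta = _simulate_genotypes(rng_geno, config, strata)
    subjects = _simulate_covariates(rng_cov, config, strata)
    subjects.index = pd.Index([f"S{i:05d}" for i in range(n_total)], name="subject_id")
    dosages.index = subjects.index
    subjects["has_metabolomics"] = has_met

    meta = _metabolite_meta(config)
    dos_focal = dosages[FOCAL_SNP_ID].to_numpy()
    latents = _simulate_metabolites(
        rng_met, config, meta, dos_focal, subjects["bmi"].to_numpy(), strata
    )
    med_col = meta.index.get_loc(config.mediator_name)
    mediator_latent = latents[config.mediator_timepoint][:, med_col]

    intercepts = {name: math.log(70.0) + d for name, d in zip(STRATA[: config.n_strata], (0.05, -0.02, 0.0, -0.08))}
    alpha = np.array([intercepts[s] for s in subjects["stratum"]])
    mu_log_index = (
        alpha
        + config.path_c * dos_focal
        + config.path_b * mediator_latent
        + COVARIATE_BETAS["bmi"] * (subjects["bmi"].to_numpy() - 27.0)
        + COVARIATE_BETAS["age"] * (subjects["age"].to_numpy() - 29.0)
    )
    ogtt, log_index, n_redraws = _invert_ogtt(rng_ogtt, mu_log_index, config.sd_log_index)
    ogtt.index = subjects.index
    subjects = pd.concat([subjects, ogtt], axis=1)

    # metabolomics arm: restrict panel, apply batch shifts + censoring
    met_ids = subjects.index[has_met]
    order = np.arange(has_met.sum())
    batch_labels = pd.Series(
        [f"batch{b:03d}" for b in order // config.batch_size], index=met_ids, name="batch"
    )
    n_batches = int(order.max() // config.batch_size) + 1
    batch_shift = rng_batch.normal(0.0, config.sd_batch, n_batches)
    nt_cols = meta["arm"] == "nontargeted"
    ln_like = (meta["class"] == "acylcarnitine") & (meta["arm"] != "nontargeted")

    matrices: dict[str, MetaboliteMatrix] = {}
    limits: dict[str, pd.Series] = {}
    for tp in ("fasting", "1h"):
        lat = latents[tp][has_met].copy()
        lat[:, nt_cols.to_numpy()] += batch_shift[order // config.batch_size][:, None]
        # raw-scale encoding: nontargeted as 2**(lat+18) peak areas,
        # acylcarnitines as exp(lat), others as the latent value directly
        raw = lat.copy()
        raw[:, nt_cols.to_numpy()] = 2.0 ** (lat[:, nt_cols.to_numpy()] + 18.0)
        raw[:, ln_like.to_numpy()] = np.exp(lat[:, ln_like.to_numpy()])
        df = pd.DataFrame(raw, index=met_ids, columns=meta.index)
        lim = pd.Series(np.nan, index=meta.index, name="detection_limit")
        if config.censor_quantile > 0:
            for col in meta.index[nt_cols]:
                q = np.quantile(df[col].to_numpy(), config.censor_quantile)
                lim[col] = q
                df.loc[df[col] < q, col] = np.nan
        limits[tp] = lim
        matrices[tp] = MetaboliteMatrix(
            values=df, meta=meta.copy(), timepoint=tp, transform="raw", batch=batch_labels.copy()
        )

    indirect = config.path_a * config.path_b
    total = indirect + config.path_c
    truth = GroundTruth(
        path_a=config.path_a,
        path_b=config.path_b,
        path_c=config.path_c,
        indirect=indirect,
        total=total,
        proportion_mediated=config.implied_proportion_mediated(),
        covariate_betas=dict(COVARIATE_BETAS),
        stratum_intercepts=intercepts,
        focal_snp=FOCAL_SNP_ID,
        focal_snp_freqs={name: f for name, f in zip(STRATA[: config.n_strata], config.focal_snp_freqs)},
        mediator_name=config.mediator_name,
        mediator_timepoint=config.mediator_timepoint,
        censor_quantile=config.censor_quantile,
        n_ogtt_redraws=n_redraws,
        latent_log_index=log_index,
        mediator_latent=mediator_latent,
        detection_limits=limits,
    )
    return SyntheticCohort(
        subjects=subjects,
        dosages=dosages,
        snp_meta=snp_meta,
        fasting=matrices["fasting"],
        one_hour=matrices["1h"],
        truth=truth,
    )
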