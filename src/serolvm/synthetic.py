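"""Synthetic cohorts with the structure the latent-variable model assumes.

The generator draws, per subject, covariates (age, injected tracer dose,
scanner), plasma testosterone, plasma estradiol coupled to testosterone,
a global latent binding factor driven by group and hormones, and four
regional BP_ND outcomes loading on that factor — then left-censors
estradiol at the assay LOQ. Because outcomes are generated from the
structural equations themselves, the fitted model is literally true in
the simulated population, which makes exact parameter-recovery and
calibration studies possible.

Group-level defaults (sample sizes, hormone moments, group effect,
hormone slopes, LOQ) follow the published cohort summaries; regional
intercepts, loadings and residual scales are free choices documented in
:func:`default_params`, picked so simulated BP_ND is positive and
region-ordered (neostriatum high, hippocampus/amygdala intermediate,
prefrontal cortex low).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import (
    BP_COLUMNS,
    GROUP_HC,
    GROUP_MDD,
    HAMD_COLUMNS,
    HAMD_ITEM_MAX,
    REGIONS,
    SCANNER_GE,
    SCANNER_HRRT,
    VEGETATIVE_ITEMS,
)

__all__ = ["GeneratorParams", "default_params", "generate_cohort", "generate_hamd"]


@dataclass
class HamdParams:
    """Item-generation settings for the 17-item Hamilton scale.

    Items are generated by thresholding a standard-normal latent score.
    For vegetative items the latent score is ``veg_loading`` times the
    subject's standardized testosterone plus independent noise; core and
    remaining items are independent of hormones.
    """

    veg_loading: float = 0.5
    #: marginal level probabilities for 0–4 items (moderate–severe cohort)
    p_levels_04: tuple = (0.15, 0.25, 0.30, 0.20, 0.10)
    #: marginal level probabilities for 0–2 items
    p_levels_02: tuple = (0.35, 0.45, 0.20)


@dataclass
class GeneratorParams:
    """Population parameters of the synthetic cohort generator.

    Regional vectors are ordered (neostriatum, hippocampus, amygdala,
    prefrontal). The first loading is fixed at 1 by the identification
    convention of the fitting engine. Group is coded 0 = HC, 1 = MDD and
    scanner 0 = HRRT, 1 = GE throughout.
    """

    n_mdd: int = 25
    n_hc: int = 52

    # measurement model -------------------------------------------------
    nu: tuple = (3.00, 1.05, 1.00, 0.65)
    lam: tuple = (1.0, 0.45, 0.40, 0.30)
    beta_age: tuple = (-0.015, -0.006, -0.006, -0.004)
    beta_dose: tuple = (-3.0, -1.2, -1.2, -0.8)
    beta_scanner: tuple = (-0.10, -0.05, -0.05, -0.03)
    sigma_region: tuple = (0.22, 0.12, 0.12, 0.08)
    #: extra residual covariance between hippocampus and amygdala (BP_ND²)
    cov_hipp_amyg: float = 0.004

    # structural model ---------------------------------------------------
    gamma_group: float = -0.07
    gamma1_hc: float = -0.0074
    gamma1_mdd: float = 0.0001
    gamma2_hc: float = 1.74
    gamma2_mdd: float = 0.64
    sigma_zeta: float = 0.12

    # hormone submodel ----------------------------------------------------
    gamma3: float = 0.003
    alpha_e: float = 0.05
    sigma_e: float = 0.03
    mu_t_hc: float = 17.9
    sigma_t_hc: float = 5.7
    mu_t_mdd: float = 16.7
    sigma_t_mdd: float = 7.4
    loq: float = 0.09

    # covariate distributions --------------------------------------------
    age_mu_hc: float = 26.5
    age_sd_hc: float = 5.9
    age_mu_mdd: float = 27.2
    age_sd_mdd: float = 7.9
    age_range: tuple = (18.0, 50.0)
    dose_mu_hc: float = 0.019
    dose_sd_hc: float = 0.015
    dose_mu_mdd: float = 0.012
    dose_sd_mdd: float = 0.011
    #: fraction of HC subjects scanned on the GE camera (6 of 52)
    ge_fraction_hc: float = 6.0 / 52.0
    #: whether MDD subjects may be assigned the GE scanner
    ge_allowed_mdd: bool = False

    hamd_params: HamdParams = field(default_factory=HamdParams)
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.hamd_params, dict):
            self.hamd_params = HamdParams(**self.hamd_params)
        self.validate()

    def validate(self) -> None:
        if self.n_mdd < 0 or self.n_hc < 0:
            raise ValueError("sample sizes must be non-negative")
        # zero SDs are permitted so that noise-free oracle cohorts exist
        for name in ("sigma_zeta", "sigma_e", "sigma_t_hc", "sigma_t_mdd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(s < 0 for s in self.sigma_region):
            raise ValueError("sigma_region entries must be >= 0")
        if self.loq <= 0:
            raise ValueError("loq must be > 0")
        for vec in (self.nu, self.lam, self.beta_age, self.beta_dose,
                    self.beta_scanner, self.sigma_region):
            if len(vec) != len(REGIONS):
                raise ValueError("regional parameter vectors must have 4 entries")
            if not np.all(np.isfinite(vec)):
                raise ValueError("regional parameters must be finite")

    # YAML round-trip ----------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key, val in list(d.items()):
            if isinstance(val, list):
                d[key] = tuple(val)
        if "hamd_params" in d and isinstance(d["hamd_params"], dict):
            for key, val in list(d["hamd_params"].items()):
                if isinstance(val, list):
                    d["hamd_params"][key] = tuple(val)
        return cls(**d)


def default_params(**overrides) -> GeneratorParams:
    """Parameters emulating the study cohort (25 MDD, 52 HC men).

    Group effect on the latent factor, hormone→latent slopes, the
    testosterone→estradiol slope, the LOQ, and testosterone moments are
    the published point estimates. Regional intercepts/loadings/residual
    scales and the covariate distributions are free choices (no regional
    values are published numerically); they give realistic positive
    BP_ND with the high/intermediate/low ordering.
    """
    return GeneratorParams(**overrides)


def _truncnorm(rng, mu, sd, lo, hi, size):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                               random_state=rng)


def _lognormal_from_moments(rng, mean, sd, size):
    """Lognormal draws matching a target mean and SD (keeps dose > 0)."""
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def generate_cohort(params: GeneratorParams, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort table from the generative model.

    Returns one row per subject with covariates, hormones (estradiol
    stored at the LOQ when censored, plus the uncensored value in
    ``estradiol_true`` for oracle checks), and the four regional BP_ND
    outcomes. HAMD item columns are created empty; fill them with
    :func:`generate_hamd`.
    """
    params.validate()
    if seed is None:
        seed = params.seed
    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(6)]
    rng_cov, rng_t, rng_e, rng_zeta, rng_eps, _ = streams

    n = params.n_mdd + params.n_hc
    g = np.concatenate([np.ones(params.n_mdd), np.zeros(params.n_hc)])  # 1=MDD

    age = np.where(
        g == 1,
        _truncnorm(rng_cov, params.age_mu_mdd, params.age_sd_mdd,
                   *params.age_range, size=n),
        _truncnorm(rng_cov, params.age_mu_hc, params.age_sd_hc,
                   *params.age_range, size=n),
    )
    dose = np.where(
        g == 1,
        _lognormal_from_moments(rng_cov, params.dose_mu_mdd,
                                params.dose_sd_mdd, n),
        _lognormal_from_moments(rng_cov, params.dose_mu_hc,
                                params.dose_sd_hc, n),
    )
    ge = (rng_cov.random(n) < params.ge_fraction_hc).astype(float)
    if not params.ge_allowed_mdd:
        ge[g == 1] = 0.0

    t = np.where(
        g == 1,
        rng_t.normal(params.mu_t_mdd, params.sigma_t_mdd, n),
        rng_t.normal(params.mu_t_hc, params.sigma_t_hc, n),
    )
    t = np.abs(t)  # testosterone is a concentration

    e_true = params.alpha_e + params.gamma3 * t + rng_e.normal(0.0, params.sigma_e, n)

    gamma1 = np.where(g == 1, params.gamma1_mdd, params.gamma1_hc)
    gamma2 = np.where(g == 1, params.gamma2_mdd, params.gamma2_hc)
    eta = (params.gamma_group * g + gamma1 * t + gamma2 * e_true
           + rng_zeta.normal(0.0, params.sigma_zeta, n))

    sig = np.asarray(params.sigma_region, dtype=float)
    cov_eps = np.diag(sig ** 2)
    cov_eps[1, 2] = cov_eps[2, 1] = params.cov_hipp_amyg
    eps = rng_eps.multivariate_normal(np.zeros(4), cov_eps, size=n,
                                      method="svd")

    lam = np.asarray(params.lam, dtype=float)
    nu = np.asarray(params.nu, dtype=float)
    betas = np.column_stack([params.beta_age, params.beta_dose,
                             params.beta_scanner])  # (4, 3)
    x = np.column_stack([age, dose, ge])  # (n, 3)
    y = nu[None, :] + np.outer(eta, lam) + x @ betas.T + eps

    censored = e_true <= params.loq
    e_obs = np.where(censored, params.loq, e_true)

    table = pd.DataFrame({
        "id": [f"S{i:04d}" for i in range(n)],
        "group": np.where(g == 1, GROUP_MDD, GROUP_HC),
        "age": age,
        "dose": dose,
        "scanner": np.where(ge == 1, SCANNER_GE, SCANNER_HRRT),
    })
    for j, col in enumerate(BP_COLUMNS):
        table[col] = y[:, j]
    table["testosterone"] = t
    table["estradiol"] = e_obs
    table["estradiol_censored"] = censored.astype(int)
    table["estradiol_true"] = e_true
    for col in HAMD_COLUMNS:
        table[col] = np.nan
    return table


def generate_hamd(params: GeneratorParams, cohort: pd.DataFrame,
                  seed: int | None = None) -> pd.DataFrame:
    """Fill HAMD-17 items for the MDD rows of a cohort.

    Vegetative items (initial/middle/delayed insomnia, gastrointestinal,
    weight loss) load on standardized testosterone with slope
    ``hamd_params.veg_loading``; core (HAMD6) and remaining items are
    hormone-independent. Each item is an ordinal score obtained by
    cutting a standard-normal latent variable at thresholds implied by
    the configured marginal level probabilities.
    """
    hp = params.hamd_params
    mdd_mask = (cohort["group"] == GROUP_MDD).to_numpy()
    if not mdd_mask.any():
        raise ValueError("cohort has no MDD subjects")
    if seed is None:
        seed = params.seed + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    out = cohort.copy()
    t = cohort.loc[mdd_mask, "testosterone"].to_numpy(dtype=float)
    t_sd = t.std(ddof=1) if len(t) > 1 and t.std(ddof=1) > 0 else 1.0
    z_t = (t - t.mean()) / t_sd
    n = mdd_mask.sum()

    for item in range(1, 18):
        vegetative = item in VEGETATIVE_ITEMS
        loading = hp.veg_loading if vegetative else 0.0
        latent = loading * z_t + rng.normal(0.0, 1.0, n)
        latent = latent / np.sqrt(loading ** 2 + 1.0)
        probs = hp.p_levels_04 if HAMD_ITEM_MAX[item] == 4 else hp.p_levels_02
        cuts = stats.norm.ppf(np.cumsum(probs[:-1]))
        score = np.searchsorted(cuts, latent)
        out.loc[mdd_mask, f"hamd_{item}"] = score.astype(float)
    return out
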