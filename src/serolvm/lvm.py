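"""Latent-variable models for regional PET binding.

Two models share one engine. The *group_only* model explains the four
regional BP_ND outcomes through a single global latent factor shifted by
diagnostic group; the *hormones* model adds plasma testosterone and
estradiol effects on the latent factor (with group interactions) and a
linear testosterone→estradiol submodel, and handles left-censoring of
estradiol at the assay LOQ by integrating the likelihood over estradiol
values below the limit.

Within each group the model is linear-Gaussian, so the joint
distribution of (regional outcomes, estradiol) given testosterone,
group, and covariates is multivariate normal and the censored-data
integral has a closed form: the marginal density of the outcomes times
the conditional-Gaussian probability that estradiol lies below the LOQ.

Structural equations (group coded 0 = HC, 1 = MDD)::

    E   = alpha_e + gamma3 * T + eps_E
    eta = gamma_group * G + (gamma1 + dgamma1 * G) * T
          + (gamma2 + dgamma2 * G) * E + zeta
    Y_r = nu_r + lambda_r * eta + beta_r' x + eps_r

with ``lambda_1 = 1`` fixed for identification (neostriatum), residuals
independent except for explicitly freed region-pair covariances.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular
from scipy.special import log_ndtr

from .cohort import COVARIATES, GROUP_MDD, REGIONS, SCANNER_GE

__all__ = [
    "LVMSpec",
    "FittedLVM",
    "build_lvm_spec",
    "model_moments",
    "log_likelihood",
    "fit_lvm",
    "residuals",
]

_LOG2PI = np.log(2.0 * np.pi)


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LVMSpec:
    """Symbolic definition of a latent-variable model.

    ``model`` selects the structural terms: ``group_only`` has the group
    effect alone; ``hormones`` adds testosterone and estradiol main and
    group-interaction effects plus the hormone submodel.
    ``censoring_mode`` controls the treatment of estradiol values below
    the LOQ: ``integrate_full`` integrates within each group (exact),
    ``integrate_main_only`` integrates through the main estradiol
    pathway with the interaction covariate plugged in at the LOQ (the
    simplification used when full integration is numerically fragile),
    ``plugin`` substitutes the LOQ as if observed, ``none`` requires
    uncensored data. ``normalization`` fixes either the first loading
    (``loading``) or the latent disturbance SD (``variance``).
    """

    model: str = "group_only"
    regions: tuple = REGIONS
    covariates: tuple = COVARIATES
    extra_covariances: tuple = ()
    censoring_mode: str = "none"
    loq: float = 0.09
    normalization: str = "loading"

    def __post_init__(self):
        if self.model not in ("group_only", "hormones"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.censoring_mode not in ("none", "integrate_full",
                                       "integrate_main_only", "plugin"):
            raise ValueError(f"unknown censoring mode {self.censoring_mode!r}")
        if self.normalization not in ("loading", "variance"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for a, b in self.extra_covariances:
            if a == b or a not in self.regions or b not in self.regions:
                raise ValueError(f"invalid covariance pair ({a}, {b})")
        if len(set(map(frozenset, self.extra_covariances))) != len(self.extra_covariances):
            raise ValueError("duplicate covariance pairs")

    @property
    def hormone_submodel(self) -> bool:
        return self.model == "hormones"

    def with_covariance(self, pair) -> "LVMSpec":
        """Spec with one more free residual covariance."""
        return LVMSpec(
            model=self.model, regions=self.regions, covariates=self.covariates,
            extra_covariances=self.extra_covariances + (tuple(pair),),
            censoring_mode=self.censoring_mode, loq=self.loq,
            normalization=self.normalization,
        )


def build_lvm_spec(model: str, *, covariates=COVARIATES, extra_covariances=(),
                   censoring_mode: str | None = None, loq: float = 0.09,
                   normalization: str = "loading") -> LVMSpec:
    """Construct the group-difference or hormone-mediation model spec.

    By default the extra hippocampus–amygdala covariance is off; the
    diagnostics refinement loop adds residual covariances when score
    tests demand them. The hormones model defaults to the
    ``integrate_main_only`` censoring treatment.
    """
    if model not in ("group_only", "hormones"):
        raise ValueError(f"unknown model {model!r}")
    if censoring_mode is None:
        censoring_mode = "integrate_main_only" if model == "hormones" else "none"
    return LVMSpec(model=model, covariates=tuple(covariates),
                   extra_covariances=tuple(tuple(p) for p in extra_covariances),
                   censoring_mode=censoring_mode, loq=loq,
                   normalization=normalization)


# --------------------------------------------------------------------------
# parameter layout
# --------------------------------------------------------------------------

class ParameterLayout:
    """Bijective map between named parameters and the internal vector.

    SD parameters live on the log scale internally so the optimizer is
    unconstrained; residual covariances and structural slopes are
    untransformed.
    """

    def __init__(self, spec: LVMSpec):
        self.spec = spec
        R = list(spec.regions)
        names: list[str] = []
        self.log_scale: list[bool] = []

        def add(name, log=False):
            names.append(name)
            self.log_scale.append(log)

        for r in R:
            add(f"nu_{r}")
        free_lam = R[1:] if spec.normalization == "loading" else R
        for r in free_lam:
            add(f"lambda_{r}")
        for r in R:
            for c in spec.covariates:
                add(f"beta_{r}_{c}")
        for r in R:
            add(f"sigma_{r}", log=True)
        for a, b in spec.extra_covariances:
            add(f"cov_{a}_{b}")
        if spec.normalization == "loading":
            add("sigma_zeta", log=True)
        add("gamma_group")
        if spec.hormone_submodel:
            for g in ("gamma1", "dgamma1", "gamma2", "dgamma2"):
                add(g)
            add("alpha_e")
            add("gamma3")
            add("sigma_e", log=True)

        self.names = names
        self.index = {n: i for i, n in enumerate(names)}
        self.k = len(names)
        self.log_scale = np.asarray(self.log_scale)

    def to_internal(self, named: dict) -> np.ndarray:
        z = np.empty(self.k)
        for n, i in self.index.items():
            v = float(named[n])
            z[i] = np.log(v) if self.log_scale[i] else v
        return z

    def to_named(self, z: np.ndarray) -> dict:
        out = {}
        for n, i in self.index.items():
            out[n] = float(np.exp(z[i])) if self.log_scale[i] else float(z[i])
        return out


@dataclass
class _Unpacked:
    """Natural-scale parameter arrays for fast likelihood evaluation."""
    nu: np.ndarray
    lam: np.ndarray
    beta: np.ndarray          # (4, n_cov)
    sigma_eps: np.ndarray     # (4, 4) residual covariance
    sigma_zeta: float
    gamma_group: float
    gamma1: float = 0.0
    dgamma1: float = 0.0
    gamma2: float = 0.0
    dgamma2: float = 0.0
    alpha_e: float = 0.0
    gamma3: float = 0.0
    sigma_e: float = 1.0


def _unpack(z: np.ndarray, layout: ParameterLayout) -> _Unpacked:
    spec = layout.spec
    R = list(spec.regions)
    idx = layout.index
    g = lambda n: z[idx[n]]
    nu = np.array([g(f"nu_{r}") for r in R])
    if spec.normalization == "loading":
        lam = np.array([1.0] + [g(f"lambda_{r}") for r in R[1:]])
        sigma_zeta = float(np.exp(min(g("sigma_zeta"), 150.0)))
    else:
        lam = np.array([g(f"lambda_{r}") for r in R])
        sigma_zeta = 1.0
    beta = np.array([[g(f"beta_{r}_{c}") for c in spec.covariates] for r in R])
    # cap log-SDs so wild optimizer excursions do not overflow squares
    sig = np.exp(np.minimum([g(f"sigma_{r}") for r in R], 150.0))
    sigma_eps = np.diag(sig ** 2)
    pos = {r: i for i, r in enumerate(R)}
    for a, b in spec.extra_covariances:
        val = g(f"cov_{a}_{b}")
        sigma_eps[pos[a], pos[b]] = sigma_eps[pos[b], pos[a]] = val
    p = _Unpacked(nu=nu, lam=lam, beta=beta, sigma_eps=sigma_eps,
                  sigma_zeta=sigma_zeta, gamma_group=float(g("gamma_group")))
    if spec.hormone_submodel:
        p.gamma1 = float(g("gamma1"))
        p.dgamma1 = float(g("dgamma1"))
        p.gamma2 = float(g("gamma2"))
        p.dgamma2 = float(g("dgamma2"))
        p.alpha_e = float(g("alpha_e"))
        p.gamma3 = float(g("gamma3"))
        p.sigma_e = float(np.exp(g("sigma_e")))
    return p


# --------------------------------------------------------------------------
# data preparation
# --------------------------------------------------------------------------

@dataclass
class _Stratum:
    """Rows sharing one implied covariance: same group and censor state."""
    g: float
    censored: bool
    y: np.ndarray
    x: np.ndarray
    t: np.ndarray | None
    e: np.ndarray | None


@dataclass
class PreparedData:
    y: np.ndarray             # (n, 4)
    x: np.ndarray             # (n, n_cov)
    group: np.ndarray         # (n,) 0/1
    t: np.ndarray | None
    e: np.ndarray | None
    censored: np.ndarray | None
    n_dropped: int
    index: np.ndarray         # original row positions kept
    strata: list = None       # precomputed _Stratum slices


def prepare_data(spec: LVMSpec, table: pd.DataFrame) -> PreparedData:
    """Extract model arrays from a cohort table with listwise deletion."""
    cols = [f"bp_{r}" for r in spec.regions] + ["group"] + list(spec.covariates)
    if spec.hormone_submodel:
        cols += ["testosterone", "estradiol", "estradiol_censored"]
    df = table.copy()
    if "scanner" in spec.covariates:
        df["scanner"] = (df["scanner"] == SCANNER_GE).astype(float) \
            if df["scanner"].dtype == object else df["scanner"].astype(float)
    keep = df[cols].notna().all(axis=1)
    n_dropped = int((~keep).sum())
    df = df.loc[keep]
    y = df[[f"bp_{r}" for r in spec.regions]].to_numpy(dtype=float)
    x = df[list(spec.covariates)].to_numpy(dtype=float) if spec.covariates \
        else np.zeros((len(df), 0))
    grp = (df["group"] == GROUP_MDD).astype(float).to_numpy()
    t = e = cens = None
    if spec.hormone_submodel:
        t = df["testosterone"].to_numpy(dtype=float)
        e = df["estradiol"].to_numpy(dtype=float)
        cens = df["estradiol_censored"].to_numpy(dtype=float).astype(bool)
        if spec.censoring_mode == "none" and cens.any():
            raise ValueError("censored rows present but censoring_mode='none'")
    dat = PreparedData(y=y, x=x, group=grp, t=t, e=e, censored=cens,
                       n_dropped=n_dropped, index=np.flatnonzero(keep.to_numpy()))
    strata = []
    if spec.hormone_submodel:
        # stored estradiol equals the LOQ on censored rows, which is
        # exactly the plug-in convention
        treat_cens = cens if spec.censoring_mode != "plugin" \
            else np.zeros_like(cens)
        for g in (0.0, 1.0):
            for c in (False, True):
                m = (grp == g) & (treat_cens == c)
                if m.any():
                    strata.append(_Stratum(g=g, censored=c, y=y[m], x=x[m],
                                           t=t[m], e=e[m]))
    else:
        strata.append(_Stratum(g=np.nan, censored=False, y=y, x=x,
                               t=None, e=None))
    dat.strata = strata
    return dat


# --------------------------------------------------------------------------
# implied moments and log-likelihood
# --------------------------------------------------------------------------

def _implied_cov(p: _Unpacked, spec: LVMSpec, group: float, *,
                 main_only_censored: bool = False):
    """Implied covariance of the observable vector given (T, G, x).

    Returns (cov_yy, cov_ye, var_e) — the latter two are None for the
    group-only model. ``main_only_censored`` switches the estradiol
    slope entering the latent factor to the main effect only (the
    interaction pathway is then a fixed plug-in offset in the mean).
    """
    if not spec.hormone_submodel:
        var_eta = p.sigma_zeta ** 2
        return np.outer(p.lam, p.lam) * var_eta + p.sigma_eps, None, None
    a2 = p.gamma2 if main_only_censored else p.gamma2 + p.dgamma2 * group
    var_e = p.sigma_e ** 2
    var_eta = a2 ** 2 * var_e + p.sigma_zeta ** 2
    cov_yy = np.outer(p.lam, p.lam) * var_eta + p.sigma_eps
    cov_ye = p.lam * a2 * var_e
    return cov_yy, cov_ye, var_e


def model_moments(theta: dict, spec: LVMSpec, covariate_row, group,
                  testosterone: float | None = None):
    """Implied joint Gaussian moments of the observables for one subject.

    For the hormones model the observable vector is (Y_1..Y_4, E) given
    testosterone, group, and covariates; for the group-only model it is
    (Y_1..Y_4) given group and covariates. Raises if the implied
    covariance is not positive definite.
    """
    layout = ParameterLayout(spec)
    p = _unpack(layout.to_internal(theta), layout)
    x = np.asarray(covariate_row, dtype=float)
    g = float(group)
    xb = p.beta @ x if x.size else np.zeros(len(spec.regions))
    if spec.hormone_submodel:
        if testosterone is None:
            raise ValueError("hormones model requires testosterone")
        a1 = p.gamma1 + p.dgamma1 * g
        a2 = p.gamma2 + p.dgamma2 * g
        mu_e = p.alpha_e + p.gamma3 * float(testosterone)
        mu_eta = p.gamma_group * g + a1 * float(testosterone) + a2 * mu_e
        cov_yy, cov_ye, var_e = _implied_cov(p, spec, g)
        mean = np.concatenate([p.nu + p.lam * mu_eta + xb, [mu_e]])
        cov = np.block([[cov_yy, cov_ye[:, None]],
                        [cov_ye[None, :], np.array([[var_e]])]])
    else:
        mu_eta = p.gamma_group * g
        cov_yy, _, _ = _implied_cov(p, spec, g)
        mean = p.nu + p.lam * mu_eta + xb
        cov = cov_yy
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError("implied covariance is not positive definite")
    return mean, cov


def _gauss_logpdf_rows(resid: np.ndarray, cov: np.ndarray):
    """Row-wise multivariate normal log-density; also returns the
    Cholesky factor for reuse."""
    L = np.linalg.cholesky(cov)
    sol = solve_triangular(L, resid.T, lower=True, check_finite=False)
    quad = np.sum(sol ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    d = cov.shape[0]
    return -0.5 * (d * _LOG2PI + logdet + quad), L


def _loglik_from_unpacked(p: _Unpacked, spec: LVMSpec, dat: PreparedData) -> float:
    total = 0.0
    try:
        if not spec.hormone_submodel:
            xb = dat.x @ p.beta.T if dat.x.shape[1] else 0.0
            mu_y = p.nu[None, :] + np.outer(p.gamma_group * dat.group, p.lam) + xb
            cov_yy, _, _ = _implied_cov(p, spec, 0.0)
            ll, _ = _gauss_logpdf_rows(dat.y - mu_y, cov_yy)
            return float(np.sum(ll))

        main_only = spec.censoring_mode == "integrate_main_only"
        for s in dat.strata:
            g = s.g
            a1 = p.gamma1 + p.dgamma1 * g
            a2 = p.gamma2 + p.dgamma2 * g
            mu_e = p.alpha_e + p.gamma3 * s.t
            xb = s.x @ p.beta.T if s.x.shape[1] else 0.0
            if not s.censored:
                # joint Gaussian density of (Y, E) given (T, G, x)
                mu_eta = p.gamma_group * g + a1 * s.t + a2 * mu_e
                cov_yy, cov_ye, var_e = _implied_cov(p, spec, g)
                d = cov_yy.shape[0] + 1
                cov = np.empty((d, d))
                cov[:-1, :-1] = cov_yy
                cov[:-1, -1] = cov[-1, :-1] = cov_ye
                cov[-1, -1] = var_e
                mu_y = p.nu[None, :] + np.outer(mu_eta, p.lam) + xb
                resid = np.column_stack([s.y - mu_y, s.e - mu_e])
                ll, _ = _gauss_logpdf_rows(resid, cov)
                total += float(np.sum(ll))
            else:
                a2c = p.gamma2 if main_only else a2
                mu_eta = p.gamma_group * g + a1 * s.t + a2c * mu_e
                if main_only:
                    # interaction pathway plugged in at the LOQ
                    mu_eta = mu_eta + p.dgamma2 * g * spec.loq
                cov_yy, cov_ye, var_e = _implied_cov(
                    p, spec, g, main_only_censored=main_only)
                mu_y = p.nu[None, :] + np.outer(mu_eta, p.lam) + xb
                resid = s.y - mu_y
                ll_y, _ = _gauss_logpdf_rows(resid, cov_yy)
                # conditional E | Y is Gaussian: integrate up to the LOQ
                w = np.linalg.solve(cov_yy, cov_ye)
                var_e_y = var_e - cov_ye @ w
                if var_e_y <= 0:
                    return -np.inf
                zc = (spec.loq - mu_e - resid @ w) / np.sqrt(var_e_y)
                total += float(np.sum(ll_y) + np.sum(log_ndtr(zc)))
        return total
    except np.linalg.LinAlgError:
        return -np.inf


def _strata_moments(p: _Unpacked, spec: LVMSpec, dat: PreparedData):
    """Implied Gaussian moments per stratum: list of (mean matrix, cov).

    Uncensored strata use the joint (Y, E) moments; censored strata
    contribute their marginal-Y Gaussian block (the probability mass
    below the LOQ carries little additional curvature information).
    Used by the expected-information assembly in the diagnostics.
    """
    out = []
    if not spec.hormone_submodel:
        xb = dat.x @ p.beta.T if dat.x.shape[1] else 0.0
        mu = p.nu[None, :] + np.outer(p.gamma_group * dat.group, p.lam) + xb
        cov, _, _ = _implied_cov(p, spec, 0.0)
        return [(mu, cov)]
    main_only = spec.censoring_mode == "integrate_main_only"
    for s in dat.strata:
        g = s.g
        a1 = p.gamma1 + p.dgamma1 * g
        a2 = p.gamma2 + p.dgamma2 * g
        mu_e = p.alpha_e + p.gamma3 * s.t
        xb = s.x @ p.beta.T if s.x.shape[1] else 0.0
        if not s.censored:
            mu_eta = p.gamma_group * g + a1 * s.t + a2 * mu_e
            cov_yy, cov_ye, var_e = _implied_cov(p, spec, g)
            d = cov_yy.shape[0] + 1
            cov = np.empty((d, d))
            cov[:-1, :-1] = cov_yy
            cov[:-1, -1] = cov[-1, :-1] = cov_ye
            cov[-1, -1] = var_e
            mu_y = p.nu[None, :] + np.outer(mu_eta, p.lam) + xb
            out.append((np.column_stack([mu_y, mu_e]), cov))
        else:
            a2c = p.gamma2 if main_only else a2
            mu_eta = p.gamma_group * g + a1 * s.t + a2c * mu_e
            if main_only:
                mu_eta = mu_eta + p.dgamma2 * g * spec.loq
            cov_yy, _, _ = _implied_cov(p, spec, g,
                                        main_only_censored=main_only)
            mu_y = p.nu[None, :] + np.outer(mu_eta, p.lam) + xb
            out.append((mu_y, cov_yy))
    return out


def log_likelihood(theta, spec: LVMSpec, data) -> float:
    """Model log-likelihood at named parameters ``theta`` on a cohort.

    ``theta`` is a dict of named natural-scale parameters; ``data`` is a
    cohort table (DataFrame) or an already-prepared :class:`PreparedData`.
    For censored estradiol rows the likelihood contribution is the
    closed-form integral of the joint Gaussian density over estradiol
    values below the LOQ.
    """
    layout = ParameterLayout(spec)
    dat = data if isinstance(data, PreparedData) else prepare_data(spec, data)
    p = _unpack(layout.to_internal(theta), layout)
    return _loglik_from_unpacked(p, spec, dat)


def _loglik_internal(z: np.ndarray, layout: ParameterLayout,
                     dat: PreparedData) -> float:
    return _loglik_from_unpacked(_unpack(z, layout), layout.spec, dat)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class FittedLVM:
    """Maximum-likelihood fit of an LVM.

    ``vcov`` is the inverse observed information over the internal free
    parameters (SDs on the log scale); ``estimates`` are natural-scale
    point estimates with delta-method SEs for the SD parameters.
    """

    spec: LVMSpec
    layout: ParameterLayout
    theta_internal: np.ndarray
    vcov: np.ndarray | None
    loglik: float
    n_obs: int
    n_dropped: int
    converged: bool
    n_iter: int
    message: str
    fit_seconds: float

    @property
    def names(self):
        return self.layout.names

    def _require_converged(self):
        if not self.converged:
            raise RuntimeError(
                f"fit did not converge ({self.message}); estimates withheld")

    @property
    def estimates(self) -> dict:
        self._require_converged()
        return self.layout.to_named(self.theta_internal)

    @property
    def se(self) -> dict:
        """Natural-scale standard errors (delta method for SD params)."""
        self._require_converged()
        if self.vcov is None:
            return {n: np.nan for n in self.names}
        se_int = np.sqrt(np.maximum(np.diag(self.vcov), 0.0))
        est = self.estimates
        out = {}
        for n, i in self.layout.index.items():
            out[n] = se_int[i] * (est[n] if self.layout.log_scale[i] else 1.0)
        return out

    def structural_vcov(self, names) -> np.ndarray:
        """Joint covariance of untransformed parameters by name."""
        self._require_converged()
        if self.vcov is None:
            raise RuntimeError("SEs unavailable (singular information)")
        idx = [self.layout.index[n] for n in names]
        for n in names:
            if self.layout.log_scale[self.layout.index[n]]:
                raise ValueError(f"{n} is log-scale internally")
        return self.vcov[np.ix_(idx, idx)]

    def params_table(self) -> pd.DataFrame:
        """Flat table of estimates, SEs, Wald CIs and p-values."""
        est, se = self.estimates, self.se
        rows = []
        for n in self.names:
            s = se[n]
            z = est[n] / s if s and np.isfinite(s) and s > 0 else np.nan
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            rows.append({
                "parameter": n, "estimate": est[n], "se": s,
                "ci_low": est[n] - 1.96 * s, "ci_high": est[n] + 1.96 * s,
                "p": p,
            })
        return pd.DataFrame(rows)


def _starting_values(spec: LVMSpec, dat: PreparedData,
                     layout: ParameterLayout) -> np.ndarray:
    """Moment-based starts: per-region least squares plus factor-analytic
    loading ratios from the OLS residual covariance."""
    n = dat.y.shape[0]
    cols = [np.ones(n)]
    if dat.x.shape[1]:
        cols.append(dat.x)
    cols.append(dat.group[:, None])
    if spec.hormone_submodel:
        e_fill = np.where(dat.censored, spec.loq, dat.e)
        cols += [dat.t[:, None], (dat.t * dat.group)[:, None],
                 e_fill[:, None], (e_fill * dat.group)[:, None]]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, dat.y, rcond=None)
    fitted = X @ coef
    res = dat.y - fitted
    C = np.cov(res.T)

    # factor starts: lambda_1 = 1; latent variance from a covariance triple
    n_reg = len(spec.regions)
    var_eta = np.nan
    if n_reg >= 3 and abs(C[1, 2]) > 1e-12:
        with np.errstate(divide="ignore", invalid="ignore"):
            var_eta = C[0, 1] * C[0, 2] / C[1, 2]
    if not np.isfinite(var_eta) or var_eta <= 0 or var_eta >= C[0, 0]:
        var_eta = 0.5 * C[0, 0]
    lam = np.ones(n_reg)
    lam[1:] = C[0, 1:] / var_eta
    sig2 = np.maximum(np.diag(C) - lam ** 2 * var_eta, 0.05 * np.diag(C))

    named: dict = {}
    k_cov = dat.x.shape[1]
    for j, r in enumerate(spec.regions):
        named[f"nu_{r}"] = coef[0, j]
        for c_i, c in enumerate(spec.covariates):
            named[f"beta_{r}_{c}"] = coef[1 + c_i, j]
        named[f"sigma_{r}"] = max(np.sqrt(sig2[j]), 1e-3)
    if spec.normalization == "loading":
        for j, r in enumerate(spec.regions):
            if j:
                named[f"lambda_{r}"] = lam[j]
        named["sigma_zeta"] = max(np.sqrt(var_eta), 1e-3)
    else:
        s = max(np.sqrt(var_eta), 1e-3)
        for j, r in enumerate(spec.regions):
            named[f"lambda_{r}"] = lam[j] * s
    for a, b in spec.extra_covariances:
        named[f"cov_{a}_{b}"] = 0.0

    ig = 1 + k_cov  # column index of group in X
    named["gamma_group"] = coef[ig, 0]
    if spec.hormone_submodel:
        named["gamma1"] = coef[ig + 1, 0]
        named["dgamma1"] = coef[ig + 2, 0]
        named["gamma2"] = coef[ig + 3, 0]
        named["dgamma2"] = coef[ig + 4, 0]
        # hormone submodel from uncensored estradiol least squares
        unc = ~dat.censored
        if unc.sum() >= 3:
            A = np.column_stack([np.ones(unc.sum()), dat.t[unc]])
            ce, *_ = np.linalg.lstsq(A, dat.e[unc], rcond=None)
            resid_e = dat.e[unc] - A @ ce
            named["alpha_e"] = ce[0]
            named["gamma3"] = ce[1]
            named["sigma_e"] = max(resid_e.std(ddof=2), 1e-3)
        else:
            named["alpha_e"] = float(np.mean(dat.e))
            named["gamma3"] = 0.0
            named["sigma_e"] = max(float(np.std(dat.e)), 1e-3)
    return layout.to_internal(named)


def _numerical_hessian(fun, z0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian, symmetric by construction."""
    k = z0.size
    h = rel_step * np.maximum(np.abs(z0), 1.0)
    H = np.empty((k, k))
    f0 = fun(z0)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        zp, zm = z0.copy(), z0.copy()
        zp[i] += h[i]
        zm[i] -= h[i]
        fp[i] = fun(zp)
        fm[i] = fun(zm)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(k):
        for j in range(i + 1, k):
            zpp = z0.copy()
            zpp[[i, j]] += [h[i], h[j]]
            zmm = z0.copy()
            zmm[[i, j]] -= [h[i], h[j]]
            H[i, j] = H[j, i] = (
                (fun(zpp) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fun(zmm))
                / (2 * h[i] * h[j])
            )
    return H


def fit_lvm(spec: LVMSpec, data, *, start: dict | None = None,
            compute_vcov: bool = True, maxiter: int = 500,
            gtol: float = 1e-5) -> FittedLVM:
    """Fit an LVM by quasi-Newton maximum likelihood.

    Starting values come from per-region least squares and moment-based
    loading ratios unless supplied. Standard errors are taken from the
    inverse observed information (numerical Hessian at the optimum); a
    singular Hessian leaves SEs unavailable rather than failing the fit.
    """
    t0 = time.perf_counter()
    layout = ParameterLayout(spec)
    dat = data if isinstance(data, PreparedData) else prepare_data(spec, data)
    if dat.y.shape[0] < layout.k:
        raise ValueError(
            f"{dat.y.shape[0]} usable rows for {layout.k} parameters")
    z0 = layout.to_internal(start) if start is not None \
        else _starting_values(spec, dat, layout)

    def nll(z):
        v = _loglik_internal(z, layout, dat)
        return 1e12 if not np.isfinite(v) else -v

    # diagonal curvature preconditions the quasi-Newton search; without
    # it the mixed parameter scales stall convergence. The preconditioner
    # is recomputed and the search restarted until the optimizer reports
    # convergence (the start can sit in a region of negative curvature).
    k = layout.k

    def precondition(z):
        h = 1e-4 * np.maximum(np.abs(z), 1.0)
        f0 = nll(z)
        diag = np.empty(k)
        for i in range(k):
            zp, zm = z.copy(), z.copy()
            zp[i] += h[i]
            zm[i] -= h[i]
            diag[i] = (nll(zp) - 2.0 * f0 + nll(zm)) / h[i] ** 2
        return 1.0 / np.sqrt(np.clip(diag, 1e-2, None))

    z_cur = z0
    res = None
    n_iter = 0
    for _ in range(3):
        scale = precondition(z_cur)
        res = optimize.minimize(lambda s: nll(z_cur + scale * s), np.zeros(k),
                                method="L-BFGS-B", jac="2-point",
                                options={"maxiter": maxiter, "gtol": gtol,
                                         "ftol": 1e-12, "maxcor": 30,
                                         "maxfun": 200000})
        n_iter += int(res.nit)
        z_cur = z_cur + scale * res.x
        if res.success:
            break
    res.x = z_cur
    res.nit = n_iter
    ll = -res.fun
    converged = bool(res.success) and np.isfinite(ll)

    vcov = None
    if converged and compute_vcov:
        H = _numerical_hessian(lambda z: -_loglik_internal(z, layout, dat),
                               res.x)
        try:
            # observed information; require positive-definiteness
            np.linalg.cholesky(H)
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = None

    return FittedLVM(
        spec=spec, layout=layout, theta_internal=res.x, vcov=vcov,
        loglik=float(ll), n_obs=dat.y.shape[0], n_dropped=dat.n_dropped,
        converged=converged, n_iter=int(res.nit), message=str(res.message),
        fit_seconds=time.perf_counter() - t0,
    )


def residuals(fit: FittedLVM, data) -> pd.DataFrame:
    """Standardized regional residuals given structural predictors.

    Each residual is ``Y_r − E[Y_r | covariates, group, hormones]``
    divided by the implied conditional SD ``sqrt(lambda_r² sigma_zeta² +
    sigma_r²)``. Censored estradiol enters at the LOQ.
    """
    fit._require_converged()
    spec = fit.spec
    dat = data if isinstance(data, PreparedData) else prepare_data(spec, data)
    p = _unpack(fit.theta_internal, fit.layout)
    xb = dat.x @ p.beta.T if dat.x.shape[1] else 0.0
    if spec.hormone_submodel:
        e_fill = np.where(dat.censored, spec.loq, dat.e)
        a1 = p.gamma1 + p.dgamma1 * dat.group
        a2 = p.gamma2 + p.dgamma2 * dat.group
        mu_eta = p.gamma_group * dat.group + a1 * dat.t + a2 * e_fill
    else:
        mu_eta = p.gamma_group * dat.group
    mu_y = p.nu[None, :] + np.outer(mu_eta, p.lam) + xb
    sd = np.sqrt(p.lam ** 2 * p.sigma_zeta ** 2 + np.diag(p.sigma_eps))
    resid = (dat.y - mu_y) / sd[None, :]
    return pd.DataFrame(resid, columns=list(spec.regions))
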