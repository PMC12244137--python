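"""LVM engine: implied moments, censored likelihood, fitting, residuals."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, stats

from conftest import truth_named
from serolvm.lvm import (
    LVMSpec,
    ParameterLayout,
    build_lvm_spec,
    fit_lvm,
    log_likelihood,
    model_moments,
    prepare_data,
    residuals,
)
from serolvm.synthetic import default_params, generate_cohort


class TestSpecConstruction:
    def test_group_only_shape(self):
        spec = build_lvm_spec("group_only")
        assert len(spec.regions) == 4
        assert spec.model == "group_only"
        assert spec.extra_covariances == ()
        assert ParameterLayout(spec).k == 4 + 3 + 12 + 4 + 1 + 1

    def test_hormones_has_interaction_terms_and_submodel(self):
        spec = build_lvm_spec("hormones")
        layout = ParameterLayout(spec)
        for name in ("gamma1", "dgamma1", "gamma2", "dgamma2",
                     "alpha_e", "gamma3", "sigma_e"):
            assert name in layout.index
        assert spec.censoring_mode == "integrate_main_only"

    def test_extra_covariance_registered_once(self):
        spec = build_lvm_spec(
            "hormones", extra_covariances=[("hippocampus", "amygdala")])
        assert spec.extra_covariances == (("hippocampus", "amygdala"),)
        assert "cov_hippocampus_amygdala" in ParameterLayout(spec).index
        with pytest.raises(ValueError):
            spec.with_covariance(("amygdala", "hippocampus"))

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            build_lvm_spec("bifactor")


def _plain_theta(spec, **overrides):
    """Simple valid parameter dict for moment identities."""
    d = {}
    for j, r in enumerate(spec.regions):
        d[f"nu_{r}"] = 0.0
        if j:
            d[f"lambda_{r}"] = 1.0
        for c in spec.covariates:
            d[f"beta_{r}_{c}"] = 0.0
        d[f"sigma_{r}"] = 1.0
    for a, b in spec.extra_covariances:
        d[f"cov_{a}_{b}"] = 0.0
    d["sigma_zeta"] = 1.0
    d["gamma_group"] = 0.0
    if spec.model == "hormones":
        d.update(gamma1=0.0, dgamma1=0.0, gamma2=0.0, dgamma2=0.0,
                 alpha_e=0.0, gamma3=0.0, sigma_e=1.0)
    d.update(overrides)
    return d


class TestModelMoments:
    def test_unit_factor_model_gives_ones_plus_identity(self):
        spec = LVMSpec(model="group_only", covariates=())
        mean, cov = model_moments(_plain_theta(spec), spec,
                                  covariate_row=[], group=0)
        np.testing.assert_allclose(cov, np.ones((4, 4)) + np.eye(4),
                                   atol=1e-12)
        np.testing.assert_allclose(mean, 0.0, atol=1e-12)

    def test_extra_covariance_enters_off_diagonal(self):
        spec = LVMSpec(model="group_only", covariates=(),
                       extra_covariances=(("hippocampus", "amygdala"),))
        th = _plain_theta(spec, **{"cov_hippocampus_amygdala": 0.25,
                                   "lambda_hippocampus": 0.5,
                                   "lambda_amygdala": 0.4,
                                   "sigma_zeta": 2.0})
        _, cov = model_moments(th, spec, covariate_row=[], group=0)
        assert cov[1, 2] == pytest.approx(0.5 * 0.4 * 4.0 + 0.25, abs=1e-12)

    def test_moments_match_monte_carlo_oracle(self):
        spec = LVMSpec(model="hormones", covariates=("age",),
                       extra_covariances=(("hippocampus", "amygdala"),),
                       censoring_mode="integrate_full")
        rng = np.random.default_rng(5)
        th = _plain_theta(spec)
        th.update({
            "nu_neostriatum": 3.0, "nu_hippocampus": 1.0,
            "nu_amygdala": 0.9, "nu_prefrontal": 0.6,
            "lambda_hippocampus": 0.5, "lambda_amygdala": 0.4,
            "lambda_prefrontal": 0.3, "sigma_zeta": 0.2,
            "beta_neostriatum_age": -0.01, "beta_hippocampus_age": -0.005,
            "beta_amygdala_age": -0.004, "beta_prefrontal_age": -0.002,
            "sigma_neostriatum": 0.3, "sigma_hippocampus": 0.15,
            "sigma_amygdala": 0.15, "sigma_prefrontal": 0.1,
            "cov_hippocampus_amygdala": 0.01,
            "gamma_group": -0.1, "gamma1": -0.01, "dgamma1": 0.008,
            "gamma2": 1.5, "dgamma2": -1.0,
            "alpha_e": 0.05, "gamma3": 0.003, "sigma_e": 0.03,
        })
        t_val, age, group = 17.0, 30.0, 1.0
        mean, cov = model_moments(th, spec, covariate_row=[age], group=group,
                                  testosterone=t_val)

        n = 1_000_000
        e = th["alpha_e"] + th["gamma3"] * t_val + rng.normal(0, th["sigma_e"], n)
        a1 = th["gamma1"] + th["dgamma1"] * group
        a2 = th["gamma2"] + th["dgamma2"] * group
        eta = (th["gamma_group"] * group + a1 * t_val + a2 * e
               + rng.normal(0, th["sigma_zeta"], n))
        sig = np.array([th[f"sigma_{r}"] for r in spec.regions])
        cov_eps = np.diag(sig ** 2)
        cov_eps[1, 2] = cov_eps[2, 1] = th["cov_hippocampus_amygdala"]
        eps = rng.multivariate_normal(np.zeros(4), cov_eps, size=n)
        lam = np.array([1.0, th["lambda_hippocampus"], th["lambda_amygdala"],
                        th["lambda_prefrontal"]])
        nu = np.array([th[f"nu_{r}"] for r in spec.regions])
        beta = np.array([th[f"beta_{r}_age"] for r in spec.regions])
        y = nu + np.outer(eta, lam) + beta * age + eps
        z = np.column_stack([y, e])

        emp_mean = z.mean(axis=0)
        emp_cov = np.cov(z.T)
        se_mean = z.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(emp_mean - mean) < 3 * se_mean)
        se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov))
                          + cov ** 2) / n)
        assert np.all(np.abs(emp_cov - cov) < 3.5 * se_cov)

    def test_nonpositive_definite_reported(self):
        spec = LVMSpec(model="group_only", covariates=(),
                       extra_covariances=(("hippocampus", "amygdala"),))
        th = _plain_theta(spec, **{"cov_hippocampus_amygdala": -5.0})
        with pytest.raises(ValueError, match="positive definite"):
            model_moments(th, spec, covariate_row=[], group=0)


@pytest.fixture(scope="module")
def hormone_setup():
    p = default_params(n_mdd=150, n_hc=150)
    tab = generate_cohort(p, seed=31)
    spec = build_lvm_spec("hormones", censoring_mode="integrate_full")
    theta = truth_named(spec, p)
    return p, tab, spec, theta


class TestCensoredLikelihood:
    def test_modes_agree_without_censoring(self, hormone_setup):
        p, tab, _, theta = hormone_setup
        unc = tab[tab["estradiol_censored"] == 0]
        vals = [log_likelihood(theta, build_lvm_spec("hormones",
                                                     censoring_mode=m), unc)
                for m in ("integrate_full", "integrate_main_only", "plugin")]
        assert max(vals) - min(vals) < 1e-10

    @pytest.mark.parametrize("mode", ["integrate_full", "integrate_main_only"])
    def test_closed_form_matches_quadrature(self, hormone_setup, mode):
        """One censored subject: the closed form equals numerical
        integration of the joint density over estradiol below the LOQ."""
        p, tab, _, theta = hormone_setup
        spec = build_lvm_spec("hormones", censoring_mode=mode)
        row = tab[(tab["estradiol_censored"] == 1)
                  & (tab["group"] == "MDD")].iloc[[0]]
        closed = log_likelihood(theta, spec, row)

        r = row.iloc[0]
        x = np.array([r["age"], r["dose"], 1.0 if r["scanner"] == "GE" else 0.0])
        y = np.array([r[f"bp_{reg}"] for reg in spec.regions])
        t_val, g = r["testosterone"], 1.0
        lam = np.array([1.0] + [theta[f"lambda_{reg}"]
                                for reg in spec.regions[1:]])
        nu = np.array([theta[f"nu_{reg}"] for reg in spec.regions])
        beta = np.array([[theta[f"beta_{reg}_{c}"] for c in spec.covariates]
                         for reg in spec.regions])
        sig = np.array([theta[f"sigma_{reg}"] for reg in spec.regions])
        cov_eps = np.diag(sig ** 2)
        a1 = theta["gamma1"] + theta["dgamma1"] * g
        mu_e = theta["alpha_e"] + theta["gamma3"] * t_val

        def density(e):
            if mode == "integrate_full":
                a2e = theta["gamma2"] + theta["dgamma2"] * g
                off = 0.0
            else:
                a2e = theta["gamma2"]
                off = theta["dgamma2"] * g * spec.loq
            mu_eta = theta["gamma_group"] * g + a1 * t_val + a2e * e + off
            mu_y = nu + lam * mu_eta + beta @ x
            cov_y = np.outer(lam, lam) * theta["sigma_zeta"] ** 2 + cov_eps
            return (stats.multivariate_normal.pdf(y, mu_y, cov_y)
                    * stats.norm.pdf(e, mu_e, theta["sigma_e"]))

        val, _ = integrate.quad(density, -1.0, spec.loq,
                                epsabs=1e-14, limit=200)
        assert closed == pytest.approx(np.log(val), abs=1e-8)

    def test_loq_to_infinity_recovers_marginal_density(self, hormone_setup):
        p, tab, _, theta = hormone_setup
        row = tab[tab["estradiol_censored"] == 1].iloc[[0]]
        spec_inf = build_lvm_spec("hormones", censoring_mode="integrate_full",
                                  loq=1e9)
        ll = log_likelihood(theta, spec_inf, row)
        r = row.iloc[0]
        mean, cov = model_moments(
            theta, spec_inf,
            covariate_row=[r["age"], r["dose"],
                           1.0 if r["scanner"] == "GE" else 0.0],
            group=1.0 if r["group"] == "MDD" else 0.0,
            testosterone=r["testosterone"])
        y = np.array([r[f"bp_{reg}"] for reg in spec_inf.regions])
        marginal = stats.multivariate_normal.logpdf(y, mean[:4], cov[:4, :4])
        assert ll == pytest.approx(marginal, abs=1e-10)

    def test_censoring_mode_none_rejects_censored_rows(self, hormone_setup):
        _, tab, _, _ = hormone_setup
        spec = build_lvm_spec("hormones", censoring_mode="none")
        with pytest.raises(ValueError, match="censor"):
            prepare_data(spec, tab)


class TestFit:
    def test_fitted_loglik_beats_generating_theta(self, hormone_setup):
        p, tab, spec, theta = hormone_setup
        fit = fit_lvm(spec, tab, compute_vcov=False)
        assert fit.converged
        assert fit.loglik >= log_likelihood(theta, spec, tab) - 1e-6

    def test_single_replicate_recovery_within_4_se(self, hormones_fit,
                                                   medium_params):
        est, se = hormones_fit.estimates, hormones_fit.se
        p = medium_params
        truth = {"gamma_group": p.gamma_group, "gamma1": p.gamma1_hc,
                 "gamma2": p.gamma2_hc, "gamma3": p.gamma3,
                 "alpha_e": p.alpha_e}
        for k, v in truth.items():
            assert abs(est[k] - v) < 4 * se[k], k

    def test_brute_force_optimizer_agrees_on_toy_model(self):
        """Independent derivative-free maximization reaches the same
        maximized likelihood on a 2-region model without covariates."""
        rng = np.random.default_rng(11)
        n = 400
        eta = rng.normal(0, 0.5, n) - 0.2 * (np.arange(n) < n // 2)
        g = (np.arange(n) < n // 2).astype(float)
        tab = pd.DataFrame({
            "group": np.where(g == 1, "MDD", "HC"),
            "bp_a": 1.0 + eta + rng.normal(0, 0.3, n),
            "bp_b": 0.5 + 0.6 * eta + rng.normal(0, 0.2, n),
        })
        spec = LVMSpec(model="group_only", regions=("a", "b"), covariates=())
        fit = fit_lvm(spec, tab, compute_vcov=False)
        assert fit.converged

        layout = ParameterLayout(spec)
        dat = prepare_data(spec, tab)
        from serolvm.lvm import _loglik_internal

        def neg(z):
            v = _loglik_internal(z, layout, dat)
            return 1e12 if not np.isfinite(v) else -v

        best = np.inf
        for i in range(8):
            z0 = fit.theta_internal + rng.normal(0, 0.3, layout.k) * (i > 0)
            res = optimize.minimize(neg, z0, method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-12,
                                             "maxiter": 20000,
                                             "maxfev": 20000})
            best = min(best, res.fun)
        assert fit.loglik == pytest.approx(-best, abs=1e-6)

    def test_normalization_choices_give_identical_moments(self):
        """Fixing the first loading vs fixing the latent SD is a pure
        reparameterization: the analytic map between the two leaves the
        implied moments unchanged, and both optimizers reach the same
        maximized likelihood."""
        p = default_params(n_mdd=200, n_hc=200)
        tab = generate_cohort(p, seed=37)
        spec_l = build_lvm_spec("group_only", normalization="loading")
        spec_v = build_lvm_spec("group_only", normalization="variance")
        fit_l = fit_lvm(spec_l, tab, compute_vcov=False)
        fit_v = fit_lvm(spec_v, tab, compute_vcov=False)
        assert fit_l.converged and fit_v.converged
        assert fit_l.loglik == pytest.approx(fit_v.loglik, abs=1e-5)

        # analytic map: lambda'_r = lambda_r * sigma_zeta, sigma_zeta' = 1,
        # gamma' = gamma / sigma_zeta ... except the group effect acts on
        # the latent mean, so it rescales with the loadings instead
        est = fit_l.estimates
        sz = est["sigma_zeta"]
        mapped = dict(est)
        mapped.pop("sigma_zeta")
        mapped["lambda_neostriatum"] = sz
        for r in spec_l.regions[1:]:
            mapped[f"lambda_{r}"] = est[f"lambda_{r}"] * sz
        mapped["gamma_group"] = est["gamma_group"] / sz
        covrow = [30.0, 0.015, 0.0]
        for group in (0.0, 1.0):
            m1, c1 = model_moments(est, spec_l, covrow, group)
            m2, c2 = model_moments(mapped, spec_v, covrow, group)
            np.testing.assert_allclose(m1, m2, atol=1e-10)
            np.testing.assert_allclose(c1, c2, atol=1e-10)

    def test_nonconverged_fit_withholds_estimates(self, medium_cohort):
        spec = build_lvm_spec("group_only")
        fit = fit_lvm(spec, medium_cohort, maxiter=1, compute_vcov=False)
        if not fit.converged:
            with pytest.raises(RuntimeError, match="converge"):
                _ = fit.estimates

    def test_too_few_rows_rejected(self, medium_cohort):
        spec = build_lvm_spec("group_only")
        with pytest.raises(ValueError, match="rows"):
            fit_lvm(spec, medium_cohort.head(10))


class TestResiduals:
    def test_noise_free_residuals_are_zero(self):
        p = default_params(
            n_mdd=60, n_hc=60,
            sigma_region=(1e-7,) * 4, sigma_zeta=1e-7, cov_hipp_amyg=0.0)
        tab = generate_cohort(p, seed=13)
        spec = build_lvm_spec("hormones", censoring_mode="integrate_full")
        # evaluate residuals at the generating parameters directly
        from serolvm.lvm import FittedLVM
        layout = ParameterLayout(spec)
        theta = truth_named(spec, p)
        fit = FittedLVM(spec=spec, layout=layout,
                        theta_internal=layout.to_internal(theta),
                        vcov=None, loglik=0.0, n_obs=len(tab), n_dropped=0,
                        converged=True, n_iter=0, message="", fit_seconds=0.0)
        res = residuals(fit, tab[tab["estradiol_censored"] == 0])
        # undo standardization: raw residuals vanish with the noise
        import serolvm.lvm as lvm_mod
        pp = lvm_mod._unpack(layout.to_internal(theta), layout)
        sd = np.sqrt(pp.lam ** 2 * pp.sigma_zeta ** 2 + np.diag(pp.sigma_eps))
        raw = res.to_numpy() * sd[None, :]
        assert np.abs(raw).max() < 1e-6

    def test_residual_mean_zero_variance_one(self, group_fit, medium_cohort):
        res = residuals(group_fit, medium_cohort).to_numpy()
        n = res.shape[0]
        assert np.all(np.abs(res.mean(axis=0)) < 3 / np.sqrt(n))
        assert np.all(np.abs(res.var(axis=0, ddof=1) - 1)
                      < 3 * np.sqrt(2.0 / n))

    def test_residual_normality_across_replicates(self):
        """Kolmogorov–Smirnov on fitted residuals of correctly specified
        models is non-significant in the vast majority of replicates."""
        p = default_params(n_mdd=100, n_hc=100, cov_hipp_amyg=0.0)
        spec = build_lvm_spec("group_only")
        n_sig = 0
        n_tot = 0
        for rep in range(40):
            tab = generate_cohort(p, seed=1000 + rep)
            fit = fit_lvm(spec, tab, compute_vcov=False,
                          start=truth_named(spec, p))
            if not fit.converged:
                continue
            res = residuals(fit, tab)
            for col in res.columns:
                n_tot += 1
                if stats.kstest(res[col], "norm").pvalue < 0.05:
                    n_sig += 1
        assert n_tot >= 120
        assert n_sig / n_tot <= 0.10
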