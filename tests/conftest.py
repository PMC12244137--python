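import pytest

from serolvm.lvm import build_lvm_spec, fit_lvm
from serolvm.synthetic import default_params, generate_cohort, generate_hamd


def truth_named(spec, p):
    """Generator parameters expressed in the fitting engine's naming."""
    d = {}
    for j, r in enumerate(spec.regions):
        d[f"nu_{r}"] = p.nu[j]
        if j or spec.normalization == "variance":
            d[f"lambda_{r}"] = p.lam[j]
        for c, vec in zip(("age", "dose", "scanner"),
                          (p.beta_age, p.beta_dose, p.beta_scanner)):
            if c in spec.covariates:
                d[f"beta_{r}_{c}"] = vec[j]
        d[f"sigma_{r}"] = p.sigma_region[j]
    for a, b in spec.extra_covariances:
        d[f"cov_{a}_{b}"] = p.cov_hipp_amyg \
            if {a, b} == {"hippocampus", "amygdala"} else 0.0
    if spec.normalization == "loading":
        d["sigma_zeta"] = p.sigma_zeta
    d["gamma_group"] = p.gamma_group
    if spec.model == "hormones":
        d["gamma1"] = p.gamma1_hc
        d["dgamma1"] = p.gamma1_mdd - p.gamma1_hc
        d["gamma2"] = p.gamma2_hc
        d["dgamma2"] = p.gamma2_mdd - p.gamma2_hc
        d["alpha_e"] = p.alpha_e
        d["gamma3"] = p.gamma3
        d["sigma_e"] = p.sigma_e
    return d


@pytest.fixture(scope="session")
def medium_params():
    return default_params(n_mdd=500, n_hc=500)


@pytest.fixture(scope="session")
def medium_cohort(medium_params):
    tab = generate_cohort(medium_params, seed=42)
    return generate_hamd(medium_params, tab, seed=43)


@pytest.fixture(scope="session")
def hormones_fit(medium_params, medium_cohort):
    """One shared converged hormone-model fit with SEs available."""
    spec = build_lvm_spec("hormones",
                          extra_covariances=[("hippocampus", "amygdala")],
                          censoring_mode="integrate_full")
    fit = fit_lvm(spec, medium_cohort,
                  start=truth_named(spec, medium_params))
    assert fit.converged and fit.vcov is not None
    return fit


@pytest.fixture(scope="session")
def group_fit(medium_params, medium_cohort):
    spec = build_lvm_spec("group_only",
                          extra_covariances=[("hippocampus", "amygdala")])
    fit = fit_lvm(spec, medium_cohort,
                  start=truth_named(spec, medium_params))
    assert fit.converged
    return fit
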