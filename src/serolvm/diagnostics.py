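"""Residual-covariance misspecification diagnostics and model refinement.

A fitted latent-variable model constrains all residual covariances
between regions to zero unless explicitly freed. For every constrained
region pair a Rao score test evaluates whether freeing that covariance
would improve the model, using the likelihood gradient and observed
information of the extended model at the restricted maximum-likelihood
estimate — the extended model never has to be fitted.

The refinement loop mirrors stepwise covariance selection: Holm-adjust
the score-test p-values over the current candidate family, free the
covariance with the smallest p-value if it stays significant, refit,
and repeat until nothing is significant. The loop terminates because
the candidate set strictly shrinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .lvm import (
    FittedLVM,
    LVMSpec,
    ParameterLayout,
    PreparedData,
    _loglik_internal,
    _strata_moments,
    _unpack,
    fit_lvm,
    prepare_data,
)

__all__ = ["score_tests", "refine_covariance", "qq_points", "holm_adjust"]


def holm_adjust(pvals) -> np.ndarray:
    """Holm–Bonferroni step-down adjustment (monotone, clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def _candidate_pairs(spec: LVMSpec):
    free = {frozenset(p) for p in spec.extra_covariances}
    return [pair for pair in combinations(spec.regions, 2)
            if frozenset(pair) not in free]


def _expected_information(layout: ParameterLayout, z0: np.ndarray,
                          dat: PreparedData) -> np.ndarray:
    """Fisher information of the Gaussian model at ``z0``.

    Classical form for stratified multivariate normals with shared
    within-stratum covariance: mean part ``Σ_i ∂μ_i' Σ⁻¹ ∂μ_i`` plus
    covariance part ``n_s/2 · tr(Σ⁻¹ ∂Σ Σ⁻¹ ∂Σ)``, with derivatives by
    central differences of the implied moments. Positive semi-definite
    by construction — unlike the observed information, which can turn
    indefinite at a restricted estimate under strong misspecification.
    """
    spec = layout.spec
    k = layout.k
    base = _strata_moments(_unpack(z0, layout), spec, dat)
    h = 1e-4 * np.maximum(np.abs(z0), 1.0)
    dmu = [np.empty((k,) + m.shape) for m, _ in base]
    dcov = [np.empty((k,) + c.shape) for _, c in base]
    for j in range(k):
        zp, zm = z0.copy(), z0.copy()
        zp[j] += h[j]
        zm[j] -= h[j]
        mp = _strata_moments(_unpack(zp, layout), spec, dat)
        mm = _strata_moments(_unpack(zm, layout), spec, dat)
        for s in range(len(base)):
            dmu[s][j] = (mp[s][0] - mm[s][0]) / (2 * h[j])
            dcov[s][j] = (mp[s][1] - mm[s][1]) / (2 * h[j])
    info = np.zeros((k, k))
    for s, (mu, cov) in enumerate(base):
        n_s = mu.shape[0]
        L = np.linalg.cholesky(cov)
        # mean part: whiten the mean derivatives, then Gram matrix
        white = np.linalg.solve(L, dmu[s].transpose(0, 2, 1))  # (k, d, n)
        info += np.einsum("adn,bdn->ab", white, white)
        # covariance part
        ci = np.linalg.inv(cov)
        cder = np.einsum("ij,ajk->aik", ci, dcov[s])  # (k, d, d)
        info += 0.5 * n_s * np.einsum("aij,bji->ab", cder, cder)
    return info


def score_tests(fit: FittedLVM, data) -> pd.DataFrame:
    """Score tests for every residual covariance constrained to zero.

    For each candidate pair the statistic is the efficient score
    ``U_c² / (I_cc − I_cθ I_θθ⁻¹ I_θc)`` evaluated at the restricted
    MLE with the candidate fixed at 0, referred to chi-square(1). The
    score is a central difference of the log-likelihood; the information
    is the expected (Fisher) information of the extended model, whose
    Schur complement is non-negative by construction. Candidates with a
    numerically singular information are flagged untestable.
    """
    fit._require_converged()
    spec = fit.spec
    dat = data if isinstance(data, PreparedData) else prepare_data(spec, data)
    est = fit.estimates

    rows = []
    for pair in _candidate_pairs(spec):
        ext_spec = spec.with_covariance(pair)
        ext_layout = ParameterLayout(ext_spec)
        named = dict(est)
        named[f"cov_{pair[0]}_{pair[1]}"] = 0.0
        z0 = ext_layout.to_internal(named)
        ci = ext_layout.index[f"cov_{pair[0]}_{pair[1]}"]
        rest_idx = np.array([ext_layout.index[n] for n in fit.layout.names])

        hc = 1e-4
        zp, zm = z0.copy(), z0.copy()
        zp[ci] += hc
        zm[ci] -= hc
        u_c = (_loglik_internal(zp, ext_layout, dat)
               - _loglik_internal(zm, ext_layout, dat)) / (2 * hc)

        info = _expected_information(ext_layout, z0, dat)
        i_cc = info[ci, ci]
        i_ct = info[ci, rest_idx]
        i_tt = info[np.ix_(rest_idx, rest_idx)]
        try:
            denom = i_cc - i_ct @ np.linalg.solve(i_tt, i_ct)
        except np.linalg.LinAlgError:
            denom = np.nan
        if not np.isfinite(denom) or denom <= 1e-10 * max(i_cc, 1.0):
            rows.append({"pair": pair, "statistic": np.nan, "df": 1,
                         "p": np.nan, "testable": False})
            continue
        stat = u_c ** 2 / denom
        rows.append({"pair": pair, "statistic": float(stat), "df": 1,
                     "p": float(stats.chi2.sf(stat, 1)), "testable": True})

    table = pd.DataFrame(rows)
    testable = table["testable"].to_numpy()
    adj = np.full(len(table), np.nan)
    if testable.any():
        adj[testable] = holm_adjust(table.loc[testable, "p"].to_numpy())
    table["p_holm"] = adj
    # ties broken by lexicographic region-pair order for determinism
    table = table.sort_values(["p", "pair"], kind="stable").reset_index(drop=True)
    return table


@dataclass
class RefinementLog:
    """Ordered record of the covariance parameters added."""
    steps: list = field(default_factory=list)
    tables: list = field(default_factory=list)
    aborted: bool = False
    message: str = ""

    def to_records(self):
        return [{"pair": list(s["pair"]), "statistic": s["statistic"],
                 "p": s["p"], "p_holm": s["p_holm"]} for s in self.steps]


def refine_covariance(spec: LVMSpec, data, alpha: float = 0.05,
                      **fit_kwargs):
    """Iteratively free residual covariances flagged by score tests.

    Each round fits the current model, score-tests all remaining
    candidate pairs, Holm-adjusts within the round, and frees the
    smallest-p candidate if its adjusted p-value is below ``alpha``.
    Returns ``(final_fit, RefinementLog)``. Non-convergence of an inner
    fit aborts with the partial log.
    """
    log = RefinementLog()
    current = spec
    fit = fit_lvm(current, data, **fit_kwargs)
    fit_kwargs = dict(fit_kwargs)
    while True:
        if not fit.converged:
            log.aborted = True
            log.message = f"inner fit failed: {fit.message}"
            return fit, log
        candidates = _candidate_pairs(current)
        if alpha <= 0 or not candidates:
            return fit, log
        table = score_tests(fit, data)
        log.tables.append(table)
        usable = table[table["testable"]]
        if usable.empty:
            log.message = "no testable candidates"
            return fit, log
        best = usable.iloc[0]
        if not np.isfinite(best["p_holm"]) or best["p_holm"] >= alpha:
            return fit, log
        log.steps.append(best.to_dict())
        pair = tuple(best["pair"])
        current = current.with_covariance(pair)
        # warm-start the extended fit at the previous estimates
        start = dict(fit.estimates)
        start[f"cov_{pair[0]}_{pair[1]}"] = 0.0
        fit_kwargs["start"] = start
        fit = fit_lvm(current, data, **fit_kwargs)


def qq_points(resid) -> dict:
    """Normal QQ coordinates per region for residual diagnostics.

    Theoretical quantiles are standard-normal at rankit positions
    (i − 0.5)/n; empirical coordinates are the sorted residuals. A
    region with (numerically) zero spread is flagged degenerate.
    """
    df = pd.DataFrame(resid)
    out = {}
    for col in df.columns:
        v = df[col].dropna().to_numpy(dtype=float)
        n = v.size
        if n < 3:
            raise ValueError("need at least 3 residuals per region")
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        emp = np.sort(v)
        out[col] = {
            "theoretical": theo,
            "empirical": emp,
            "degenerate_spread": bool(np.ptp(emp) < 1e-12),
        }
    return out
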