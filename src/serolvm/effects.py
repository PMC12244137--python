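"""Mediation decomposition of the testosterone effect on the latent factor.

Testosterone acts on the global binding factor directly (slope gamma1)
and indirectly via estradiol (testosterone→estradiol slope gamma3 times
estradiol→latent slope gamma2). Per group::

    direct   = gamma1(group)
    indirect = gamma2(group) * gamma3
    total    = direct + indirect

with gamma(MDD) = gamma(HC) + dgamma and gamma3 shared across groups.
Standard errors use the first-order delta method on the joint covariance
of (gamma1, dgamma1, gamma2, dgamma2, gamma3) from the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lvm import FittedLVM

__all__ = ["EffectEstimate", "decompose_effects", "group_contrast",
           "decompose_from_coefs", "contrast_from_coefs", "effects_table"]

_PARAMS = ("gamma1", "dgamma1", "gamma2", "dgamma2", "gamma3")


@dataclass
class EffectEstimate:
    """Point estimate with Wald inference for a scalar effect functional."""

    name: str
    group: str          # "HC", "MDD", or "MDD-HC"
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float

    @classmethod
    def from_delta(cls, name, group, estimate, grad, vcov):
        if vcov is None:
            se = np.nan
        else:
            se = float(np.sqrt(grad @ vcov @ grad))
        z = estimate / se if se and np.isfinite(se) and se > 0 else np.nan
        p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan
        return cls(name=name, group=group, estimate=float(estimate), se=se,
                   ci_low=float(estimate - 1.96 * se),
                   ci_high=float(estimate + 1.96 * se), p=p)


def _coefs_and_vcov(fit: FittedLVM):
    if fit.spec.model != "hormones":
        raise ValueError("effect decomposition requires the hormones model")
    est = fit.estimates
    th = np.array([est[n] for n in _PARAMS])
    try:
        vcov = fit.structural_vcov(_PARAMS)
    except RuntimeError:
        vcov = None
    return th, vcov


def decompose_from_coefs(coefs: dict, group: str, vcov=None) -> dict:
    """Effect decomposition from plain structural coefficients.

    ``coefs`` maps gamma1/dgamma1/gamma2/dgamma2/gamma3 to values
    (missing dgamma terms default to 0); ``vcov`` is an optional 5×5
    covariance in that order. Useful for reproducing published worked
    examples from reported coefficients alone.
    """
    th = np.array([float(coefs.get(n, 0.0)) for n in _PARAMS])
    return _decompose(th, vcov, group)


def contrast_from_coefs(coefs: dict, effect: str, vcov=None) -> EffectEstimate:
    """Group contrast from plain structural coefficients."""
    th = np.array([float(coefs.get(n, 0.0)) for n in _PARAMS])
    return _contrast(th, vcov, effect)


def decompose_effects(fit: FittedLVM, group: str) -> dict:
    """Direct, estradiol-mediated indirect, and total testosterone effect.

    ``group`` is "HC" or "MDD". Returns a dict of
    :class:`EffectEstimate`; direct + indirect = total exactly.
    """
    th, vcov = _coefs_and_vcov(fit)
    return _decompose(th, vcov, group)


def _decompose(th, vcov, group: str) -> dict:
    g1, d1, g2, d2, g3 = th
    gi = {"HC": 0.0, "MDD": 1.0}[group]
    direct = g1 + gi * d1
    indirect = (g2 + gi * d2) * g3
    grad_direct = np.array([1.0, gi, 0.0, 0.0, 0.0])
    grad_indirect = np.array([0.0, 0.0, g3, gi * g3, g2 + gi * d2])
    return {
        "direct": EffectEstimate.from_delta("direct", group, direct,
                                            grad_direct, vcov),
        "indirect": EffectEstimate.from_delta("indirect", group, indirect,
                                              grad_indirect, vcov),
        "total": EffectEstimate.from_delta("total", group, direct + indirect,
                                           grad_direct + grad_indirect, vcov),
    }


def group_contrast(fit: FittedLVM, effect: str) -> EffectEstimate:
    """MDD − HC contrast of an effect functional.

    ``effect`` is one of direct, indirect, total, or estradiol (the
    estradiol→latent slope difference dgamma2). Because gamma3 is shared
    across groups the total contrast reduces to
    ``dgamma1 + dgamma2 * gamma3``.
    """
    th, vcov = _coefs_and_vcov(fit)
    return _contrast(th, vcov, effect)


def _contrast(th, vcov, effect: str) -> EffectEstimate:
    _, d1, _, d2, g3 = th
    if effect == "direct":
        val, grad = d1, np.array([0.0, 1.0, 0.0, 0.0, 0.0])
    elif effect == "estradiol":
        val, grad = d2, np.array([0.0, 0.0, 0.0, 1.0, 0.0])
    elif effect == "indirect":
        val, grad = d2 * g3, np.array([0.0, 0.0, 0.0, g3, d2])
    elif effect == "total":
        val = d1 + d2 * g3
        grad = np.array([0.0, 1.0, 0.0, g3, d2])
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return EffectEstimate.from_delta(effect, "MDD-HC", val, grad, vcov)


def effects_table(fit: FittedLVM) -> pd.DataFrame:
    """All per-group effects and group contrasts as one flat table."""
    rows = []
    for group in ("HC", "MDD"):
        rows.extend(decompose_effects(fit, group).values())
    for effect in ("direct", "indirect", "total", "estradiol"):
        rows.append(group_contrast(fit, effect))
    return pd.DataFrame([{
        "effect": r.name, "group": r.group, "estimate": r.estimate,
        "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
    } for r in rows])
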