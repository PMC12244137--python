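"""Two-group comparisons that respect left-censored concentrations.

A left-censored value at c means the true concentration is known only
to be at or below c (the assay's limit of quantification). Gehan's
generalized Wilcoxon test scores every between-group pair of
observations +1 / 0 / −1 according to whether their ordering is
unambiguous given the censoring, and sums the scores; inference is by
group-label permutation (exact when the pooled sample is small) or by
the asymptotic normal approximation with the permutation variance.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["gehan_scores", "gehan_statistic", "gehan_test", "welch_t",
           "censoring_summary"]


def _pairwise(u, cu, v, cv) -> int:
    """Gehan score of one pair under left-censoring.

    +1 if the first observation is unambiguously greater, −1 if
    unambiguously smaller, 0 if the ordering is indeterminate (both
    censored, a bound that does not separate, or tied uncensored
    values).
    """
    if cu and cv:
        return 0
    if not cu and not cv:
        return int(u > v) - int(u < v)
    if cu:                       # u ≤ u_bound vs observed v
        return -1 if v > u else 0
    return 1 if u > v else 0     # observed u vs v ≤ v_bound


def gehan_scores(values, censored) -> np.ndarray:
    """Pooled-sample Gehan score of each observation.

    ``s_k`` counts the observations that observation k is unambiguously
    greater than, minus those it is unambiguously smaller than, over
    the whole pooled sample. The between-group pairwise statistic
    equals the sum of ``s_k`` over one group because within-group terms
    cancel by antisymmetry.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(censored, dtype=bool)
    # vectorized: u > v comparisons with censor masks
    obs_i = ~c[:, None]
    obs_j = ~c[None, :]
    gt = v[:, None] > v[None, :]
    win = (obs_i & obs_j & gt) | (obs_i & ~obs_j & gt)
    loss = (obs_i & obs_j & gt.T) | (~obs_i & obs_j & gt.T)
    return (win.sum(axis=1) - loss.sum(axis=1)).astype(float)


def gehan_statistic(values, censored, groups) -> float:
    """Sum of pairwise Gehan scores, first group vs second.

    Group orientation: labels sorted lexicographically; the statistic
    is positive when the first label's values tend to be larger.
    """
    labels = np.unique(np.asarray(groups))
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    s = gehan_scores(values, censored)
    mask1 = np.asarray(groups) == labels[0]
    return float(s[mask1].sum())


def gehan_test(values, censored, groups, *, inference: str = "permutation",
               n_perm: int = 10000, seed: int | None = None) -> dict:
    """Gehan's generalized Wilcoxon test for two censored samples.

    ``inference='permutation'`` permutes group labels: exact
    enumeration when the pooled size is at most 10, otherwise
    Monte-Carlo with ``n_perm`` draws (seeded). ``'asymptotic'`` refers
    the statistic to a normal distribution with the permutation
    variance ``n1·n2·Σs_k²/(N(N−1))``. Returns a dict with the
    statistic, two-sided p, and method metadata.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(censored, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    n1 = int((g == labels[0]).sum())
    n2 = int((g == labels[1]).sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    s = gehan_scores(v, c)
    w_obs = float(s[g == labels[0]].sum())
    n = n1 + n2
    out = {"statistic": w_obs, "n1": n1, "n2": n2,
           "group_order": (str(labels[0]), str(labels[1]))}

    if inference == "asymptotic":
        var = n1 * n2 * np.sum(s ** 2) / (n * (n - 1))
        if var <= 0:
            out.update(p=1.0, method="asymptotic", z=0.0)
            return out
        z = w_obs / np.sqrt(var)
        out.update(p=float(2 * stats.norm.sf(abs(z))), z=float(z),
                   method="asymptotic")
        return out
    if inference != "permutation":
        raise ValueError(f"unknown inference {inference!r}")

    if n <= 10:
        total = comb(n, n1)
        count = sum(abs(s[list(ix)].sum()) >= abs(w_obs) - 1e-12
                    for ix in combinations(range(n), n1))
        out.update(p=count / total, method="exact-permutation",
                   n_perm=total)
        return out

    if n_perm < 100:
        raise ValueError("n_perm must be at least 100 for Monte-Carlo")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        w = s[rng.permutation(n)[:n1]].sum()
        if abs(w) >= abs(w_obs) - 1e-12:
            hits += 1
    out.update(p=(hits + 1) / (n_perm + 1), method="mc-permutation",
               n_perm=n_perm, seed=seed)
    return out


def welch_t(values, groups) -> dict:
    """Welch's unequal-variance t-test with Satterthwaite df."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError("exactly two groups required")
    a, b = v[g == labels[0]], v[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue),
            "mean_diff": float(a.mean() - b.mean()),
            "group_order": (str(labels[0]), str(labels[1]))}


def censoring_summary(censored, groups) -> pd.DataFrame:
    """Per-group censoring counts with integer percentages."""
    df = pd.DataFrame({"censored": np.asarray(censored, dtype=bool),
                       "group": np.asarray(groups)})
    rows = []
    for label, sub in df.groupby("group", sort=True):
        n = len(sub)
        nc = int(sub["censored"].sum())
        rows.append({"group": label, "n": n, "n_censored": nc,
                     "percent_censored": int(round(100.0 * nc / n)) if n else 0})
    return pd.DataFrame(rows)
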