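"""Regularized partial-correlation network of symptoms, hormones and binding.

The exploratory network couples neostriatal binding (adjusted for age
and tracer dose), testosterone and a binary below-LOQ estradiol
indicator (both adjusted for age), and Hamilton depression items: the
six-item core subscale plus five vegetative items. Edges are partial
correlations from an L1-penalized Gaussian precision matrix (graphical
lasso); the penalty is chosen by the extended Bayesian information
criterion with hyperparameter ``tuning`` (0.5 by convention for
psychometric networks). Node importance is summarized by strength (sum
of absolute incident edge weights) and betweenness (shortest paths
through the node with edge length 1/|weight|).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from .cohort import HAMD_ITEM_MAX, HAMD6_ITEMS, VEGETATIVE_ITEMS

__all__ = ["residualize", "hamd_subscales", "ebic_glasso", "centrality",
           "NetworkResult"]

_VEG_NAMES = {4: "insomnia_initial", 5: "insomnia_middle",
              6: "insomnia_delayed", 12: "gastrointestinal", 16: "weight_loss"}


def residualize(table: pd.DataFrame, adjustments: dict) -> pd.DataFrame:
    """Replace named variables by OLS residuals on their covariates.

    ``adjustments`` maps a column name to the list of covariate columns
    it should be adjusted for (an intercept is always included, so
    residuals are centered). Unnamed columns pass through unchanged.
    Rows with missing values in any involved column are dropped
    listwise first. Collinear covariate sets raise.
    """
    involved = set()
    for var, covs in adjustments.items():
        involved.add(var)
        involved.update(covs)
    df = table.dropna(subset=[c for c in involved if c in table.columns]).copy()
    for var, covs in adjustments.items():
        X = np.column_stack([np.ones(len(df))]
                            + [df[c].to_numpy(dtype=float) for c in covs])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"collinear covariates adjusting {var!r}: {covs}")
        y = df[var].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        df[var] = y - X @ coef
    return df


def hamd_subscales(items) -> tuple[pd.Series, pd.DataFrame]:
    """Core (HAMD6) sum score and the five vegetative items.

    ``items`` is a DataFrame with columns hamd_1..hamd_17 (or a 17-wide
    array). Returns the Bech core subscale (items 1, 2, 7, 8, 10, 13
    summed) and the individual vegetative items (initial, middle and
    delayed insomnia; gastrointestinal; weight loss). Values outside an
    item's standard range raise.
    """
    df = pd.DataFrame(items)
    if df.shape[1] == 17 and not str(df.columns[0]).startswith("hamd_"):
        df.columns = [f"hamd_{i}" for i in range(1, 18)]
    missing = [f"hamd_{i}" for i in range(1, 18) if f"hamd_{i}" not in df.columns]
    if missing:
        raise ValueError(f"missing HAMD items: {missing}")
    for i in range(1, 18):
        col = df[f"hamd_{i}"]
        bad = (col < 0) | (col > HAMD_ITEM_MAX[i])
        if bad.any():
            raise ValueError(
                f"hamd_{i} outside 0..{HAMD_ITEM_MAX[i]} in {int(bad.sum())} rows")
    hamd6 = df[[f"hamd_{i}" for i in HAMD6_ITEMS]].sum(axis=1)
    hamd6.name = "hamd6"
    veg = df[[f"hamd_{i}" for i in VEGETATIVE_ITEMS]].copy()
    veg.columns = [_VEG_NAMES[i] for i in VEGETATIVE_ITEMS]
    return hamd6, veg


@dataclass
class NetworkResult:
    """Estimated partial-correlation network."""

    nodes: tuple
    adjacency: pd.DataFrame      # symmetric, zero diagonal
    precision: np.ndarray
    penalty: float
    ebic: float
    tuning: float
    grid: pd.DataFrame           # (penalty, ebic, n_edges) over the search

    @property
    def n_edges(self) -> int:
        a = self.adjacency.to_numpy()
        return int(np.count_nonzero(np.triu(np.abs(a) > 1e-10, k=1)))

    def edge_list(self) -> pd.DataFrame:
        a = self.adjacency.to_numpy()
        rows = []
        for i in range(len(self.nodes)):
            for j in range(i + 1, len(self.nodes)):
                if abs(a[i, j]) > 1e-10:
                    rows.append({"node1": self.nodes[i], "node2": self.nodes[j],
                                 "weight": a[i, j]})
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])


def _nearest_pd(corr: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(corr)
    if w.min() > eps:
        return corr
    warnings.warn("correlation matrix not positive definite; "
                  "projecting to the nearest PD matrix", stacklevel=3)
    w = np.clip(w, eps, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def _partial_corr(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    pc = -precision / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    return pc


def _support_mle(S: np.ndarray, edges: frozenset, tol: float = 1e-9,
                 max_iter: int = 500) -> np.ndarray:
    """Gaussian MLE of the precision matrix with a fixed zero pattern.

    Iterative proportional scaling over the edge set: each pass matches
    the fitted covariance to S on the diagonal and on every permitted
    edge while keeping the complement of the support exactly zero in
    the precision. Converges for any support when S is positive
    definite.
    """
    p = S.shape[0]
    K = np.diag(1.0 / np.diag(S))
    if not edges:
        return K
    idx = [np.array(e) for e in sorted(tuple(sorted(e)) for e in edges)]
    for _ in range(max_iter):
        W = np.linalg.inv(K)
        delta = 0.0
        for e in idx:
            block = np.ix_(e, e)
            adj = np.linalg.inv(S[block]) - np.linalg.inv(W[block])
            K[block] += adj
            delta = max(delta, np.abs(adj).max())
            W = np.linalg.inv(K)
        if delta < tol:
            break
    return K


def ebic_glasso(data: pd.DataFrame, tuning: float = 0.5,
                penalties=None, n_penalties: int = 100,
                small_sample_ack: bool = False) -> NetworkResult:
    """Gaussian graphical model by EBIC-selected graphical lasso.

    The graphical-lasso path over a logarithmic penalty grid (by
    default 100 values spanning [0.01, 1] times the largest absolute
    off-diagonal correlation) proposes candidate edge sets; each
    distinct support is refitted by the unpenalized Gaussian MLE with
    that zero pattern, and the refit minimizing
    ``EBIC = −2·loglik + k·log(n) + 4·k·tuning·log(p)`` (k = number of
    edges) is kept. Scoring supports at their constrained MLE rather
    than at the shrunk path solution is what makes the extended BIC
    consistent for support recovery. Edges are reported as partial
    correlations of the refitted precision.

    With fewer than 3 observations per node the estimate is unstable;
    pass ``small_sample_ack=True`` to run anyway.
    """
    df = pd.DataFrame(data).dropna()
    n, p = df.shape
    if p < 3:
        raise ValueError("need at least 3 nodes")
    if n <= 3:
        raise ValueError("need more than 3 observations")
    if n < 3 * p and not small_sample_ack:
        raise ValueError(
            f"n={n} below 3×p={3*p}: pass small_sample_ack=True to "
            "acknowledge an unstable small-sample network")
    nodes = tuple(df.columns)
    S = _nearest_pd(np.corrcoef(df.to_numpy(dtype=float), rowvar=False))

    if penalties is None:
        off = np.abs(S[~np.eye(p, dtype=bool)])
        hi = max(off.max(), 1e-3)
        penalties = np.logspace(np.log10(0.01 * hi), np.log10(hi), n_penalties)
    penalties = np.asarray(penalties, dtype=float)

    # candidate supports along the lasso path
    supports: dict[frozenset, float] = {}
    for alpha in penalties:
        try:
            if alpha == 0:
                prec = np.linalg.inv(S)
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, prec = graphical_lasso(S, alpha=float(alpha),
                                              max_iter=500, tol=1e-4)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        sup = frozenset(
            (i, j) for i in range(p) for j in range(i + 1, p)
            if abs(prec[i, j]) > 1e-10)
        supports.setdefault(sup, float(alpha))
    if not supports:
        raise RuntimeError("graphical lasso failed on every penalty")

    best = None
    grid_rows = []
    for sup, alpha in supports.items():
        prec = _support_mle(S, sup)
        sign, logdet = np.linalg.slogdet(prec)
        if sign <= 0:
            continue
        loglik = 0.5 * n * (logdet - np.trace(S @ prec))
        k = len(sup)
        ebic = -2.0 * loglik + k * np.log(n) + 4.0 * k * tuning * np.log(p)
        grid_rows.append({"penalty": alpha, "ebic": float(ebic),
                          "n_edges": k})
        if best is None or ebic < best[0]:
            best = (ebic, alpha, prec, sup)

    ebic_val, alpha, prec, sup = best
    pc = _partial_corr(prec)
    mask = np.zeros((p, p), dtype=bool)
    for i, j in sup:
        mask[i, j] = mask[j, i] = True
    pc[~mask] = 0.0
    adjacency = pd.DataFrame(pc, index=nodes, columns=nodes)
    return NetworkResult(nodes=nodes, adjacency=adjacency, precision=prec,
                         penalty=alpha, ebic=ebic_val, tuning=tuning,
                         grid=pd.DataFrame(grid_rows))


def centrality(network) -> pd.DataFrame:
    """Strength and betweenness per node, raw and z-scored across nodes.

    Strength is the sum of absolute incident edge weights. Betweenness
    counts shortest paths through the node, with edge length defined as
    the reciprocal absolute weight (strong edges are short). Isolated
    nodes get zero on both.
    """
    adj = network.adjacency if isinstance(network, NetworkResult) \
        else pd.DataFrame(network)
    nodes = list(adj.columns)
    a = adj.to_numpy(dtype=float)
    strength = np.abs(a).sum(axis=1)

    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(a[i, j]) > 1e-10:
                g.add_edge(nodes[i], nodes[j], length=1.0 / abs(a[i, j]))
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)

    def z(v):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

    out = pd.DataFrame({
        "node": nodes,
        "strength": strength,
        "betweenness": [btw[n] for n in nodes],
    })
    out["strength_z"] = z(out["strength"])
    out["betweenness_z"] = z(out["betweenness"])
    return out
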