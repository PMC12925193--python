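"""Weighted maximum likelihood for the random-intercept linear mixed model.

The trajectory analysis needs a Gaussian random-intercept model whose
log-likelihood is weighted at the cluster level (IPTW: each trial block is
one cluster carrying one analysis weight) and optionally at the row level
(IPCW: follow-up months carry time-varying censoring weights).  Neither
weighting is available in off-the-shelf mixed-model fitters, but the
random-intercept structure keeps everything closed form: with cluster k
holding rows j with row weights w_j and cluster weight g_k, the weighted
pseudo-log-likelihood is

    -2 pll = sum_k g_k [ q_k + W_k log(s) + log(1 + a W_k / s) ] + const,

    q_k = (1/s) [ sum_j w_j r_j^2  -  c_k (sum_j w_j r_j)^2 ],
    c_k = a / (s + a W_k),          W_k = sum_j w_j,

where a and s are the random-intercept and residual variances and r = y - Xb.
Duplicating a whole cluster m times is identical to g_k = m; duplicating a
row within its cluster is identical to w_j = m.  Profiling b out via GLS
leaves a two-parameter optimization over (log a, log s), evaluated from
per-cluster sufficient statistics so each likelihood call is O(K p^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize


@dataclass
class MixedFit:
    """Result of a weighted random-intercept fit."""

    beta: np.ndarray
    sigma_b: float
    sigma_e: float
    neg2ll: float
    converged: bool
    n_obs: int
    n_clusters: int

    @property
    def variance_components(self) -> tuple[float, float]:
        return self.sigma_b**2, self.sigma_e**2


class _Suffstats:
    """Weight-dependent sufficient statistics, reusable across (a, s) evals."""

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        cluster: np.ndarray,
        cluster_weights: np.ndarray,
        row_weights: np.ndarray,
    ):
        K = int(cluster.max()) + 1
        p = X.shape[1]
        g_row = cluster_weights[cluster]
        gw = g_row * row_weights
        self.A0 = X.T @ (gw[:, None] * X)
        self.b0 = X.T @ (gw * y)
        self.yy = float(gw @ (y * y))
        self.S = np.empty((K, p))
        wX = row_weights[:, None] * X
        for j in range(p):
            self.S[:, j] = np.bincount(cluster, wX[:, j], minlength=K)
        self.t = np.bincount(cluster, row_weights * y, minlength=K)
        self.W = np.bincount(cluster, row_weights, minlength=K)
        self.g = cluster_weights
        self.gW_sum = float(self.g @ self.W)
        self.p = p

    def profile(self, a: float, s: float):
        """GLS beta and -2 pseudo-log-likelihood at variance components (a, s)."""
        c = a / (s + a * self.W)
        gc = self.g * c
        XtViX = (self.A0 - self.S.T @ (gc[:, None] * self.S)) / s
        XtViy = (self.b0 - self.S.T @ (gc * self.t)) / s
        ytViy = (self.yy - gc @ (self.t * self.t)) / s
        try:
            beta = linalg.solve(XtViX, XtViy, assume_a="pos")
        except linalg.LinAlgError:
            beta = np.linalg.lstsq(XtViX, XtViy, rcond=None)[0]
        quad = ytViy - beta @ XtViy
        logdet = np.log(s) * self.gW_sum + self.g @ np.log1p(a * self.W / s)
        return beta, float(quad + logdet)


def _start_values(stats: _Suffstats) -> tuple[float, float]:
    """Moment-style starts: split OLS residual variance between/within."""
    try:
        beta = linalg.solve(stats.A0, stats.b0, assume_a="pos")
    except linalg.LinAlgError:
        beta = np.linalg.lstsq(stats.A0, stats.b0, rcond=None)[0]
    # residual second moment and cluster-mean second moment from suffstats
    tot = (stats.yy - 2 * beta @ stats.b0 + beta @ stats.A0 @ beta) / max(
        stats.gW_sum, 1.0
    )
    rbar = (stats.t - stats.S @ beta) / np.maximum(stats.W, 1e-12)
    multi = stats.W > 1
    if multi.any():
        between = float(
            np.average(rbar[multi] ** 2, weights=(stats.g * stats.W)[multi])
        )
    else:
        between = tot / 2
    between = min(max(between, 1e-4), max(tot, 1e-3))
    within = max(tot - between, 1e-3)
    return between, within


def fit_weighted_random_intercept(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    cluster_weights: np.ndarray | None = None,
    row_weights: np.ndarray | None = None,
    start: tuple[float, float] | None = None,
    xatol: float = 1e-4,
    maxiter: int = 400,
) -> MixedFit:
    """Fit y = X beta + b_cluster + e by weighted profiled maximum likelihood.

    Parameters
    ----------
    X, y
        Design matrix (with intercept column) and response.
    clusters
        Cluster labels, one per row (any hashable values).
    cluster_weights
        One weight per row, constant within cluster (e.g. stabilized IPTW
        times bootstrap multiplicity).  Weights of zero drop the cluster.
    row_weights
        Optional observation-level weights (e.g. IPCW).
    start
        Optional warm start ``(sigma_b^2, sigma_e^2)``.

    Raises
    ------
    ValueError
        If no cluster with positive weight has two or more rows (variance
        components unidentifiable) or the optimizer fails to converge.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    labels, cl = np.unique(np.asarray(clusters), return_inverse=True)
    K = len(labels)
    n = len(y)
    if cluster_weights is None:
        g = np.ones(K)
    else:
        cw = np.asarray(cluster_weights, dtype=float)
        if (cw < 0).any():
            raise ValueError("cluster weights must be nonnegative")
        g = np.zeros(K)
        np.maximum.at(g, cl, cw)  # constant within cluster; max is the value
    w = (
        np.ones(n)
        if row_weights is None
        else np.asarray(row_weights, dtype=float)
    )
    sizes = np.bincount(cl[g[cl] > 0], minlength=K)
    if sizes.max(initial=0) < 2:
        raise ValueError(
            "variance components unidentifiable: no weighted cluster has "
            "two or more observations"
        )
    stats = _Suffstats(X, y, cl, g, w)

    a0, s0 = start if start is not None else _start_values(stats)

    def objective(theta: np.ndarray) -> float:
        a, s = np.exp(theta)
        _, n2ll = stats.profile(a, s)
        return n2ll

    res = optimize.minimize(
        objective,
        x0=np.log([max(a0, 1e-8), max(s0, 1e-8)]),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": 1e-6, "maxiter": maxiter},
    )
    a, s = np.exp(res.x)
    beta, n2ll = stats.profile(a, s)
    if not np.isfinite(n2ll):
        raise ValueError("mixed-model fit diverged (non-finite likelihood)")
    return MixedFit(
        beta=beta,
        sigma_b=float(np.sqrt(a)),
        sigma_e=float(np.sqrt(s)),
        neg2ll=float(n2ll),
        converged=bool(res.success),
        n_obs=n,
        n_clusters=K,
    )
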