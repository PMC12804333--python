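"""MultiWeightedLR: a maximum test over all weighted log-rank statistics.

Instead of combining the m weights per contrast into one quadratic form,
every statistic ``T_{j1,j2}(w^(r))`` is kept as its own coordinate.  Under
the global null the full m*q vector is asymptotically centered multivariate
normal; the test standardizes each coordinate by its estimated standard
deviation, takes ``T_max``, the maximum absolute standardized statistic, and
compares it to the equicoordinate (1-alpha)-quantile ``c`` of a centered
Gaussian vector with the estimated correlation matrix — the standard
multiple-contrast-test construction.  The per-pair maximum over weights
drives the local decisions, with the shared critical value ``c`` giving
simultaneous (single-step) error control.

Covariance estimation: the m x m diagonal blocks are the pairwise estimates
of :func:`survmctp.pairwise.wlr_sigma`; the cross-contrast blocks use a
martingale plug-in.  Each two-sample statistic decomposes into per-group
integrals ``sum_j eps_a(j) int H_{a,p} dA_hat_j`` with integrand

    H_{a,p}(t) = sqrt(n_a/(n_j1 n_j2)) w_p(F_hat_a(t-)) Y_j1 Y_j2/(Y_j1+Y_j2),

and the optional-variation estimate of the shared-group covariance is

    sum_{j shared} eps_a(j) eps_b(j) sum_t H_{a,p}(t) H_{b,s}(t) dN_j(t)/Y_j(t)^2.

Blocks for disjoint pairs vanish (independent samples).  The plug-in matrix
need not be jointly positive semidefinite in finite samples, so the induced
correlation matrix is PSD-repaired (negative eigenvalues clipped, diagonal
rescaled to 1) before the Gaussian quantile is computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .contrasts import ContrastSet, default_weights
from .data import SurvivalData
from .pairwise import PairQuantities, pair_quantities, wlr_statistic, wlr_sigma
from .procedures import MCTPResults, _resolve_pairs

__all__ = [
    "JointWlr",
    "joint_wlr",
    "joint_covariance",
    "psd_repair_correlation",
    "equicoordinate_quantile",
    "multiweightedlr_test",
]


@dataclass(frozen=True)
class JointWlr:
    """All m*q weighted log-rank statistics with their joint covariance.

    Coordinates are ordered contrast-major, weight-minor: coordinate
    ``a*m + p`` is contrast ``pairs[a]`` with weight ``p``.
    """

    stats: np.ndarray  # (m*q,)
    sigma: np.ndarray  # (m*q, m*q)
    pairs: tuple
    m: int

    @property
    def q(self) -> int:
        return len(self.pairs)


def _weight_matrix(weights, x: np.ndarray) -> np.ndarray:
    return np.vstack([np.asarray(w(x)) for w in weights])


def _h_integrand(pq: PairQuantities, weights, idx: np.ndarray) -> np.ndarray:
    """``H_{a,p}`` evaluated at the grid indices ``idx`` of pair a."""
    y1, y2 = pq.y1[idx], pq.y2[idx]
    atrisk = np.where(y1 + y2 > 0, y1 * y2 / np.maximum(y1 + y2, 1.0), 0.0)
    return pq.scale * _weight_matrix(weights, pq.f_left[idx]) * atrisk


def joint_wlr(data: SurvivalData, contrasts: ContrastSet, weights=None) -> JointWlr:
    """Statistic vector and plug-in joint covariance for all contrasts."""
    weights = default_weights() if weights is None else tuple(weights)
    contrasts.validate_pairwise()
    m, q = len(weights), contrasts.q
    pqs = [pair_quantities(data, pair) for pair in contrasts.pairs]

    stats = np.empty(m * q)
    for a, (pair, pq) in enumerate(zip(contrasts.pairs, pqs)):
        for p, w in enumerate(weights):
            stats[a * m + p] = wlr_statistic(data, pair, w, pq)

    sigma = np.zeros((m * q, m * q))
    for a, (pair, pq) in enumerate(zip(contrasts.pairs, pqs)):
        sigma[a * m : (a + 1) * m, a * m : (a + 1) * m] = wlr_sigma(
            data, pair, weights, pq
        )

    # per-group event times, counts, and at-risk numbers (group's own sample)
    ev_times, ev_dn, ev_y = {}, {}, {}
    for j in range(data.k):
        mask = data.group_mask(j)
        tj = data.time[mask]
        te, dn = np.unique(tj[data.status[mask] == 1], return_counts=True)
        ev_times[j] = te
        ev_dn[j] = dn.astype(float)
        tg = np.sort(tj)
        ev_y[j] = tg.size - np.searchsorted(tg, te, side="left").astype(float)

    for a in range(q):
        for b in range(a + 1, q):
            shared = set(contrasts.pairs[a]) & set(contrasts.pairs[b])
            if not shared:
                continue
            block = np.zeros((m, m))
            for j in shared:
                te = ev_times[j]
                if te.size == 0:
                    continue
                idx_a = np.searchsorted(pqs[a].grid, te)
                idx_b = np.searchsorted(pqs[b].grid, te)
                Ha = _h_integrand(pqs[a], weights, idx_a)  # (m, T)
                Hb = _h_integrand(pqs[b], weights, idx_b)
                eps = (1.0 if j == contrasts.pairs[a][1] else -1.0) * (
                    1.0 if j == contrasts.pairs[b][1] else -1.0
                )
                incr = ev_dn[j] / ev_y[j] ** 2
                block += eps * np.einsum("pt,st,t->ps", Ha, Hb, incr)
            sigma[a * m : (a + 1) * m, b * m : (b + 1) * m] = block
            sigma[b * m : (b + 1) * m, a * m : (a + 1) * m] = block.T
    return JointWlr(stats=stats, sigma=sigma, pairs=contrasts.pairs, m=m)


def joint_covariance(data: SurvivalData, contrasts: ContrastSet, weights=None) -> np.ndarray:
    """The (m*q) x (m*q) plug-in covariance matrix alone."""
    return joint_wlr(data, contrasts, weights).sigma


def psd_repair_correlation(R: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues at zero and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh((R + R.T) / 2.0)
    if vals.min() >= 0:
        return R
    fixed = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-300, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _max_abs_cdf(c: float, R: np.ndarray, seed) -> float:
    """P(max_i |Z_i| <= c) for Z ~ N(0, R), randomized-lattice integration.

    The fixed seed makes the lattice deterministic; the point budget trades
    a ~2e-4 probability error (well inside the quantile tolerance) for speed.
    """
    d = R.shape[0]
    if c <= 0:
        return 0.0
    return float(
        sps.multivariate_normal.cdf(
            np.full(d, c),
            mean=np.zeros(d),
            cov=R,
            lower_limit=np.full(d, -c),
            allow_singular=True,
            maxpts=min(20_000 * d, 200_000),
            abseps=2e-4,
            releps=0.0,
            rng=np.random.default_rng(seed),
        )
    )


def equicoordinate_quantile(
    R: np.ndarray, alpha: float, tol: float = 1e-3, seed=None
) -> float:
    """Smallest c with ``P(max_i |Z_i| <= c) >= 1 - alpha``, Z ~ N(0, R).

    Rectangle probabilities come from deterministic randomized-lattice
    integration at a fixed seed; c is located by bisection to ``tol``.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if R.shape[0] == 1:
        return float(sps.norm.ppf(1.0 - alpha / 2.0))
    # Bonferroni sandwich: z_{1-alpha/2} <= c <= z_{1-alpha/(2d)}
    lo = float(sps.norm.ppf(1.0 - alpha / 2.0))
    hi = float(sps.norm.ppf(1.0 - alpha / (2.0 * R.shape[0])))
    if _max_abs_cdf(lo, R, seed) >= 1.0 - alpha:
        return lo
    while _max_abs_cdf(hi, R, seed) < 1.0 - alpha:  # numeric guard at the border
        hi += 4.0 * tol
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _max_abs_cdf(mid, R, seed) >= 1.0 - alpha:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def multiweightedlr_test(
    data: SurvivalData,
    contrasts: ContrastSet,
    weights=None,
    alpha: float = 0.05,
    seed=None,
    quantile_tol: float = 1e-3,
) -> MCTPResults:
    """MultiWeightedLR maximum test over all contrasts and weights.

    Each coordinate is studentized by its estimated standard deviation; the
    local statistic is the per-pair maximum absolute standardized value, the
    global statistic ``T_max`` their overall maximum, both compared to the
    shared equicoordinate (1-alpha)-quantile of the fitted Gaussian.
    Adjusted p-values are ``1 - P(max <= observed)`` under that Gaussian.
    Coordinates with zero estimated variance (no events in the pair) are
    dropped with a warning.
    """
    weights = default_weights() if weights is None else tuple(weights)
    labels = _resolve_pairs(data, contrasts)
    jw = joint_wlr(data, contrasts, weights)
    m, q = jw.m, jw.q
    var = np.diag(jw.sigma).copy()
    keep = var > 0
    if not keep.all():
        warnings.warn(
            f"{np.count_nonzero(~keep)} coordinate(s) with zero estimated "
            "variance (no events) dropped from the maximum test",
            UserWarning,
            stacklevel=2,
        )
    if not keep.any():
        pvals = np.ones(q)
        return MCTPResults(
            method="MultiWeightedLR",
            contrasts=contrasts,
            pair_labels=labels,
            statistics=np.zeros(q),
            pvalues=pvals,
            reject_local=np.zeros(q, dtype=bool),
            alpha=alpha,
            critical_value=None,
            info={"seed": seed, "note": "no events in any contrast"},
        )

    sd = np.sqrt(var[keep])
    z = jw.stats[keep] / sd
    R = jw.sigma[np.ix_(keep, keep)] / np.outer(sd, sd)
    np.fill_diagonal(R, 1.0)
    R = psd_repair_correlation(R)
    c = equicoordinate_quantile(R, alpha, tol=quantile_tol, seed=seed)

    coord_pair = np.repeat(np.arange(q), m)[keep]
    t_local = np.zeros(q)
    for a in range(q):
        sel = coord_pair == a
        t_local[a] = np.abs(z[sel]).max() if sel.any() else 0.0
    pvals = np.array(
        [
            min(max(1.0 - _max_abs_cdf(t, R, seed), np.finfo(float).tiny), 1.0)
            if t > 0
            else 1.0
            for t in t_local
        ]
    )
    return MCTPResults(
        method="MultiWeightedLR",
        contrasts=contrasts,
        pair_labels=labels,
        statistics=t_local,
        pvalues=pvals,
        reject_local=t_local > c,
        alpha=alpha,
        critical_value=c,
        info={"seed": seed, "weights": [w.name for w in weights], "t_max": float(t_local.max())},
    )
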