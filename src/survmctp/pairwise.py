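"""Two-sample weighted log-rank statistics and the multi-directional
(mdir) combination test — the computational core shared by every procedure
in this package.

For groups ``j1, j2`` with pooled pair size ``n = n_j1 + n_j2`` and a weight
``w``, the weighted log-rank statistic is

    T(w) = sqrt(n / (n_j1 n_j2)) * sum_t w(F_hat(t-))
           * Y_j1(t) Y_j2(t) / (Y_j1(t) + Y_j2(t))
           * (dA_hat_j2(t) - dA_hat_j1(t)),

summed over the event times of the pooled pair; ``F_hat`` is the pair-pooled
Kaplan–Meier CDF.  The covariance estimate between two weights ``w_p, w_s``
replaces the hazard-difference increment with the pair-pooled Nelson–Aalen
increment:

    Sigma[p, s] = n / (n_j1 n_j2) * sum_t w_p(F_hat(t-)) w_s(F_hat(t-))
                  * Y_j1 Y_j2 / (Y_j1 + Y_j2) * dA_hat_pooled(t).

The mdir statistic studentizes the vector of statistics for m linearly
independent weights through the Moore–Penrose inverse, ``Z = T' Sigma^- T``,
asymptotically chi-square with m degrees of freedom under the local null.
Because that approximation is anti-conservative in finite samples, the
default calibration is a pairwise permutation test (labels reshuffled within
the two groups being compared, preserving group sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .contrasts import WeightFunction
from .data import SurvivalData, build_counting, kaplan_meier

__all__ = [
    "WlrVector",
    "PairQuantities",
    "pair_quantities",
    "wlr_statistic",
    "wlr_sigma",
    "wlr_vector",
    "mdir_statistic",
    "mdir_chi2_pvalue",
    "mdir_permutation_pvalue",
]

#: singular values below ``m * sqrt(machine eps) * s_max`` are treated as
#: zero when pseudo-inverting an m x m covariance estimate.
PINV_RTOL_FACTOR = float(np.sqrt(np.finfo(float).eps))


def _pinv(mat: np.ndarray) -> np.ndarray:
    m = mat.shape[-1]
    return np.linalg.pinv(mat, rcond=m * PINV_RTOL_FACTOR, hermitian=True)


@dataclass(frozen=True)
class PairQuantities:
    """Everything a pairwise statistic needs, on the pair's event grid."""

    grid: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    dn1: np.ndarray
    dn2: np.ndarray
    f_left: np.ndarray  # pair-pooled Kaplan-Meier CDF, left limits
    n1: int
    n2: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    @property
    def scale(self) -> float:
        return float(np.sqrt(self.n / (self.n1 * self.n2)))


def pair_quantities(data: SurvivalData, pair: tuple) -> PairQuantities:
    """Risk sets, event counts and pooled-KM left limits for one pair."""
    j1, j2 = pair
    cp = build_counting(data, (j1, j2))
    if cp.sizes[0] == 0 or cp.sizes[1] == 0:
        raise ValueError(f"pair {pair} has an empty group")
    km = kaplan_meier(cp)
    # F_hat(t-) at grid point i is 1 - S_hat at the previous grid point.
    f_left = 1.0 - np.concatenate(([1.0], km.values[:-1]))
    return PairQuantities(
        grid=cp.grid,
        y1=cp.risk[0],
        y2=cp.risk[1],
        dn1=cp.events[0],
        dn2=cp.events[1],
        f_left=f_left,
        n1=int(cp.sizes[0]),
        n2=int(cp.sizes[1]),
    )


def wlr_statistic(
    data: SurvivalData, pair: tuple, w: WeightFunction, pq: PairQuantities | None = None
) -> float:
    """Weighted log-rank statistic ``T_{j1,j2}(w)`` (signed, not studentized)."""
    pq = pair_quantities(data, pair) if pq is None else pq
    if pq.grid.size == 0:
        return 0.0
    y = pq.y1 + pq.y2
    # Y1 Y2/(Y1+Y2) * (dN2/Y2 - dN1/Y1) == (Y1 dN2 - Y2 dN1)/(Y1+Y2);
    # the right-hand form needs no I{Y_j > 0} guard (dN_j = 0 forces it).
    contrib = (pq.y1 * pq.dn2 - pq.y2 * pq.dn1) / y
    return float(pq.scale * np.sum(np.asarray(w(pq.f_left)) * contrib))


def wlr_sigma(
    data: SurvivalData,
    pair: tuple,
    weights: Sequence[WeightFunction],
    pq: PairQuantities | None = None,
) -> np.ndarray:
    """Estimated m x m covariance of the weighted log-rank vector."""
    pq = pair_quantities(data, pair) if pq is None else pq
    m = len(weights)
    if pq.grid.size == 0:
        return np.zeros((m, m))
    y = pq.y1 + pq.y2
    var_term = pq.y1 * pq.y2 * (pq.dn1 + pq.dn2) / (y * y)
    W = np.vstack([np.asarray(w(pq.f_left)) for w in weights])
    return (pq.scale**2) * np.einsum("pt,st,t->ps", W, W, var_term)


@dataclass(frozen=True)
class WlrVector:
    """Vector of weighted log-rank statistics with its covariance estimate."""

    stats: np.ndarray  # (m,)
    sigma: np.ndarray  # (m, m)
    pair: tuple
    n: int

    def __post_init__(self):
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("covariance estimate must be symmetric")


def wlr_vector(
    data: SurvivalData, pair: tuple, weights: Sequence[WeightFunction]
) -> WlrVector:
    pq = pair_quantities(data, pair)
    stats = np.array([wlr_statistic(data, pair, w, pq) for w in weights])
    sigma = wlr_sigma(data, pair, weights, pq)
    return WlrVector(stats=stats, sigma=sigma, pair=tuple(pair), n=pq.n)


def mdir_statistic(v: WlrVector) -> float:
    """Studentized quadratic form ``Z = T' Sigma^- T`` (Moore–Penrose)."""
    z = float(v.stats @ _pinv(v.sigma) @ v.stats)
    return max(z, 0.0)


def mdir_chi2_pvalue(v: WlrVector) -> float:
    """Asymptotic chi-square_m p-value of the mdir statistic.

    Kept for reference; the permutation calibration is the default because
    the asymptotic one shows inflated type I errors in small samples.
    """
    return float(sps.chi2.sf(mdir_statistic(v), df=len(v.stats)))


def mdir_permutation_pvalue(
    data: SurvivalData,
    pair: tuple,
    weights: Sequence[WeightFunction],
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> tuple:
    """Permutation p-value of the mdir statistic for one pair.

    Group labels of the pooled pair are reshuffled ``n_perm`` times
    (preserving the group sizes), the quadratic form recomputed each time,
    and the add-one p-value ``(1 + #{Z* >= Z_obs}) / (n_perm + 1)`` returned
    together with ``Z_obs``.  The p-value is never 0 and never exceeds 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    j1, j2 = pair
    sel = np.isin(data.group, (j1, j2))
    t, d = data.time[sel], data.status[sel]
    z0 = (data.group[sel] == j1).astype(float)
    pq = pair_quantities(data, pair)
    m = len(weights)
    z_obs = mdir_statistic(wlr_vector(data, pair, weights))
    if pq.grid.size == 0:
        return 1.0, z_obs

    grid = pq.grid
    # subject-level indicators on the pooled grid: at-risk and event-at-t
    A = (t[None, :] >= grid[:, None]).astype(float)  # (G, n): X_i >= t_g
    E = ((t[None, :] == grid[:, None]) & (d[None, :] == 1)).astype(float)
    y = pq.y1 + pq.y2  # fixed under permutation
    dn = pq.dn1 + pq.dn2
    W = np.vstack([np.asarray(w(pq.f_left)) for w in weights])  # (m, G)
    scale2 = pq.scale**2

    member = np.tile(z0, (n_perm, 1))
    member = rng.permuted(member, axis=1).T  # (n, B)

    y1 = A @ member  # (G, B)
    dn1 = E @ member
    numer = y1 * dn[:, None] - y[:, None] * dn1  # Y1*dN - Y*dN1 == Y1 dN2 - Y2 dN1
    T = pq.scale * (W @ (numer / y[:, None]))  # (m, B)
    var_term = y1 * (y[:, None] - y1) * dn[:, None] / (y * y)[:, None]  # (G, B)
    Sig = scale2 * np.einsum("pg,sg,gb->bps", W, W, var_term)  # (B, m, m)
    pinvs = np.linalg.pinv(Sig, rcond=m * PINV_RTOL_FACTOR, hermitian=True)
    z_star = np.einsum("pb,bps,sb->b", T, pinvs, T)
    z_star = np.maximum(z_star, 0.0)

    p = (1.0 + np.count_nonzero(z_star >= z_obs - 1e-12)) / (n_perm + 1.0)
    return float(p), float(z_obs)
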