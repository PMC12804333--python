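"""multiCASANOVA: pooled-weight contrast statistics with wild-bootstrap
calibration of the maximum statistic.

In contrast to the pairwise procedures, every ingredient except the two
hazard increments is pooled over *all* k groups: with ``F_hat`` the
all-group Kaplan–Meier CDF and ``Y(t)`` the total number at risk,

    T_tilde_{j1,j2}(w) = sqrt(n/(n_j1 n_j2)) * sum_t w(F_hat(t-))
                         * Y_j1(t) Y_j2(t) / Y(t)
                         * (dA_hat_j2(t) - dA_hat_j1(t)),

    Cov_hat[p, s] = n/(n_j1 n_j2) * sum_t w_p(F_hat(t-)) w_s(F_hat(t-))
                    * Y_j1 Y_j2 / Y(t) * dA_hat(t),

with ``dA_hat`` the all-group pooled Nelson–Aalen increment and
``n = n_j1 + n_j2``.  The per-contrast Wald statistic is
``C_{j1,j2} = T_tilde' Cov_hat^- T_tilde`` and the global statistic the
maximum ``C_max`` over contrasts (the weights are already combined inside
each quadratic form, so no maximum over weights is taken).

Calibration uses the wild bootstrap for counting processes: every subject
receives an i.i.d. multiplier ``G_ji`` with mean 0 and variance 1
(Rademacher or centered Poisson — counting processes are discrete, so the
multiplier laws are too), giving the bootstrap Nelson–Aalen process

    A*_j(t) = sum_{s <= t} ( sum_{i: X_ji = s, delta_ji = 1} G_ji ) / Y_j(s).

Bootstrap statistics ``T_tilde*`` replace ``dA_hat_j2 - dA_hat_j1`` with
``dA*_j2 - dA*_j1`` while the data-based ``Cov_hat`` stays fixed; the
critical value is the empirical (1-alpha)-quantile of the bootstrap
``C*_max`` sample, shared by the global and all local decisions.
Multipliers are drawn once per subject per bootstrap replication and shared
across contrasts, preserving the joint dependence between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .contrasts import ContrastSet, default_weights
from .data import SurvivalData, StepEstimate, build_counting, kaplan_meier
from .pairwise import _pinv
from .procedures import MCTPResults, _resolve_pairs

__all__ = [
    "CasanovaStat",
    "casanova_statistic",
    "wild_bootstrap_na",
    "multicasanova_test",
    "MULTIPLIERS",
]


def _rademacher(rng, shape):
    return rng.integers(0, 2, size=shape).astype(float) * 2.0 - 1.0


def _centered_poisson(rng, shape):
    return rng.poisson(1.0, size=shape).astype(float) - 1.0


MULTIPLIERS = {"rademacher": _rademacher, "poisson": _centered_poisson}


class _PooledQuantities:
    """All-group counting processes and pooled estimators on the joint grid."""

    def __init__(self, data: SurvivalData):
        cp = build_counting(data, tuple(range(data.k)))
        self.grid = cp.grid
        self.risk = cp.risk  # (k, G)
        self.events = cp.events
        self.risk_total = cp.risk_total
        self.events_total = cp.events_total
        self.sizes = cp.sizes
        km = kaplan_meier(cp)
        self.f_left = 1.0 - np.concatenate(([1.0], km.values[:-1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            self.da_pooled = np.where(
                self.risk_total > 0,
                self.events_total / np.maximum(self.risk_total, 1.0),
                0.0,
            )


@dataclass(frozen=True)
class CasanovaStat:
    """Pooled contrast statistic vector, its covariance, and the Wald form."""

    pair: tuple
    t_vector: np.ndarray  # (m,)
    cov: np.ndarray  # (m, m)
    C: float


def casanova_statistic(
    data: SurvivalData,
    pair: tuple,
    weights=None,
    pooled: _PooledQuantities | None = None,
) -> CasanovaStat:
    """Pooled contrast statistic ``T_tilde``, ``Cov_hat`` and ``C`` for one pair.

    All k groups enter through the pooled CDF, the total at-risk process and
    the pooled Nelson–Aalen increment; for ``k = 2`` the result coincides
    exactly with the pairwise mdir quantities.
    """
    weights = default_weights() if weights is None else tuple(weights)
    pooled = _PooledQuantities(data) if pooled is None else pooled
    j1, j2 = pair
    if not (0 <= j1 < data.k and 0 <= j2 < data.k):
        raise KeyError(f"pair {pair} outside group codes 0..{data.k - 1}")
    n1, n2 = int(pooled.sizes[j1]), int(pooled.sizes[j2])
    if n1 == 0 or n2 == 0:
        raise ValueError(f"pair {pair} has an empty group")
    m = len(weights)
    if pooled.grid.size == 0:
        return CasanovaStat(tuple(pair), np.zeros(m), np.zeros((m, m)), 0.0)
    scale = np.sqrt((n1 + n2) / (n1 * n2))
    y1, y2 = pooled.risk[j1], pooled.risk[j2]
    dn1, dn2 = pooled.events[j1], pooled.events[j2]
    y = pooled.risk_total
    contrib = (y1 * dn2 - y2 * dn1) / y
    t_vec = np.array(
        [float(scale * np.sum(np.asarray(w(pooled.f_left)) * contrib)) for w in weights]
    )
    var_term = y1 * y2 * pooled.events_total / (y * y)
    W = np.vstack([np.asarray(w(pooled.f_left)) for w in weights])
    cov = (scale**2) * np.einsum("pt,st,t->ps", W, W, var_term)
    C = max(float(t_vec @ _pinv(cov) @ t_vec), 0.0)
    return CasanovaStat(tuple(pair), t_vec, cov, C)


def wild_bootstrap_na(
    data: SurvivalData, group: int, multipliers: Sequence[float]
) -> StepEstimate:
    """Wild-bootstrap Nelson–Aalen process ``A*_j`` for one group.

    ``multipliers`` holds one value per subject of the group, aligned with
    the subjects' order of appearance in ``data``.  Censored subjects
    contribute nothing; with all multipliers 1 the ordinary Nelson–Aalen
    estimator is recovered, with all 0 the process is identically zero.
    """
    mask = data.group_mask(group)
    g = np.asarray(multipliers, dtype=float)
    if g.shape != (int(mask.sum()),):
        raise ValueError(
            f"need one multiplier per subject of group {group} "
            f"({int(mask.sum())}), got {g.shape}"
        )
    t = data.time[mask]
    d = data.status[mask]
    te = np.unique(t[d == 1])
    tg = np.sort(t)
    y = tg.size - np.searchsorted(tg, te, side="left").astype(float)
    g_sum = np.zeros(te.size)
    ev = d == 1
    np.add.at(g_sum, np.searchsorted(te, t[ev]), g[ev])
    return StepEstimate(te, np.cumsum(g_sum / y), initial=0.0)


def multicasanova_test(
    data: SurvivalData,
    contrasts: ContrastSet,
    weights=None,
    multiplier: str = "rademacher",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> MCTPResults:
    """multiCASANOVA wild-bootstrap test over pairwise contrasts.

    Rejects locally where ``C_{j1,j2} > q*`` and globally where
    ``C_max > q*``, with ``q*`` the empirical (1-alpha)-quantile (order
    statistic ``ceil((1-alpha) n_boot)``) of the bootstrap ``C*_max``
    sample.  Reported p-values are the add-one bootstrap tail fractions
    ``(1 + #{C*_max >= C}) / (n_boot + 1)`` — descriptive companions to the
    quantile rule.
    """
    if multiplier not in MULTIPLIERS:
        raise ValueError(
            f"unknown multiplier {multiplier!r}; choose from {sorted(MULTIPLIERS)}"
        )
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    weights = default_weights() if weights is None else tuple(weights)
    labels = _resolve_pairs(data, contrasts)
    m, q = len(weights), contrasts.q
    pooled = _PooledQuantities(data)
    rng = np.random.default_rng(seed)

    stats = [casanova_statistic(data, pair, weights, pooled) for pair in contrasts.pairs]
    c_obs = np.array([s.C for s in stats])
    pinvs = np.stack([_pinv(s.cov) for s in stats])  # (q, m, m)

    # bootstrap: T*[a, p] = sum_i K[a, p, i] G_i with one coefficient per
    # event subject shared across replications
    n_tot = data.n_total
    K = np.zeros((q, m, n_tot))
    W = np.vstack([np.asarray(w(pooled.f_left)) for w in weights])  # (m, G)
    for a, (j1, j2) in enumerate(contrasts.pairs):
        n1, n2 = int(pooled.sizes[j1]), int(pooled.sizes[j2])
        scale = np.sqrt((n1 + n2) / (n1 * n2))
        base = scale * W * (pooled.risk[j1] * pooled.risk[j2] / pooled.risk_total)
        for j, eps in ((j1, -1.0), (j2, 1.0)):
            mask = data.group_mask(j) & (data.status == 1)
            if not mask.any():
                continue
            idx = np.searchsorted(pooled.grid, data.time[mask])
            K[a, :, mask] = (eps * base[:, idx] / pooled.risk[j][idx]).T

    G = MULTIPLIERS[multiplier](rng, (n_tot, n_boot))
    t_star = K.reshape(q * m, n_tot) @ G  # (q*m, B)
    t_star = t_star.reshape(q, m, n_boot)
    c_star = np.einsum("apb,aps,asb->ab", t_star, pinvs, t_star)
    c_max_star = np.clip(c_star, 0.0, None).max(axis=0)  # (B,)

    order = int(np.ceil((1.0 - alpha) * n_boot)) - 1
    q_star = float(np.sort(c_max_star)[order])
    pvals = (1.0 + (c_max_star[None, :] >= c_obs[:, None] - 1e-12).sum(axis=1)) / (
        n_boot + 1.0
    )
    return MCTPResults(
        method=f"multiCASANOVA ({multiplier})",
        contrasts=contrasts,
        pair_labels=labels,
        statistics=c_obs,
        pvalues=pvals,
        reject_local=c_obs > q_star,
        alpha=alpha,
        critical_value=q_star,
        info={
            "n_boot": n_boot,
            "multiplier": multiplier,
            "seed": seed,
            "c_max": float(c_obs.max()),
            "weights": [w.name for w in weights],
        },
    )
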