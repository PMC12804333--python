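"""Bonferroni-adjusted reference procedures and the shared results object.

Both reference methods test every pairwise contrast locally and declare a
global difference as soon as the smallest local p-value undercuts the
Bonferroni-adjusted level ``alpha / q``:

* **adjusted log-rank** — per pair the classical (optionally Fleming–
  Harrington-weighted) log-rank chi-square with 1 df;
* **adjusted mdir** — per pair the multi-directional combination of several
  weighted log-rank statistics, calibrated by a pairwise permutation test.

:class:`MCTPResults` is the results object every procedure in this package
returns (including the maximum-type tests in :mod:`survmctp.maxtest` and
:mod:`survmctp.casanova`); it carries per-contrast statistics, p-values,
decisions, and renders a summary table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contrasts import ContrastSet, WeightFunction, default_weights, log_rank_weight
from .data import SurvivalData
from .pairwise import mdir_permutation_pvalue, wlr_sigma, wlr_statistic, pair_quantities

__all__ = [
    "MCTPResults",
    "bonferroni_level",
    "adjusted_logrank_test",
    "adjusted_mdir_test",
]


@dataclass
class MCTPResults:
    """Simultaneous test decisions for a family of pairwise contrasts.

    Attributes
    ----------
    method : str
        Procedure name.
    contrasts : ContrastSet
        The tested contrast family (0-based group codes).
    pair_labels : list of tuple
        The same pairs in the caller's original group labels.
    statistics : ndarray
        One local test statistic per contrast (chi-square-type quadratic
        form, or the per-pair maximum of standardized statistics).
    pvalues : ndarray
        Local p-values in (0, 1]; for quantile-calibrated methods these are
        multiplicity-adjusted by construction.
    reject_local : ndarray of bool
    reject_global : bool
        True iff at least one local rejection.
    alpha : float
        Global significance level.
    local_threshold : float or None
        Bonferroni level alpha/q when p-values are compared to it.
    critical_value : float or None
        Shared critical value (equicoordinate quantile or bootstrap
        quantile) when statistics are compared to it.
    info : dict
        Resampling diagnostics: seeds, replication counts, multiplier law.
    """

    method: str
    contrasts: ContrastSet
    pair_labels: list
    statistics: np.ndarray
    pvalues: np.ndarray
    reject_local: np.ndarray
    alpha: float
    local_threshold: float | None = None
    critical_value: float | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.statistics = np.asarray(self.statistics, dtype=float)
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.reject_local = np.asarray(self.reject_local, dtype=bool)
        if np.any((self.pvalues <= 0) | (self.pvalues > 1)):
            raise ValueError("p-values must lie in (0, 1]")

    @property
    def reject_global(self) -> bool:
        return bool(self.reject_local.any())

    @property
    def q(self) -> int:
        return self.contrasts.q

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-contrast table (one row per local test)."""
        return pd.DataFrame(
            {
                "contrast": [f"{a} vs {b}" for a, b in self.pair_labels],
                "statistic": self.statistics,
                "p_value": self.pvalues,
                "reject": self.reject_local,
            }
        )

    def summary(self) -> str:
        """Human-readable report, 4 significant digits."""
        lines = [
            f"Multiple contrast test: {self.method}",
            f"contrasts: {self.contrasts.kind} (q = {self.q}), alpha = {self.alpha:.4g}",
        ]
        if self.local_threshold is not None:
            lines.append(f"Bonferroni-adjusted local level: {self.local_threshold:.4g}")
        if self.critical_value is not None:
            lines.append(f"critical value: {self.critical_value:.4g}")
        for key in ("n_perm", "n_boot", "multiplier", "seed"):
            if key in self.info and self.info[key] is not None:
                lines.append(f"{key}: {self.info[key]}")
        lines.append("-" * 56)
        lines.append(f"{'contrast':<18}{'statistic':>12}{'p-value':>12}{'reject':>8}")
        for (a, b), s, p, r in zip(
            self.pair_labels, self.statistics, self.pvalues, self.reject_local
        ):
            lines.append(f"{f'{a} vs {b}':<18}{s:>12.4g}{p:>12.4g}{'yes' if r else 'no':>8}")
        lines.append("-" * 56)
        lines.append(f"global null rejected: {'yes' if self.reject_global else 'no'}")
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"<MCTPResults {self.method}: q={self.q}, "
            f"global reject={self.reject_global}>"
        )


def bonferroni_level(alpha: float, q: int) -> float:
    """Bonferroni-adjusted local significance level ``alpha / q``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if q < 1:
        raise ValueError("q must be a positive integer")
    return alpha / q


def _resolve_pairs(data: SurvivalData, contrasts: ContrastSet) -> list:
    contrasts.validate_pairwise()
    if contrasts.k != data.k:
        raise ValueError(
            f"contrast matrix has k={contrasts.k} columns but data has {data.k} groups"
        )
    return [(data.labels[j1], data.labels[j2]) for j1, j2 in contrasts.pairs]


def adjusted_logrank_test(
    data: SurvivalData,
    contrasts: ContrastSet,
    w: WeightFunction | None = None,
    alpha: float = 0.05,
) -> MCTPResults:
    """Bonferroni-adjusted (weighted) log-rank test over pairwise contrasts.

    Per contrast the studentized statistic ``T(w)^2 / Sigma_hat`` is compared
    to the chi-square distribution with 1 df; local rejection at
    ``p < alpha/q``.  With ``q = 1`` this is the plain two-sample log-rank
    test at level ``alpha``.
    """
    w = log_rank_weight() if w is None else w
    labels = _resolve_pairs(data, contrasts)
    thr = bonferroni_level(alpha, contrasts.q)
    stat = np.empty(contrasts.q)
    pval = np.empty(contrasts.q)
    for a, pair in enumerate(contrasts.pairs):
        pq = pair_quantities(data, pair)
        t = wlr_statistic(data, pair, w, pq)
        s2 = wlr_sigma(data, pair, (w,), pq)[0, 0]
        stat[a] = t * t / s2 if s2 > 0 else 0.0
        pval[a] = sps.chi2.sf(stat[a], df=1) if s2 > 0 else 1.0
    return MCTPResults(
        method="adjusted log-rank",
        contrasts=contrasts,
        pair_labels=labels,
        statistics=stat,
        pvalues=pval,
        reject_local=pval < thr,
        alpha=alpha,
        local_threshold=thr,
        info={"weight": w.name},
    )


def adjusted_mdir_test(
    data: SurvivalData,
    contrasts: ContrastSet,
    weights=None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> MCTPResults:
    """Bonferroni-adjusted multi-directional log-rank test.

    Per contrast the mdir quadratic form is calibrated by permuting labels
    within the two compared groups (``n_perm`` permutations, add-one
    p-value); local rejection at ``p < alpha/q``.  Each pair draws its
    permutations from an independent stream spawned deterministically from
    ``seed``, so results are reproducible and order-independent.
    """
    weights = default_weights() if weights is None else tuple(weights)
    labels = _resolve_pairs(data, contrasts)
    thr = bonferroni_level(alpha, contrasts.q)
    if 1.0 / (n_perm + 1.0) >= thr:
        warnings.warn(
            f"smallest achievable permutation p-value 1/(n_perm+1) = "
            f"{1.0 / (n_perm + 1):.4g} is not below the Bonferroni level "
            f"{thr:.4g}; no rejection is possible — increase n_perm",
            UserWarning,
            stacklevel=2,
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(contrasts.q)
    stat = np.empty(contrasts.q)
    pval = np.empty(contrasts.q)
    for a, pair in enumerate(contrasts.pairs):
        p, z = mdir_permutation_pvalue(
            data, pair, weights, n_perm=n_perm, rng=np.random.default_rng(streams[a])
        )
        stat[a], pval[a] = z, p
    return MCTPResults(
        method="adjusted mdir",
        contrasts=contrasts,
        pair_labels=labels,
        statistics=stat,
        pvalues=pval,
        reject_local=pval < thr,
        alpha=alpha,
        local_threshold=thr,
        info={"n_perm": n_perm, "seed": seed, "weights": [w.name for w in weights]},
    )
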