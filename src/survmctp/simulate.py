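"""Scenario generator and Monte-Carlo harness for FWER/power studies.

The built-in four-group scenarios span the hazard relationships the test
procedures are meant to distinguish:

* ``prop`` — proportional hazards: Exponential rates 1.2, 1.8, 2.3, 2.9;
* ``nprop`` — non-proportional, non-crossing: Lognormal(2.2, 1.7),
  (2.6, 1.6), (3.5, 1.7), (4.5, 1.6) (mean / sd of log time);
* ``cross`` — crossing hazards: Weibull shapes 1.5, 2.5, 3.5, 4.5 at
  common scale 5;
* ``mix`` — Lognormal(2.3, 1.7), Exponential(0.05), Weibull(2.4, 11.7),
  Lognormal(3, 1.6);
* ``null`` — global null: all four groups Exponential(1.2).

Parameter conventions follow the standard statistical-software reading:
Exponential(rate), Lognormal(mean, sd of log-time), Weibull(shape, scale).
Group size defaults to 100 per group.  Censoring is uniform on ``(0, u)``
with ``u`` calibrated per group law by numeric root finding so that
``P(C < T)`` hits the requested target rate (0–30% in the study design);
target 0 means no censoring.

Runs are seeded through a spawned `numpy.random.SeedSequence` tree, so a
study is exactly reproducible from its master seed and independent of
execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy import stats as sps

from .casanova import multicasanova_test
from .contrasts import ContrastSet, make_contrasts
from .data import SurvivalData
from .maxtest import multiweightedlr_test
from .procedures import adjusted_logrank_test, adjusted_mdir_test

__all__ = [
    "Distribution",
    "distribution",
    "Scenario",
    "scenario",
    "calibrate_censoring",
    "sample_scenario",
    "run_study",
    "MonteCarloReport",
    "METHODS",
    "binomial_band",
]


@dataclass(frozen=True)
class Distribution:
    """A parametric survival law used by the scenario generator."""

    family: str
    params: tuple

    def __post_init__(self):
        if self.family not in ("exponential", "lognormal", "weibull"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            (rate,) = self.params
            return rng.exponential(1.0 / rate, size)
        if self.family == "lognormal":
            mu, sigma = self.params
            return rng.lognormal(mu, sigma, size)
        shape, scale = self.params
        return scale * rng.weibull(shape, size)

    def sf(self, t):
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            (rate,) = self.params
            return np.exp(-rate * t)
        if self.family == "lognormal":
            mu, sigma = self.params
            return sps.norm.sf((np.log(np.maximum(t, 1e-300)) - mu) / sigma)
        shape, scale = self.params
        return np.exp(-((t / scale) ** shape))

    def hazard(self, t):
        """Hazard rate alpha(t) = f(t) / S(t), for scenario diagnostics."""
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            (rate,) = self.params
            return np.full_like(t, rate)
        if self.family == "lognormal":
            mu, sigma = self.params
            z = (np.log(t) - mu) / sigma
            return sps.norm.pdf(z) / (t * sigma * sps.norm.sf(z))
        shape, scale = self.params
        return (shape / scale) * (t / scale) ** (shape - 1.0)

    def __str__(self):  # pragma: no cover - cosmetic
        return f"{self.family}{self.params}"


def distribution(family: str, *params: float) -> Distribution:
    return Distribution(family.lower(), params)


_SCENARIO_LAWS = {
    "prop": (
        distribution("exponential", 1.2),
        distribution("exponential", 1.8),
        distribution("exponential", 2.3),
        distribution("exponential", 2.9),
    ),
    "nprop": (
        distribution("lognormal", 2.2, 1.7),
        distribution("lognormal", 2.6, 1.6),
        distribution("lognormal", 3.5, 1.7),
        distribution("lognormal", 4.5, 1.6),
    ),
    "cross": (
        distribution("weibull", 1.5, 5),
        distribution("weibull", 2.5, 5),
        distribution("weibull", 3.5, 5),
        distribution("weibull", 4.5, 5),
    ),
    "mix": (
        distribution("lognormal", 2.3, 1.7),
        distribution("exponential", 0.05),
        distribution("weibull", 2.4, 11.7),
        distribution("lognormal", 3, 1.6),
    ),
    "null": (distribution("exponential", 1.2),) * 4,
}


@dataclass(frozen=True)
class Scenario:
    """A simulation setting: one survival law per group plus censoring."""

    name: str
    distributions: tuple
    n_per_group: tuple
    censoring: float = 0.0
    contrast_kind: str = "tukey"

    def __post_init__(self):
        if not 0.0 <= self.censoring < 1.0:
            raise ValueError("censoring target must lie in [0, 1)")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("group sizes must be >= 1")
        if len(self.n_per_group) != len(self.distributions):
            raise ValueError("one group size per distribution required")

    @property
    def k(self) -> int:
        return len(self.distributions)

    def null_mask(self, contrasts: ContrastSet) -> np.ndarray:
        """True for contrasts whose two groups share an identical law."""
        return np.array(
            [self.distributions[j1] == self.distributions[j2] for j1, j2 in contrasts.pairs]
        )


def scenario(
    name: str,
    n: int | Sequence[int] = 100,
    censoring: float = 0.0,
    contrast_kind: str = "tukey",
) -> Scenario:
    """A named built-in scenario; ``n`` is per group (scalar or sequence)."""
    key = name.lower()
    if key not in _SCENARIO_LAWS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_SCENARIO_LAWS)}")
    laws = _SCENARIO_LAWS[key]
    sizes = tuple([int(n)] * len(laws)) if np.isscalar(n) else tuple(int(v) for v in n)
    return Scenario(key, laws, sizes, censoring, contrast_kind)


_CENSOR_CACHE: dict = {}


def calibrate_censoring(dist: Distribution, target: float) -> float | None:
    """Upper bound u of the Uniform(0, u) censoring law hitting ``target``.

    Solves ``P(C < T) = (1/u) * int_0^u S(t) dt = target`` by bracketed root
    finding; the left side decreases from 1 (u -> 0) to 0 (u -> inf), so the
    root is unique.  Returns None (no censoring) for target 0.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("censoring target must lie in [0, 1)")
    if target == 0.0:
        return None
    key = (dist, round(target, 12))
    if key in _CENSOR_CACHE:
        return _CENSOR_CACHE[key]

    def prob_censored(u: float) -> float:
        val, _ = integrate.quad(dist.sf, 0.0, u, limit=200)
        return val / u

    lo, hi = 1e-6, 1.0
    for _ in range(200):
        if prob_censored(hi) < target:
            break
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the censoring calibration root")
    u = optimize.brentq(lambda v: prob_censored(v) - target, lo, hi, xtol=1e-8)
    _CENSOR_CACHE[key] = u
    return u


def sample_scenario(s: Scenario, rng: np.random.Generator | int | None = None) -> SurvivalData:
    """Draw one dataset: T from the group law, C ~ Uniform(0, u), X = min."""
    rng = np.random.default_rng(rng)
    times, status, group = [], [], []
    for j, (dist, nj) in enumerate(zip(s.distributions, s.n_per_group)):
        t = dist.rvs(rng, nj)
        if s.censoring > 0:
            u = calibrate_censoring(dist, s.censoring)
            c = rng.uniform(0.0, u, nj)
            x = np.minimum(t, c)
            d = (t <= c).astype(int)
        else:
            x, d = t, np.ones(nj, dtype=int)
        times.append(x)
        status.append(d)
        group.append(np.full(nj, j + 1))
    return SurvivalData.from_arrays(
        np.concatenate(times), np.concatenate(status), np.concatenate(group)
    )


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------


def _run_logrank(data, contrasts, alpha, n_resample, seed):
    return adjusted_logrank_test(data, contrasts, alpha=alpha)


def _run_mdir(data, contrasts, alpha, n_resample, seed):
    return adjusted_mdir_test(data, contrasts, n_perm=n_resample, alpha=alpha, seed=seed)


def _run_maxlr(data, contrasts, alpha, n_resample, seed):
    return multiweightedlr_test(data, contrasts, alpha=alpha, seed=seed)


def _run_casanova_rade(data, contrasts, alpha, n_resample, seed):
    return multicasanova_test(
        data, contrasts, multiplier="rademacher", n_boot=n_resample, alpha=alpha, seed=seed
    )


def _run_casanova_pois(data, contrasts, alpha, n_resample, seed):
    return multicasanova_test(
        data, contrasts, multiplier="poisson", n_boot=n_resample, alpha=alpha, seed=seed
    )


METHODS: dict[str, Callable] = {
    "adjusted-logrank": _run_logrank,
    "adjusted-mdir": _run_mdir,
    "multiweightedlr": _run_maxlr,
    "multicasanova-rademacher": _run_casanova_rade,
    "multicasanova-poisson": _run_casanova_pois,
}


def binomial_band(nominal: float, runs: int, level: float = 0.95) -> tuple:
    """Binomial precision interval around a nominal rejection rate."""
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(nominal * (1.0 - nominal) / runs)
    return (nominal - half, nominal + half)


@dataclass
class MonteCarloReport:
    """Rejection-rate summary of a simulation study."""

    scenario: Scenario
    contrasts: ContrastSet
    methods: tuple
    runs: int
    n_resample: int
    alpha: float
    master_seed: object
    null_mask: np.ndarray
    fwer: dict = field(default_factory=dict)  # method -> rate or None
    global_rate: dict = field(default_factory=dict)
    local_rates: dict = field(default_factory=dict)  # method -> (q,) array

    @property
    def band(self) -> tuple:
        return binomial_band(self.alpha, self.runs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for meth in self.methods:
            for a, (j1, j2) in enumerate(self.contrasts.pairs):
                rows.append(
                    {
                        "method": meth,
                        "contrast": f"{j1 + 1} vs {j2 + 1}",
                        "null": bool(self.null_mask[a]),
                        "rejection_rate": self.local_rates[meth][a],
                    }
                )
            rows.append(
                {
                    "method": meth,
                    "contrast": "global",
                    "null": bool(self.null_mask.all()),
                    "rejection_rate": self.global_rate[meth],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lo, hi = self.band
        lines = [
            f"Monte-Carlo study: scenario '{self.scenario.name}', "
            f"{self.contrasts.kind} contrasts, k={self.scenario.k}",
            f"runs={self.runs}, resampling={self.n_resample}, alpha={self.alpha:.4g}, "
            f"seed={self.master_seed}",
            f"binomial precision band around nominal: [{100 * lo:.2f}%, {100 * hi:.2f}%]",
            "-" * 64,
        ]
        for meth in self.methods:
            fw = self.fwer[meth]
            fw_s = f"{100 * fw:6.2f}%" if fw is not None else "   n/a"
            lines.append(
                f"{meth:<26} FWER {fw_s}   global {100 * self.global_rate[meth]:6.2f}%"
            )
        lines.append("-" * 64)
        return "\n".join(lines)


def run_study(
    s: Scenario,
    methods: Sequence[str] = ("adjusted-logrank",),
    runs: int = 1000,
    n_resample: int = 1000,
    alpha: float = 0.05,
    master_seed=None,
    contrasts: ContrastSet | None = None,
) -> MonteCarloReport:
    """Simulate ``runs`` datasets and estimate FWER / local power per method.

    FWER is the fraction of runs with at least one rejection among
    *true-null* contrasts (both groups share an identical law); local power
    is the per-contrast rejection fraction.  Every run draws its data and
    every method its resampling stream from independently spawned seeds, so
    the report is reproducible from ``master_seed`` alone.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    unknown = [meth for meth in methods if meth not in METHODS]
    if unknown:
        raise ValueError(f"unknown method(s) {unknown}; choose from {sorted(METHODS)}")
    contrasts = make_contrasts(s.contrast_kind, s.k) if contrasts is None else contrasts
    null_mask = s.null_mask(contrasts)
    children = np.random.SeedSequence(master_seed).spawn(runs)
    q = contrasts.q
    local = {meth: np.zeros(q) for meth in methods}
    any_null = {meth: 0 for meth in methods}
    any_all = {meth: 0 for meth in methods}

    for r in range(runs):
        streams = children[r].spawn(1 + len(methods))
        data = sample_scenario(s, np.random.default_rng(streams[0]))
        for i, meth in enumerate(methods):
            res = METHODS[meth](data, contrasts, alpha, n_resample, streams[1 + i])
            rej = res.reject_local
            local[meth] += rej
            any_all[meth] += bool(rej.any())
            if null_mask.any():
                any_null[meth] += bool(rej[null_mask].any())

    report = MonteCarloReport(
        scenario=s,
        contrasts=contrasts,
        methods=tuple(methods),
        runs=runs,
        n_resample=n_resample,
        alpha=alpha,
        master_seed=master_seed,
        null_mask=null_mask,
    )
    for meth in methods:
        report.local_rates[meth] = local[meth] / runs
        report.global_rate[meth] = any_all[meth] / runs
        report.fwer[meth] = any_null[meth] / runs if null_mask.any() else None
    return report
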