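"""Grouped right-censored survival data, counting processes, and the
nonparametric step estimators every test in this package consumes.

The data model is the classical k-sample one: in group ``j`` we observe
``X_ji = min(T_ji, C_ji)`` (event time censored by an independent censoring
time) together with the event indicator ``delta_ji = I(X_ji = T_ji)``.  All
test statistics are built from the per-group counting processes

* ``N_j(t)`` — cumulative number of observed events in group ``j`` up to ``t``
* ``Y_j(t)`` — number at risk in group ``j`` just before ``t``

and from the Nelson–Aalen estimator of the cumulative hazard,
``A_hat_j(t) = sum_{s<=t} dN_j(s)/Y_j(s)``, and the Kaplan–Meier survival
estimator of the (pair- or all-group) pooled sample.

Tie convention: the underlying distributions are assumed continuous, so ties
are a finite-precision artifact; at a tied time, events are counted in ``dN``
while censored subjects with the same recorded time remain in the risk set
(``Y_j(t)`` counts ``X >= t``).  This is the standard convention and is what
``Y_j(t) = #{X_ji >= t}`` yields automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalData",
    "CountingProcesses",
    "StepEstimate",
    "build_counting",
    "nelson_aalen",
    "kaplan_meier",
    "read_table",
]


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored observations from ``k >= 1`` groups.

    Parameters
    ----------
    time : ndarray of float
        Observed times ``X_ji``; strictly positive.
    status : ndarray of int
        Event indicators ``delta_ji``; 1 = event observed, 0 = censored.
    group : ndarray of int
        Internal group codes ``0..k-1`` (first-appearance order of the
        original labels).
    labels : tuple
        Original group labels, ``labels[code]`` recovers the user's label.
    """

    time: np.ndarray
    status: np.ndarray
    group: np.ndarray
    labels: tuple = field(default=())

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        group = np.asarray(self.group)
        if time.ndim != 1 or time.shape != status.shape or time.shape != group.shape:
            raise ValueError("time, status and group must be 1-d arrays of equal length")
        if time.size == 0:
            raise ValueError("empty dataset")
        if not np.all(time > 0):
            raise ValueError("all observed times must be strictly positive")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must be coded 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int8))
        object.__setattr__(self, "group", group.astype(np.intp))
        labels = self.labels if self.labels else tuple(range(int(group.max()) + 1))
        object.__setattr__(self, "labels", tuple(labels))
        k = len(self.labels)
        counts = np.bincount(self.group, minlength=k)
        if self.group.min() < 0 or self.group.max() >= k or (counts == 0).any():
            raise ValueError("every group code in 0..k-1 must be non-empty")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        time: Sequence[float],
        status: Sequence[int],
        group: Sequence[Hashable],
    ) -> "SurvivalData":
        """Build from raw columns; group labels may be arbitrary hashables
        and are mapped to codes in first-appearance order."""
        group = np.asarray(group)
        labels = list(dict.fromkeys(group.tolist()))
        lut = {lab: i for i, lab in enumerate(labels)}
        codes = np.fromiter((lut[g] for g in group.tolist()), dtype=np.intp, count=len(group))
        return cls(np.asarray(time, float), np.asarray(status), codes, tuple(labels))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time: str = "time",
        status: str = "status",
        group: str = "group",
    ) -> "SurvivalData":
        missing = [c for c in (time, status, group) if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s) {missing}; available: {list(df.columns)}")
        return cls.from_arrays(df[time].to_numpy(), df[status].to_numpy(), df[group].to_numpy())

    # -- derived quantities ------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def n_total(self) -> int:
        return self.time.size

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.k)

    def group_mask(self, code: int) -> np.ndarray:
        return self.group == code

    def code_of(self, label: Hashable) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown group label {label!r}; known: {list(self.labels)}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "status": self.status.astype(int),
                "group": np.asarray(self.labels, dtype=object)[self.group],
            }
        )


def read_table(
    path,
    delimiter: str = ",",
    time: str = "time",
    status: str = "status",
    group: str = "group",
    flip_status: bool = False,
) -> SurvivalData:
    """Read delimited text with a header row into a :class:`SurvivalData`.

    ``flip_status`` accepts the opposite coding (0 = event, 1 = censored)
    and flips it on input.
    """
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in (time, status, group) if c not in df.columns]
    if missing:
        raise ValueError(
            f"input file lacks required column(s) {missing}; found {list(df.columns)}"
        )
    bad = df.index[
        df[time].isna() | df[status].isna() | df[group].isna() | ~df[status].isin((0, 1))
    ]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"malformed rows at line(s) {lines}")
    if flip_status:
        df = df.assign(**{status: 1 - df[status]})
    return SurvivalData.from_dataframe(df, time=time, status=status, group=group)


# ---------------------------------------------------------------------------
# counting processes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountingProcesses:
    """Risk sets and event counts of a (sub)sample on its event-time grid.

    ``grid`` holds the sorted unique *event* times of the selected subsample;
    ``risk[g, t]`` is ``Y_j(t)`` and ``events[g, t]`` is ``dN_j(t)`` for the
    g-th selected group.  Between event times nothing a test statistic uses
    changes, so the grid carries all information.
    """

    grid: np.ndarray
    risk: np.ndarray  # shape (n_groups, n_grid)
    events: np.ndarray  # shape (n_groups, n_grid)
    codes: tuple  # group codes, aligned with rows
    sizes: np.ndarray  # n_j per selected group

    @property
    def risk_total(self) -> np.ndarray:
        return self.risk.sum(axis=0)

    @property
    def events_total(self) -> np.ndarray:
        return self.events.sum(axis=0)

    def row(self, code: int) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"group code {code} not part of this counting process") from None


def build_counting(data: SurvivalData, groups: Sequence[int] | None = None) -> CountingProcesses:
    """Counting processes of the subsample formed by ``groups`` (codes).

    ``Y_j(t) = #{i in j : X_ji >= t}`` and ``dN_j(t) = #{i in j : X_ji = t,
    delta_ji = 1}`` evaluated on the sorted unique event times of the
    subsample.  Tied events are allowed (``dN`` may exceed 1).
    """
    if groups is None:
        groups = tuple(range(data.k))
    groups = tuple(groups)
    if not groups:
        raise ValueError("groups must be a non-empty subset")
    for g in groups:
        if not (0 <= g < data.k):
            raise KeyError(f"unknown group code {g}; dataset has codes 0..{data.k - 1}")
    sel = np.isin(data.group, groups)
    t, d, gr = data.time[sel], data.status[sel], data.group[sel]
    grid = np.unique(t[d == 1])
    n_g = len(groups)
    risk = np.empty((n_g, grid.size), dtype=float)
    events = np.empty((n_g, grid.size), dtype=float)
    sizes = np.empty(n_g, dtype=np.intp)
    for r, g in enumerate(groups):
        tg = np.sort(t[gr == g])
        sizes[r] = tg.size
        # Y_j(t) = n_j - #{X < t}
        risk[r] = tg.size - np.searchsorted(tg, grid, side="left")
        te = np.sort(t[(gr == g) & (d == 1)])
        events[r] = np.searchsorted(te, grid, side="right") - np.searchsorted(te, grid, side="left")
    return CountingProcesses(grid, risk, events, groups, sizes)


# ---------------------------------------------------------------------------
# step estimates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepEstimate:
    """A right-continuous step function over a sorted time grid.

    ``initial`` is the value on ``[0, grid[0])`` — 0 for a cumulative hazard,
    1 for a survival function.  ``left(t)`` returns the left limit, i.e. the
    value at the largest grid point strictly below ``t`` (``initial`` if none).
    """

    grid: np.ndarray
    values: np.ndarray
    initial: float = 0.0

    def __call__(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.grid, t, side="right")
        padded = np.concatenate(([self.initial], self.values))
        out = padded[idx]
        return out if np.ndim(t) else float(out)

    def left(self, t) -> np.ndarray | float:
        idx = np.searchsorted(self.grid, t, side="left")
        padded = np.concatenate(([self.initial], self.values))
        out = padded[idx]
        return out if np.ndim(t) else float(out)

    def to_frame(self, name: str = "estimate") -> pd.DataFrame:
        return pd.DataFrame({"time": self.grid, name: self.values})


def nelson_aalen(cp: CountingProcesses, group: int | None = None) -> StepEstimate:
    """Nelson–Aalen cumulative-hazard estimator.

    With ``group`` given, ``A_hat_j``; otherwise the pooled estimator of the
    whole subsample, increments ``d(sum_j N_j) / sum_j Y_j``.  Grid points
    with an empty risk set contribute nothing (the ``I{Y>0}`` guard).
    """
    if group is None:
        y, dn = cp.risk_total, cp.events_total
    else:
        r = cp.row(group)
        y, dn = cp.risk[r], cp.events[r]
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(y > 0, dn / np.where(y > 0, y, 1.0), 0.0)
    return StepEstimate(cp.grid, np.cumsum(inc), initial=0.0)


def kaplan_meier(cp: CountingProcesses) -> StepEstimate:
    """Product-limit survival estimator of the pooled subsample."""
    y, dn = cp.risk_total, cp.events_total
    with np.errstate(divide="ignore", invalid="ignore"):
        fac = np.where(y > 0, 1.0 - dn / np.where(y > 0, y, 1.0), 1.0)
    return StepEstimate(cp.grid, np.cumprod(fac), initial=1.0)
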