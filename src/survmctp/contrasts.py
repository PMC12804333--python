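"""Contrast matrices and weight functions.

A contrast matrix ``H`` (q x k, rows summing to zero) encodes which group
comparisons are tested simultaneously.  Only pairwise rows — a single -1 in
position ``j1`` and a single +1 in position ``j2`` — are supported by the
test statistics in this release; Dunnett-type (many-to-one) and Tukey-type
(all-pairs) matrices are the built-ins.

Weight functions ``w: [0,1] -> R`` are evaluated at the left limit of the
pooled Kaplan–Meier CDF and steer the power of a weighted log-rank test
toward specific alternatives: ``w == 1`` recovers the classical log-rank,
the Fleming–Harrington family ``w(t) = t^r (1-t)^g`` emphasizes late
(``r > 0``) or early (``g > 0``) differences, and the crossing weight
``w(t) = 1 - 2t`` changes sign at the pooled median and is powered against
crossing hazards.  The default set combined by every multi-weight procedure
here is ``{1, 1 - 2t}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ContrastSet",
    "WeightFunction",
    "make_contrasts",
    "pairwise_contrasts",
    "fleming_harrington",
    "log_rank_weight",
    "crossing_weight",
    "parse_weights",
    "default_weights",
    "check_linear_independence",
]


@dataclass(frozen=True)
class ContrastSet:
    """q pairwise contrasts over k groups.

    ``pairs`` lists 0-based group-code pairs ``(j1, j2)``; row ``a`` of the
    matrix has -1 at ``j1`` and +1 at ``j2``.
    """

    matrix: np.ndarray
    pairs: tuple
    kind: str = "custom"

    def __post_init__(self):
        H = np.asarray(self.matrix, dtype=float)
        if H.ndim != 2:
            raise ValueError("contrast matrix must be 2-d")
        if not np.allclose(H.sum(axis=1), 0.0):
            raise ValueError("every contrast row must sum to zero")
        object.__setattr__(self, "matrix", H)
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        if len(self.pairs) != H.shape[0]:
            raise ValueError("one (j1, j2) pair per row required")

    @property
    def q(self) -> int:
        return self.matrix.shape[0]

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    def validate_pairwise(self) -> None:
        """Raise unless every row is a proper ±1 pairwise contrast."""
        for a, (j1, j2) in enumerate(self.pairs):
            row = self.matrix[a]
            expected = np.zeros(self.k)
            expected[j1], expected[j2] = -1.0, 1.0
            if not np.array_equal(row, expected):
                raise ValueError(
                    f"row {a} is not a pairwise (-1, +1) contrast; "
                    "general contrast rows are not supported by the test procedures"
                )


def make_contrasts(kind: str, k: int) -> ContrastSet:
    """Dunnett-type (group 1 vs each other; q = k-1) or Tukey-type
    (all pairs in lexicographic order; q = k(k-1)/2) contrasts."""
    if k < 2:
        raise ValueError(f"need at least two groups, got k={k}")
    kind = kind.lower()
    if kind == "dunnett":
        pairs = [(0, j) for j in range(1, k)]
    elif kind == "tukey":
        pairs = [(i, j) for i in range(k - 1) for j in range(i + 1, k)]
    else:
        raise ValueError(f"unknown contrast kind {kind!r}; use 'dunnett' or 'tukey'")
    return pairwise_contrasts(pairs, k, kind=kind)


def pairwise_contrasts(pairs: Sequence[tuple], k: int, kind: str = "custom") -> ContrastSet:
    H = np.zeros((len(pairs), k))
    for a, (j1, j2) in enumerate(pairs):
        if not (0 <= j1 < k and 0 <= j2 < k and j1 != j2):
            raise ValueError(f"invalid pair {(j1, j2)} for k={k}")
        H[a, j1], H[a, j2] = -1.0, 1.0
    return ContrastSet(H, tuple(pairs), kind=kind)


# ---------------------------------------------------------------------------
# weight functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightFunction:
    """A weight ``w`` on [0, 1], continuous and of bounded variation.

    The built-ins satisfy the bounded-variation requirement by construction;
    user-supplied evaluators are the caller's responsibility.
    """

    func: Callable[[np.ndarray], np.ndarray]
    name: str = "custom"

    def __call__(self, x):
        return self.func(np.asarray(x, dtype=float))

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"WeightFunction({self.name})"


def fleming_harrington(r: int, g: int) -> WeightFunction:
    """Fleming–Harrington weight ``w(t) = t^r (1-t)^g``; (0, 0) is log-rank."""
    if r < 0 or g < 0:
        raise ValueError("Fleming-Harrington exponents must be non-negative")
    if r == 0 and g == 0:
        return WeightFunction(lambda x: np.ones_like(x), "log-rank")
    return WeightFunction(lambda x: x**r * (1.0 - x) ** g, f"fh({r},{g})")


def log_rank_weight() -> WeightFunction:
    return fleming_harrington(0, 0)


def crossing_weight() -> WeightFunction:
    """``w(t) = 1 - 2t``: sign change at the pooled median, for crossing hazards."""
    return WeightFunction(lambda x: 1.0 - 2.0 * x, "crossing")


def default_weights() -> tuple:
    """Log-rank plus crossing weight — the default multi-directional set."""
    return (log_rank_weight(), crossing_weight())


def parse_weights(spec) -> tuple:
    """Parse weight descriptors: ``"lr"``, ``"fh:r,g"``, ``"crossing"``.

    Accepts a single descriptor string, a WeightFunction, or a sequence of
    either; returns a tuple of WeightFunction.
    """
    if isinstance(spec, (str, WeightFunction)):
        spec = [spec]
    out = []
    for item in spec:
        if isinstance(item, WeightFunction):
            out.append(item)
            continue
        s = item.strip().lower()
        if s in ("lr", "logrank", "log-rank"):
            out.append(log_rank_weight())
        elif s == "crossing":
            out.append(crossing_weight())
        elif s.startswith("fh:"):
            try:
                r, g = (int(v) for v in s[3:].split(","))
            except Exception as exc:
                raise ValueError(f"cannot parse Fleming-Harrington spec {item!r}") from exc
            out.append(fleming_harrington(r, g))
        else:
            raise ValueError(f"unknown weight descriptor {item!r}")
    return tuple(out)


def check_linear_independence(
    weights: Sequence[WeightFunction], grid, tol: float | None = None
) -> bool:
    """True iff the weights are linearly independent as functions on ``grid``
    (the m x |grid| evaluation matrix has full row rank, numeric tolerance)."""
    grid = np.asarray(grid, dtype=float)
    M = np.vstack([w(grid) for w in weights])
    if M.shape[1] < M.shape[0]:
        return False
    rank = np.linalg.matrix_rank(M, tol=tol)
    return bool(rank == M.shape[0])
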