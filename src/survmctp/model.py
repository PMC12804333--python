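"""The user-facing model object tying the procedures together.

Typical use::

    import pandas as pd
    from survmctp import SurvivalMCTP

    df = pd.read_csv("trial.csv")          # columns: time, status, group
    model = SurvivalMCTP.from_dataframe(df)
    res = model.fit(method="multicasanova", contrasts="tukey", seed=7)
    print(res.summary())

``fit`` dispatches to one of the four procedures and returns the shared
:class:`~survmctp.procedures.MCTPResults` object.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .casanova import multicasanova_test
from .contrasts import ContrastSet, make_contrasts, parse_weights, pairwise_contrasts
from .data import SurvivalData, build_counting, kaplan_meier, nelson_aalen, read_table
from .maxtest import multiweightedlr_test
from .procedures import MCTPResults, adjusted_logrank_test, adjusted_mdir_test

__all__ = ["SurvivalMCTP"]

_METHOD_ALIASES = {
    "adjusted-logrank": "adjusted-logrank",
    "logrank": "adjusted-logrank",
    "adjusted-mdir": "adjusted-mdir",
    "mdir": "adjusted-mdir",
    "multiweightedlr": "multiweightedlr",
    "maxtest": "multiweightedlr",
    "multicasanova": "multicasanova",
    "casanova": "multicasanova",
}


class SurvivalMCTP:
    """Multiple contrast tests for k-sample right-censored survival data.

    Parameters
    ----------
    time, status, group : array-like
        Observed times, event indicators (1 = event), and group labels
        (arbitrary hashables; mapped internally in first-appearance order).
    """

    def __init__(self, time, status, group):
        self.data = SurvivalData.from_arrays(time, status, group)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time="time", status="status", group="group"
    ) -> "SurvivalMCTP":
        obj = cls.__new__(cls)
        obj.data = SurvivalData.from_dataframe(df, time=time, status=status, group=group)
        return obj

    @classmethod
    def from_table(cls, path, delimiter=",", **kwargs) -> "SurvivalMCTP":
        obj = cls.__new__(cls)
        obj.data = read_table(path, delimiter=delimiter, **kwargs)
        return obj

    # -- descriptive estimators -------------------------------------------

    @property
    def k(self) -> int:
        return self.data.k

    @property
    def group_labels(self) -> tuple:
        return self.data.labels

    def nelson_aalen(self, group) -> pd.DataFrame:
        """Nelson–Aalen cumulative-hazard table for one group label."""
        code = self.data.code_of(group)
        cp = build_counting(self.data, (code,))
        return nelson_aalen(cp, code).to_frame("cumulative_hazard")

    def kaplan_meier(self, groups=None) -> pd.DataFrame:
        """Pooled Kaplan–Meier survival table (all groups by default)."""
        codes = (
            tuple(range(self.k))
            if groups is None
            else tuple(self.data.code_of(g) for g in groups)
        )
        return kaplan_meier(build_counting(self.data, codes)).to_frame("survival")

    # -- fitting -----------------------------------------------------------

    def _contrasts(self, spec) -> ContrastSet:
        if isinstance(spec, ContrastSet):
            return spec
        if isinstance(spec, str):
            return make_contrasts(spec, self.k)
        # explicit list of label pairs
        pairs = [(self.data.code_of(a), self.data.code_of(b)) for a, b in spec]
        return pairwise_contrasts(pairs, self.k)

    def fit(
        self,
        method: str = "multicasanova",
        contrasts="tukey",
        weights=("lr", "crossing"),
        alpha: float = 0.05,
        n_resample: int = 1000,
        multiplier: str = "rademacher",
        seed=None,
    ) -> MCTPResults:
        """Run one multiple contrast test procedure.

        Parameters
        ----------
        method : {"adjusted-logrank", "adjusted-mdir", "multiweightedlr",
                  "multicasanova"}
        contrasts : "tukey", "dunnett", a ContrastSet, or a list of
            ``(label_j1, label_j2)`` pairs.
        weights : weight descriptors (see
            :func:`survmctp.contrasts.parse_weights`); the adjusted
            log-rank uses only the first entry.
        n_resample : permutation or bootstrap replications (ignored by the
            non-resampling methods).
        multiplier : wild-bootstrap multiplier law for multiCASANOVA.
        """
        key = _METHOD_ALIASES.get(method.lower().replace("_", "-"))
        if key is None:
            raise ValueError(
                f"unknown method {method!r}; choose from {sorted(set(_METHOD_ALIASES))}"
            )
        cs = self._contrasts(contrasts)
        ws = parse_weights(weights)
        if key == "adjusted-logrank":
            return adjusted_logrank_test(self.data, cs, w=ws[0], alpha=alpha)
        if key == "adjusted-mdir":
            return adjusted_mdir_test(
                self.data, cs, weights=ws, n_perm=n_resample, alpha=alpha, seed=seed
            )
        if key == "multiweightedlr":
            return multiweightedlr_test(self.data, cs, weights=ws, alpha=alpha, seed=seed)
        return multicasanova_test(
            self.data,
            cs,
            weights=ws,
            multiplier=multiplier,
            n_boot=n_resample,
            alpha=alpha,
            seed=seed,
        )
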