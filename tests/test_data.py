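"""Counting processes, Nelson–Aalen and Kaplan–Meier estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from survmctp import SurvivalData, build_counting, kaplan_meier, nelson_aalen, read_table
from .conftest import make_null_data


class TestCountingProcesses:
    def test_two_singleton_groups(self, toy_pair):
        cp = build_counting(toy_pair, (0, 1))
        assert np.array_equal(cp.grid, [1.0, 2.0])
        assert np.array_equal(cp.risk, [[1, 0], [1, 1]])
        assert np.array_equal(cp.events, [[1, 0], [0, 1]])

    def test_one_group_all_events(self):
        d = SurvivalData.from_arrays([1, 2, 3], [1, 1, 1], [1, 1, 1])
        cp = build_counting(d, (0,))
        assert np.array_equal(cp.risk[0], [3, 2, 1])
        assert np.array_equal(cp.events[0], [1, 1, 1])

    def test_tie_convention_censored_stays_at_risk(self):
        # times (1,1,2), status (1,0,1): the censored 1 is at risk at t=1
        d = SurvivalData.from_arrays([1, 1, 2], [1, 0, 1], [1, 1, 1])
        cp = build_counting(d, (0,))
        assert np.array_equal(cp.grid, [1.0, 2.0])
        assert np.array_equal(cp.risk[0], [3, 1])
        assert np.array_equal(cp.events[0], [1, 1])

    def test_event_totals_match_status_counts(self, rng):
        d = make_null_data(rng, k=3, n=25, censor_upper=1.5)
        cp = build_counting(d)
        for r, code in enumerate(cp.codes):
            mask = d.group == code
            assert cp.events[r].sum() == d.status[mask].sum()
            assert np.all(np.diff(cp.risk[r]) <= 0)

    def test_unknown_group_rejected(self, toy_pair):
        with pytest.raises(KeyError, match="unknown group"):
            build_counting(toy_pair, (0, 7))


class TestNelsonAalen:
    def test_hand_summation(self):
        d = SurvivalData.from_arrays([1, 2, 3], [1, 1, 1], [1, 1, 1])
        na = nelson_aalen(build_counting(d, (0,)), 0)
        np.testing.assert_allclose(na.values, [1 / 3, 5 / 6, 11 / 6])

    def test_all_censored_is_zero(self):
        d = SurvivalData.from_arrays([1, 2, 2.5], [0, 0, 0], [1, 1, 1])
        na = nelson_aalen(build_counting(d, (0,)), 0)
        assert na.grid.size == 0 and na(10.0) == 0.0

    def test_single_subject_single_event(self):
        d = SurvivalData.from_arrays([1.0], [1], [1])
        na = nelson_aalen(build_counting(d, (0,)), 0)
        assert na(1.0) == 1.0 and na.left(1.0) == 0.0


class TestKaplanMeier:
    def test_product_limit_by_hand(self, toy_pair):
        km = kaplan_meier(build_counting(toy_pair))
        np.testing.assert_allclose(km.values, [0.5, 0.0])
        # left limits of F = 1 - S
        assert 1.0 - km.left(1.0) == 0.0  # F(1-) = 0
        assert 1.0 - km.left(2.0) == 0.5  # F(2-) = 1/2

    def test_all_censored_stays_at_one(self):
        d = SurvivalData.from_arrays([1, 2], [0, 0], [1, 1])
        km = kaplan_meier(build_counting(d))
        assert km(5.0) == 1.0

    def test_telescoping_no_censoring(self, rng):
        n = 17
        t = np.sort(rng.uniform(0.1, 5.0, n))
        d = SurvivalData.from_arrays(t, np.ones(n, int), np.ones(n, int))
        km = kaplan_meier(build_counting(d))
        np.testing.assert_allclose(km.values, (n - np.arange(1, n + 1)) / n)

    def test_matches_ecdf_without_censoring(self, rng):
        t = rng.exponential(1.0, 40)
        d = SurvivalData.from_arrays(t, np.ones(40, int), np.ones(40, int))
        km = kaplan_meier(build_counting(d))
        ecdf = np.searchsorted(np.sort(t), km.grid, side="right") / 40
        np.testing.assert_allclose(1.0 - km.values, ecdf)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        d = make_null_data(rng, k=1, n=60, censor_upper=2.0)
        km = kaplan_meier(build_counting(d))
        kmf = KaplanMeierFitter().fit(d.time, d.status)
        ours = km(km.grid)
        theirs = kmf.survival_function_at_times(km.grid).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


@given(
    times=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=40),
    status=st.data(),
)
def test_estimator_monotonicity(times, status):
    """NA non-decreasing from 0; KM non-increasing within [0, 1]."""
    d_flags = status.draw(
        st.lists(st.integers(0, 1), min_size=len(times), max_size=len(times))
    )
    if sum(d_flags) == 0:
        d_flags[0] = 1
    data = SurvivalData.from_arrays(times, d_flags, [1] * len(times))
    cp = build_counting(data, (0,))
    na = nelson_aalen(cp, 0)
    km = kaplan_meier(cp)
    assert np.all(np.diff(na.values) >= 0) and na.values[0] >= 0
    assert np.all(np.diff(km.values) <= 0)
    assert np.all((km.values >= 0) & (km.values <= 1))


def test_rank_invariance(rng):
    """A strictly increasing time transform leaves Y and dN patterns unchanged."""
    d = make_null_data(rng, k=2, n=20, censor_upper=2.0)
    cp = build_counting(d)
    d2 = SurvivalData(np.exp(d.time), d.status, d.group, d.labels)
    cp2 = build_counting(d2)
    assert np.array_equal(cp.risk, cp2.risk)
    assert np.array_equal(cp.events, cp2.events)


class TestIO:
    def test_roundtrip_and_label_order(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame(
            {"time": [2.0, 1.0, 3.0], "status": [1, 0, 1], "group": ["b", "a", "b"]}
        ).to_csv(path, index=False)
        d = read_table(path)
        assert d.labels == ("b", "a")  # first-appearance order
        assert d.code_of("a") == 1
        pd.testing.assert_frame_equal(
            d.to_frame(), pd.DataFrame({"time": [2.0, 1.0, 3.0], "status": [1, 0, 1], "group": ["b", "a", "b"]})
        )

    def test_missing_column_diagnostic(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"time": [1.0], "group": [1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="status"):
            read_table(path)

    def test_malformed_row_line_numbers(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text("time,status,group\n1.0,1,1\n2.0,9,1\n")
        with pytest.raises(ValueError, match="line.*3"):
            read_table(path)

    def test_flip_status(self, tmp_path):
        path = tmp_path / "d.csv"
        pd.DataFrame({"time": [1.0, 2.0], "status": [0, 1], "group": [1, 1]}).to_csv(
            path, index=False
        )
        d = read_table(path, flip_status=True)
        assert np.array_equal(d.status, [1, 0])

    @pytest.mark.parametrize(
        "time,status,group,msg",
        [
            ([0.0, 1.0], [1, 1], [1, 2], "positive"),
            ([1.0, 2.0], [1, 2], [1, 2], "status"),
            ([], [], [], "empty"),
        ],
    )
    def test_validation(self, time, status, group, msg):
        with pytest.raises(ValueError, match=msg):
            SurvivalData.from_arrays(time, status, group)
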