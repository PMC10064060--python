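import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import resst
from resst.qc import (
    dip_null_table,
    dip_statistic,
    dip_test,
    independence_check,
    screen_cohort,
)

from .dip_oracle import dip_lp_oracle


class TestDipStatistic:
    def test_two_point_sample(self):
        assert dip_statistic([0.0, 1.0]) == pytest.approx(0.25)

    def test_matches_lp_oracle_small_n(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(2, 9))
            kind = rng.integers(0, 3)
            if kind == 0:
                x = rng.normal(size=n)
            elif kind == 1:
                x = rng.uniform(size=n)
            else:
                x = np.concatenate(
                    [rng.normal(-3, 0.3, size=n // 2 + 1), rng.normal(3, 0.3, size=n)]
                )[:n]
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-7)

    def test_matches_lp_oracle_moderate_n(self):
        rng = np.random.default_rng(1)
        for n in (15, 25, 40):
            x = np.concatenate(
                [rng.normal(-3, 0.4, size=n // 2), rng.normal(3, 0.4, size=n - n // 2)]
            )
            assert dip_statistic(x) == pytest.approx(dip_lp_oracle(x), abs=1e-7)

    @given(st.lists(st.floats(0.1, 1e4), min_size=2, max_size=40, unique=True))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_lower_bound_and_affine_invariance(self, xs):
        x = np.array(xs)
        d = dip_statistic(x)
        assert d >= 1.0 / (2 * len(x)) - 1e-12
        assert d <= 0.25 + 1e-12
        assert dip_statistic(3.5 * x + 11.0) == pytest.approx(d, abs=1e-12)

    def test_not_invariant_under_nonlinear_monotone_transforms(self):
        # convexity is not order-determined: a middle gap makes {1,2,4,5}
        # look bimodal, while its log is nearly equally spaced
        assert dip_statistic([1.0, 2.0, 4.0, 5.0]) == pytest.approx(1 / 6)
        assert dip_statistic(np.log([1.0, 2.0, 4.0, 5.0])) == pytest.approx(0.125)

    def test_degenerate_and_errors(self):
        assert dip_statistic([3.0, 3.0, 3.0]) == 0.0
        with pytest.raises(ValueError):
            dip_statistic([1.0])
        with pytest.raises(ValueError):
            dip_statistic([1.0, np.inf])


class TestDipTest:
    def test_p_is_multiple_of_inverse_nboot(self):
        rng = np.random.default_rng(2)
        res = dip_test(rng.uniform(size=50), n_boot=1000, rng=rng)
        assert res.p_value == pytest.approx(round(res.p_value * 1000) / 1000)

    def test_separated_bimodal_rejects(self):
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(6, 1, 100)])
        res = dip_test(x, n_boot=1000, rng=rng)
        assert res.p_value < 0.05

    def test_unimodal_accepts(self):
        rng = np.random.default_rng(4)
        res = dip_test(rng.normal(size=200), n_boot=1000, rng=rng)
        assert res.p_value > 0.05


def _subject_frame(sid, go_rts, fs_rts, cond="Neutral"):
    rows = []
    for rt in go_rts:
        rows.append(
            {"subject_id": sid, "phase": "test", "condition": cond,
             "trial_type": "go", "rt_ms": rt, "outcome": "correct_go",
             "ssd_ms": np.nan}
        )
    for rt in fs_rts:
        rows.append(
            {"subject_id": sid, "phase": "test", "condition": cond,
             "trial_type": "stop", "rt_ms": rt, "outcome": "failed_stop",
             "ssd_ms": 300.0}
        )
    return pd.DataFrame(rows)


class TestIndependence:
    def test_faster_failed_stops_pass(self):
        df = _subject_frame("s1", [600.0, 640.0], [540.0, 545.0])
        assert independence_check(df)["passed"]

    def test_equal_means_fail(self):
        df = _subject_frame("s1", [600.0, 640.0], [600.0, 640.0])
        assert not independence_check(df)["passed"]

    def test_no_failed_stops_not_evaluable(self):
        df = _subject_frame("s1", [600.0, 640.0], [])
        res = independence_check(df)
        assert res["passed"]
        assert not res["per_condition"]["Neutral"]["evaluable"]

    def test_race_cohort_passes(self, default_cohort_trials):
        for sid, sub in default_cohort_trials.groupby("subject_id"):
            assert independence_check(sub)["passed"]


class TestScreening:
    def test_clean_cohort_all_included(self, default_cohort_trials):
        rep = screen_cohort(default_cohort_trials, rng=np.random.default_rng(5))
        assert len(rep.included_ids) == 14
        for rec in rep.subjects.values():
            assert rec.included and not rec.exclusion_reasons

    def test_p_respond_window_boundary(self, default_cohort_trials):
        one = default_cohort_trials[default_cohort_trials["subject_id"] == "s01"].copy()
        stop = (one["trial_type"] == "stop") & (one["condition"] == "Gplus")
        idx = one[stop].index
        one.loc[idx, "outcome"] = "failed_stop"
        one.loc[idx[: int(0.3 * len(idx))], "outcome"] = "correct_stop"  # p = 0.70
        rep = screen_cohort(one, rng=np.random.default_rng(6))
        rec = rep.subjects["s01"]
        assert not rec.included
        assert any(r.startswith("p_respond_window") for r in rec.exclusion_reasons)

    def test_row_order_invariance(self, default_cohort_trials):
        small = default_cohort_trials[
            default_cohort_trials["subject_id"].isin(["s01", "s02", "s03"])
        ]
        rep_a = screen_cohort(small, n_boot=200, rng=np.random.default_rng(7))
        shuffled = small.sample(frac=1.0, random_state=3)
        rep_b = screen_cohort(shuffled, n_boot=200, rng=np.random.default_rng(7))
        assert rep_a.included_ids == rep_b.included_ids
        for sid in rep_a.subjects:
            assert (
                rep_a.subjects[sid].exclusion_reasons
                == rep_b.subjects[sid].exclusion_reasons
            )

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            screen_cohort(pd.DataFrame({"phase": [], "subject_id": []}))


def test_null_table_is_sorted_and_cached_free():
    rng = np.random.default_rng(8)
    tab = dip_null_table(30, 100, rng)
    assert len(tab) == 100
    assert (np.diff(tab) >= 0).all()
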