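"""Behavioral response tables: filtering, percentages, perceiver rule, generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avsync.behavior import (
    CATEGORIES,
    LAGS_MS,
    classify_perceivers,
    expected_ta_probability,
    filter_low_response,
    generate_synthetic_responses,
    group_curves,
    percent_by_category,
    read_response_csv,
    validate_table,
    write_response_csv,
)


def _table(cells):
    """cells: list of (subject, lag, ta, pa, other)."""
    rows = []
    for s, lag, ta, pa, other in cells:
        for cat, c in zip(CATEGORIES, (ta, pa, other)):
            rows.append({"subject_id": s, "av_lag_ms": lag, "category": cat,
                         "count": c})
    return pd.DataFrame(rows)


class TestFilterLowResponse:
    def test_threshold_boundary(self):
        t = _table([("a", 0, 20, 10, 4), ("a", 150, 20, 10, 5)])  # 34 vs 35
        kept = filter_low_response(t)
        assert set(kept["av_lag_ms"]) == {150}

    def test_empty_table_passes_through(self):
        out = filter_low_response(_table([]))
        assert out.empty

    def test_matches_brute_force_enumeration(self):
        """Surviving cells equal an exhaustive count over all cells of a
        10-subject cohort with incomplete response sets."""
        t = generate_synthetic_responses(n_subjects=10, response_rate=0.88,
                                         seed=5)
        kept = filter_low_response(t)
        surviving = set(
            map(tuple, kept[["subject_id", "av_lag_ms"]].drop_duplicates().values)
        )
        expected = set()
        for (s, lag), grp in t.groupby(["subject_id", "av_lag_ms"]):
            if grp["count"].sum() >= 35:
                expected.add((s, lag))
        assert surviving == expected
        assert len(expected) < 60  # the fixture does exercise the filter


class TestPercentByCategory:
    def test_simple_arithmetic(self):
        pct = percent_by_category(_table([("a", 0, 28, 8, 4)]))
        by_cat = pct.set_index("category")["percent"]
        assert by_cat["ta"] == 70.0
        assert by_cat["pa"] == 20.0
        assert by_cat["other"] == 10.0

    def test_single_category_cell(self):
        pct = percent_by_category(_table([("a", 0, 0, 40, 0)]))
        by_cat = pct.set_index("category")["percent"]
        assert by_cat["pa"] == 100.0 and by_cat["ta"] == 0.0

    def test_zero_total_cell_raises(self):
        with pytest.raises(ValueError, match="zero-total"):
            percent_by_category(_table([("a", 0, 0, 0, 0)]))

    def test_cell_percentages_sum_to_100(self):
        t = generate_synthetic_responses(n_subjects=8, seed=2)
        pct = percent_by_category(t)
        sums = pct.groupby(["subject_id", "av_lag_ms"])["percent"].sum()
        assert np.allclose(sums, 100.0, atol=1e-9)


class TestClassifyPerceivers:
    def test_single_peak_above_threshold_qualifies(self):
        t = _table([("a", 0, 28, 8, 4)] + [("a", lag, 10, 25, 5)
                                           for lag in LAGS_MS if lag != 0])
        assert classify_perceivers(t) == ["a"]

    def test_all_lags_below_threshold_excluded(self):
        t = _table([("a", lag, 20, 15, 5) for lag in LAGS_MS])  # 50% everywhere
        assert classify_perceivers(t) == []

    def test_matches_brute_force_on_synthetic_cohort(self):
        t = generate_synthetic_responses(n_subjects=20, peak_p_ta=0.65,
                                         peak_sd=0.15, seed=7)
        expected = []
        for s, grp in percent_by_category(t).groupby("subject_id"):
            ta = grp[grp["category"] == "ta"]["percent"]
            if ta.max() >= 60.0:
                expected.append(s)
        assert classify_perceivers(t) == sorted(expected)

    @given(st.integers(min_value=0, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_monotone_in_threshold(self, thr):
        t = generate_synthetic_responses(n_subjects=12, peak_p_ta=0.6,
                                         peak_sd=0.2, seed=3)
        hi = set(classify_perceivers(t, threshold_percent=thr))
        lo = set(classify_perceivers(t, threshold_percent=max(thr - 10, 0)))
        assert hi <= lo


class TestGenerator:
    def test_deterministic_under_seed(self):
        a = generate_synthetic_responses(seed=42)
        b = generate_synthetic_responses(seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_wide_tuning_gives_flat_ta_curve(self):
        p = expected_ta_probability(LAGS_MS, 0.8, width_ms=1e9, skew=1.0)
        assert np.allclose(p, 0.8, atol=1e-6)

    def test_zero_peak_probability_gives_zero_perceivers(self):
        t = generate_synthetic_responses(peak_p_ta=0.0, seed=1)
        assert classify_perceivers(t) == []
        assert t[t["category"] == "ta"]["count"].sum() == 0

    def test_default_cohort_shape(self):
        """Group curves from the default cohort: illusory /ta maximal at
        0 ms lag, auditory /pa minimal there, 'other' a small flat share —
        the lag-tuning shape the model's R(tau) is compared against."""
        t = generate_synthetic_responses(seed=11)
        curves = group_curves(t, n_boot=200, seed=0)
        ta = curves[curves.category == "ta"].set_index("av_lag_ms")["mean_percent"]
        pa = curves[curves.category == "pa"].set_index("av_lag_ms")["mean_percent"]
        other = curves[curves.category == "other"]["mean_percent"]
        assert ta.idxmax() == 0
        assert pa.idxmin() == 0
        assert 5.0 < other.mean() < 15.0
        # positive-lag skew: /ta falls off more slowly toward positive lags
        assert ta[150] > ta[-150] or ta[300] > ta[-300]
        assert (curves["ci_low"] <= curves["mean_percent"] + 1e-9).all()

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic_responses(peak_p_ta=1.5)
        with pytest.raises(ValueError):
            generate_synthetic_responses(response_rate=0.0)
        with pytest.raises(ValueError):
            expected_ta_probability(LAGS_MS, 0.8, width_ms=-1.0, skew=1.0)
        with pytest.raises(ValueError, match="length"):
            generate_synthetic_responses(n_subjects=3, peak_p_ta=[0.5, 0.5])


class TestValidationAndIO:
    def test_unknown_lag_rejected(self):
        t = _table([("a", 0, 1, 1, 1)])
        t.loc[0, "av_lag_ms"] = 75
        with pytest.raises(ValueError, match="lag"):
            validate_table(t)

    def test_fractional_count_rejected(self):
        t = _table([("a", 0, 1, 1, 1)]).astype({"count": float})
        t.loc[0, "count"] = 1.5
        with pytest.raises(ValueError, match="count"):
            validate_table(t)

    def test_csv_round_trip(self, tmp_path):
        t = generate_synthetic_responses(n_subjects=4, seed=0)
        path = tmp_path / "responses.csv"
        write_response_csv(t, path)
        back = read_response_csv(path)
        pd.testing.assert_frame_equal(
            back, t.reset_index(drop=True), check_dtype=False
        )
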