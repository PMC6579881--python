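"""Screen statistics: blank thresholds, percent positive, fixation, diffexp."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytoscreen.screen import (
    ScreenSummary,
    blank_threshold,
    differential_markers,
    fixation_classify,
    percent_positive,
    summarize_screen,
)


class TestBlankThreshold:
    def test_linear_interpolation_on_1_to_100(self):
        assert blank_threshold(np.arange(1.0, 101.0)) == pytest.approx(99.01)

    def test_constant_blank(self):
        assert blank_threshold(np.full(50, 2.5)) == 2.5

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=1000)
        assert blank_threshold(v) == blank_threshold(np.sort(v))

    def test_empty_blank_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            blank_threshold([])


class TestPercentPositive:
    def test_counting(self):
        values = np.r_[np.zeros(190), np.full(10, 9.0)]
        assert percent_positive(values, 5.0) == pytest.approx(5.0)

    def test_all_below_threshold(self):
        assert percent_positive(np.zeros(100), 1.0) == 0.0

    def test_blank_scored_against_itself_is_one_percent(self):
        rng = np.random.default_rng(1)
        blank = rng.normal(0, 1, 100_000)
        pp = percent_positive(blank, blank_threshold(blank))
        assert pp == pytest.approx(1.0, abs=0.05)

    def test_empty_input_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert percent_positive([], 0.0) == 0.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50))
    def test_monotone_nonincreasing_in_threshold(self, values):
        thresholds = np.linspace(-6, 6, 13)
        pps = [percent_positive(values, t) for t in thresholds]
        assert all(b <= a for a, b in zip(pps, pps[1:]))


def synthetic_screen_frame(seed=13, n_per_cell=2000):
    """Long event frame with planted positive fractions per (subset, antibody)."""
    rng = np.random.default_rng(seed)
    subsets = ["A", "B", "C", "D"]
    antibodies = ["Blank", "ab1", "ab2", "ab3", "ab4"]
    planted = {
        (s, a): 0.0 if a == "Blank" else rng.choice([0.05, 0.2, 0.4, 0.7, 0.9])
        for s in subsets for a in antibodies
    }
    rows = []
    for (s, a), frac in planted.items():
        pos = rng.uniform(size=n_per_cell) < frac
        value = np.where(pos, 3.0, 0.3) + rng.normal(0, 0.25, n_per_cell)
        rows.append(pd.DataFrame({
            "donor": "D1", "treatment": "fresh", "antibody": a,
            "profiling_subset": s, "value": value,
        }))
    return pd.concat(rows, ignore_index=True), planted


class TestSummarizeScreen:
    def test_percent_positive_recovers_planted_fractions(self):
        events, planted = synthetic_screen_frame(seed=13)
        summary = summarize_screen(events)
        for row in summary.table.itertuples():
            expected = 100 * planted[(row.subset, row.antibody)]
            background = (100 - expected) * 0.01  # blank-rate false positives
            assert row.pct_positive == pytest.approx(expected + background, abs=2.0)

    def test_zero_event_cell_emitted_with_null_stats(self):
        events, _p = synthetic_screen_frame(seed=3, n_per_cell=50)
        events = events.loc[~((events["antibody"] == "ab1")
                              & (events["profiling_subset"] == "A"))]
        summary = summarize_screen(events)
        row = summary.table.query("antibody == 'ab1' and subset == 'A'")
        assert len(row) == 1
        assert row["n_events"].iloc[0] == 0
        assert np.isnan(row["median"].iloc[0])

    def test_rerun_deterministic(self):
        events, _p = synthetic_screen_frame(seed=5, n_per_cell=200)
        a = summarize_screen(events).table
        b = summarize_screen(events).table
        pd.testing.assert_frame_equal(a, b)

    def test_missing_blank_rejected(self):
        events, _p = synthetic_screen_frame(seed=1, n_per_cell=50)
        with pytest.raises(ValueError, match="blank"):
            summarize_screen(events.loc[events["antibody"] != "Blank"])

    def test_one_threshold_per_condition(self):
        events, _p = synthetic_screen_frame(seed=2, n_per_cell=100)
        fixed = events.assign(treatment="fixed")
        summary = summarize_screen(pd.concat([events, fixed], ignore_index=True))
        assert set(summary.blank_thresholds) == {("D1", "fresh"), ("D1", "fixed")}


def summary_from_grid(medians_raw, pct, treatment, cofactor=5.0):
    """Build a ScreenSummary from a (subset, antibody) -> raw-median dict."""
    rows = [
        {"donor": "D1", "treatment": treatment, "subset": s, "antibody": a,
         "n_events": 1000, "median": np.arcsinh(m / cofactor),
         "pct_positive": pct.get((s, a), 50.0)}
        for (s, a), m in medians_raw.items()
    ]
    return ScreenSummary(table=pd.DataFrame(rows))


class TestFixation:
    def test_equal_medians_are_unchanged(self):
        grid = {("s1", "ab"): 100.0, ("s2", "ab"): 40.0}
        report = fixation_classify(
            summary_from_grid(grid, {}, "fresh"),
            summary_from_grid(grid, {}, "fixed"),
        )
        assert report.per_antibody["class"].tolist() == ["unchanged"]
        assert report.per_subset["log10_ratio"].abs().max() == pytest.approx(0.0)

    def test_planted_gain_detected(self):
        fresh = {("s1", "g"): 100.0, ("s2", "g"): 50.0}
        fixed = {k: 2.5 * v for k, v in fresh.items()}
        report = fixation_classify(
            summary_from_grid(fresh, {}, "fresh"), summary_from_grid(fixed, {}, "fixed")
        )
        row = report.per_antibody.iloc[0]
        assert row["class"] == "gain"
        assert row["summary_ratio"] == pytest.approx(np.log10(2.5), abs=1e-6)

    def test_subset_specific_loss_reported_at_both_granularities(self):
        # CD22-like: lost in one expressing subset, stable in the other.
        fresh = {("Basophils", "cd22"): 80.0, ("B Cells", "cd22"): 80.0}
        fixed = {("Basophils", "cd22"): 16.0, ("B Cells", "cd22"): 80.0}
        report = fixation_classify(
            summary_from_grid(fresh, {}, "fresh"), summary_from_grid(fixed, {}, "fixed")
        )
        per_subset = report.per_subset.set_index("subset")["log10_ratio"]
        assert per_subset["Basophils"] == pytest.approx(np.log10(0.2), abs=1e-6)
        assert per_subset["B Cells"] == pytest.approx(0.0, abs=1e-6)
        # Antibody class follows the median over expressing subsets.
        assert report.per_antibody.iloc[0]["summary_ratio"] == pytest.approx(
            np.log10(0.2) / 2, abs=1e-6
        )
        assert report.per_antibody.iloc[0]["class"] == "loss"

    def test_unexpressed_antibodies_excluded(self):
        grid = {("s1", "dim"): 10.0}
        pct = {("s1", "dim"): 1.0}  # below the 5% expression floor
        report = fixation_classify(
            summary_from_grid(grid, pct, "fresh"), summary_from_grid(grid, pct, "fixed")
        )
        assert report.expressed_antibodies == []
        assert report.per_antibody.empty


def diffexp_frame(seed=23, n_antibodies=50, offset_ab="ab00", offset=40.0,
                  donors=("D1", "D2", "D3"), offset_donors=None):
    rng = np.random.default_rng(seed)
    base = rng.uniform(5, 80, n_antibodies)
    rows = []
    for donor in donors:
        for i in range(n_antibodies):
            ab = f"ab{i:02d}"
            pp_neg = base[i] + rng.normal(0, 2)
            pp_pos = base[i] + rng.normal(0, 2)
            if ab == offset_ab and (offset_donors is None or donor in offset_donors):
                pp_pos += offset
            rows.append({"donor": donor, "antibody": ab,
                         "pp_pos": pp_pos, "pp_neg": pp_neg})
    return pd.DataFrame(rows)


class TestDifferentialMarkers:
    def test_identical_subsets_flag_nothing(self):
        pp = diffexp_frame(offset=0.0)
        pp["pp_pos"] = pp["pp_neg"]
        out = differential_markers(pp)
        assert not out["flagged"].any()

    def test_single_offset_antibody_flagged_with_direction(self):
        out = differential_markers(diffexp_frame(seed=23))
        flagged = out.index[out["flagged"]].tolist()
        assert flagged == ["ab00"]
        assert out.loc["ab00", "direction"] == 1

    def test_negative_offset_direction(self):
        out = differential_markers(diffexp_frame(seed=23, offset=-40.0))
        assert out.index[out["flagged"]].tolist() == ["ab00"]
        assert out.loc["ab00", "direction"] == -1

    def test_offset_in_one_donor_not_flagged(self):
        out = differential_markers(
            diffexp_frame(seed=23, offset_donors=("D1",))
        )
        assert not out["flagged"].any()

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError, match="two donors"):
            differential_markers(diffexp_frame(donors=("D1",)))

    def test_mismatched_antibody_sets_rejected(self):
        pp = diffexp_frame()
        pp = pp.drop(pp[(pp["donor"] == "D1") & (pp["antibody"] == "ab05")].index)
        with pytest.raises(ValueError, match="same antibody set"):
            differential_markers(pp)

    def test_invariant_to_antibody_order_and_constant_shift(self):
        pp = diffexp_frame(seed=7)
        a = differential_markers(pp)
        shuffled = pp.sample(frac=1.0, random_state=0)
        shifted = shuffled.assign(pp_pos=shuffled["pp_pos"] + 10,
                                  pp_neg=shuffled["pp_neg"] + 10)
        b = differential_markers(shifted)
        pd.testing.assert_frame_equal(a, b)
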