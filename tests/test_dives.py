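import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from divehab import dives as dv


def _trace(depths, t0=0.0, bird="b1"):
    return pd.DataFrame({
        "bird_id": bird,
        "timestamp": t0 + np.arange(len(depths), dtype=float),
        "depth_m": depths,
    })


def _events(**cols):
    n = len(next(iter(cols.values())))
    base = {"bird_id": ["b1"] * n}
    base.update(cols)
    return pd.DataFrame(base)


class TestDetect:
    def test_single_excursion(self):
        segs = dv.detect_dives(_trace([0, 0, 5, 10, 10, 5, 0]), 0.5)
        assert len(segs) == 1
        assert len(segs[0]) == 4

    def test_flat_surface_trace(self):
        assert dv.detect_dives(_trace([0.0] * 6), 0.5) == []

    def test_empty_trace(self):
        assert dv.detect_dives(_trace([]), 0.5) == []

    def test_two_excursions_three_surface_samples_apart(self):
        segs = dv.detect_dives(_trace([0, 4, 6, 0, 0, 0, 3, 5, 0]), 0.5)
        assert len(segs) == 2

    def test_non_monotone_timestamps_rejected(self):
        tr = _trace([0, 5, 5, 0])
        tr.loc[2, "timestamp"] = 0.5
        with pytest.raises(ValueError, match="non-monotone"):
            dv.detect_dives(tr, 0.5)

    def test_sampling_gap_splits_segments(self):
        # logger records only while submerged: a 60 s gap means a surfacing
        tr = pd.concat([_trace([2, 3, 2]), _trace([4, 5, 4], t0=60.0)], ignore_index=True)
        assert len(dv.detect_dives(tr, 0.5)) == 2

    @given(depths=hst.lists(hst.sampled_from([0.0, 0.0, 2.0, 6.0]), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_segment_count_matches_run_length_oracle(self, depths):
        segs = dv.detect_dives(_trace(depths), 0.5)
        # brute-force run-length scan
        runs, prev = 0, False
        for d in depths:
            wet = d > 0.5
            runs += wet and not prev
            prev = wet
        assert len(segs) == runs
        assert sum(len(s) for s in segs) == sum(d > 0.5 for d in depths)


class TestMetrics:
    @pytest.mark.parametrize(
        "depths, expect",
        [
            ([2, 10, 10, 10, 2], (10.0, 5.0, 3.0)),  # 80% rule threshold 8 m
            ([1, 7, 1], (7.0, 3.0, 1.0)),  # V spike: one sample >= 5.6
            ([5, 5, 5, 5], (5.0, 4.0, 4.0)),  # constant depth: bottom = duration
        ],
    )
    def test_hand_evaluated_examples(self, depths, expect):
        assert dv.compute_metrics(_trace(depths)) == expect

    def test_single_sample_dive_lasts_one_second(self):
        assert dv.compute_metrics(_trace([3.0]))[1] == 1.0

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            dv.compute_metrics(_trace([]))


class TestClassify:
    @pytest.mark.parametrize(
        "metrics, label",
        [
            ((15.0, 20.0, 5.0), "U"),  # satisfies both clauses
            ((3.0, 4.0, 1.0), "V"),  # fails both
            ((8.0, 10.0, 2.99), "V"),  # boundary: all three strict conditions fail
            ((9.0, 10.5, 1.0), "U"),  # deep & long without bottom phase
            ((20.0, 5.0, 3.0), "U"),  # bottom phase alone suffices
        ],
    )
    def test_rule(self, metrics, label):
        assert dv.classify_dive(*metrics) == label

    def test_strict_and_variant(self):
        assert dv.classify_dive(20.0, 5.0, 3.0, rule="strict_and") == "V"
        assert dv.classify_dive(20.0, 15.0, 3.0, rule="strict_and") == "U"


class TestFilter:
    def test_one_metre_boundary_kept(self):
        ev = _events(max_depth=[0.5, 1.0, 9.0])
        assert dv.filter_dives(ev)["max_depth"].tolist() == [1.0, 9.0]

    def test_identity_when_all_deep(self):
        ev = _events(max_depth=[2.0, 3.0])
        assert len(dv.filter_dives(ev)) == 2

    def test_empty_when_all_shallow(self):
        assert dv.filter_dives(_events(max_depth=[0.2, 0.9])).empty

    def test_idempotent(self):
        ev = _events(max_depth=[0.5, 1.0, 2.0, 0.1, 8.0])
        once = dv.filter_dives(ev)
        pd.testing.assert_frame_equal(dv.filter_dives(once), once)


def _ts(minute, base=dt.datetime(2021, 7, 20, 12, 0, tzinfo=dt.timezone.utc)):
    return pd.Timestamp(base + dt.timedelta(minutes=minute))


class TestForagingLocations:
    def _run(self, dive_min, fix_min):
        events = pd.DataFrame({"bird_id": ["b1"], "start_time": [_ts(dive_min)]})
        fixes = pd.DataFrame({"bird_id": "b1", "timestamp": [_ts(m) for m in fix_min],
                              "lon": list(range(len(fix_min))), "lat": [0.0] * len(fix_min)})
        return dv.assign_foraging_locations(events, fixes)

    def test_fix_twenty_minutes_before_is_associated(self):
        assert self._run(20, [0])["lon"].iloc[0] == 0

    def test_fix_thirty_one_minutes_before_is_not(self):
        assert np.isnan(self._run(31, [0])["lon"].iloc[0])

    def test_fix_after_dive_is_not(self):
        out = self._run(0, [0.02])
        assert np.isnan(out["lon"].iloc[0])

    def test_latest_of_several_fixes_wins(self):
        assert self._run(25, [0, 10, 20])["lon"].iloc[0] == 2

    def test_other_bird_fix_ignored(self):
        events = pd.DataFrame({"bird_id": ["b2"], "start_time": [_ts(10)]})
        fixes = pd.DataFrame({"bird_id": ["b1"], "timestamp": [_ts(0)],
                              "lon": [1.0], "lat": [2.0]})
        assert np.isnan(dv.assign_foraging_locations(events, fixes)["lon"].iloc[0])


def _daily_events(props, year=2021):
    """One day per proportion; 100 dives per day with that U share."""
    rows = []
    for day, p in enumerate(props):
        date = dt.datetime(year, 7, 1, 10, tzinfo=dt.timezone.utc) + dt.timedelta(days=day)
        n_u = int(round(100 * p))
        shapes = ["U"] * n_u + ["V"] * (100 - n_u)
        rows += [("b1", pd.Timestamp(date) + pd.Timedelta(seconds=i), s)
                 for i, s in enumerate(shapes)]
    return pd.DataFrame(rows, columns=["bird_id", "start_time", "shape"])


class TestCutoff:
    def test_step_drop_found_exactly(self):
        ev = _daily_events([0.4] * 20 + [0.02] * 20)
        cut = dv.detect_cutoff(ev, dv.CutoffRule())
        assert cut[2021] == dt.date(2021, 7, 21)

    def test_fixed_date_mode_echoes_configuration(self):
        rule = dv.CutoffRule("fixed_date", {2019: dt.date(2019, 8, 16), 2020: dt.date(2020, 8, 10)})
        ev = _daily_events([0.4, 0.3])
        assert dv.detect_cutoff(ev, rule) == rule.fixed_dates

    def test_monotone_linear_decline_matches_exhaustive_scan(self):
        # exact arithmetic ramp (multiples of 0.01, so no rounding error)
        props = np.arange(60, 0, -2) / 100.0
        ev = _daily_events(props)
        # independent brute-force oracle over all split points
        best, best_gap = None, -np.inf
        for k in range(1, len(props)):
            gap = props[:k].mean() - props[k:].mean()
            if gap > best_gap + 1e-12:
                best_gap, best = gap, k
        cut = dv.detect_cutoff(ev, dv.CutoffRule())
        assert cut[2021] == dt.date(2021, 7, 1) + dt.timedelta(days=best)
        # for an arithmetic ramp the two-mean contrast is the same at every
        # split (d*n/2), so the earliest-tie rule places the cutoff at the
        # first split point
        assert best == 1

    def test_constant_proportions_warn_and_return_midpoint(self):
        ev = _daily_events([0.5] * 10)
        with pytest.warns(UserWarning, match="constant"):
            cut = dv.detect_cutoff(ev, dv.CutoffRule())
        assert cut[2021] == dt.date(2021, 7, 6)

    def test_too_few_days_rejected(self):
        with pytest.raises(ValueError, match="7 days"):
            dv.detect_cutoff(_daily_events([0.4, 0.1]), dv.CutoffRule())


class TestPhaseLabels:
    def test_boundary_date_is_late(self):
        ev = _daily_events([0.5])
        out = dv.phase_labels(ev, {2021: dt.date(2021, 7, 1)})
        assert (out["phase"] == "late").all()

    def test_all_before_cutoff_early(self):
        ev = _daily_events([0.5, 0.5])
        out = dv.phase_labels(ev, {2021: dt.date(2021, 9, 1)})
        assert (out["phase"] == "early").all()

    def test_mixed_set_matches_per_date_comparison(self):
        ev = _daily_events([0.5] * 10)
        cut = dt.date(2021, 7, 5)
        out = dv.phase_labels(ev, {2021: cut})
        expect = pd.to_datetime(ev["start_time"]).dt.date.map(
            lambda d: "early" if d < cut else "late")
        assert (out["phase"] == expect).all()

    def test_missing_year_rejected(self):
        with pytest.raises(KeyError, match="2021"):
            dv.phase_labels(_daily_events([0.5]), {2019: dt.date(2019, 8, 1)})


class TestDailySummary:
    def test_proportions(self):
        ev = _daily_events([0.75])
        out = dv.daily_summary(ev)
        assert out.loc[0, "n_dives"] == 100
        assert out.loc[0, "prop_U"] == 0.75 and out.loc[0, "prop_V"] == 0.25

    def test_single_u_dive_day(self):
        ev = pd.DataFrame({"bird_id": ["b1"], "start_time": [_ts(0)], "shape": ["U"]})
        out = dv.daily_summary(ev)
        assert out["prop_U"].iloc[0] == 1.0

    def test_empty_days_absent(self):
        ev = _daily_events([0.5, 0.5])
        assert len(dv.daily_summary(ev)) == 2


class TestPipelineProperties:
    def test_shuffling_trace_rows_changes_nothing(self, small_world):
        *_, traces, _ = small_world
        shuffled = traces.sample(frac=1.0, random_state=42)
        a = dv.process_traces(traces)
        b = dv.process_traces(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_shape_counts_partition_total(self, small_world):
        *_, traces, _ = small_world
        ev = dv.process_traces(traces)
        counts = ev["shape"].value_counts()
        assert counts.get("U", 0) + counts.get("V", 0) == len(ev)

    def test_truth_labels_recovered(self, small_world):
        *_, traces, truth = small_world
        ev = dv.process_traces(traces)
        merged = pd.merge_asof(
            ev.sort_values("start_time"),
            truth.dives.sort_values("timestamp").rename(columns={"shape": "true_shape"}),
            left_on="start_time", right_on="timestamp", by="bird_id",
            direction="nearest", tolerance=pd.Timedelta(seconds=10),
        )
        assert merged["true_shape"].notna().all()
        assert (merged["shape"] == merged["true_shape"]).all()
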