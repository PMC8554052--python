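import numpy as np
import pandas as pd
import pytest

import flyfae as F
from flyfae.rhythm_summary import CANONICAL_WINDOWS, DAY_NIGHT_WINDOWS

from conftest import make_events
from oracles import tally_hourly


class TestHourlySummarize:
    def test_half_open_hour_binning(self):
        events = make_events([("f", 0, 10, 10), ("f", 0, 3599, 10), ("f", 0, 3600, 20)])
        s = F.hourly_summarize(events, "f", 0)
        assert (s.faen_by_hour[0], s.faert_by_hour[0]) == (2, 20)
        assert (s.faen_by_hour[1], s.faert_by_hour[1]) == (1, 20)
        assert s.faen_by_hour[2:].sum() == 0

    def test_no_events_all_zero(self):
        s = F.hourly_summarize([], "f", 0)
        assert s.faen_by_hour.sum() == 0 and s.faert_by_hour.sum() == 0
        assert s.undefined_hours.all()

    def test_ratio_zero_flagged_when_empty(self):
        events = make_events([("f", 0, 100, 10)])
        s = F.hourly_summarize(events, "f", 0)
        assert s.faert_per_event_by_hour[0] == 10.0
        assert s.faert_per_event_by_hour[1] == 0.0 and s.undefined_hours[1]

    def test_retained_flag_respected(self):
        events = make_events([("f", 0, 100, 10, "unlabeled", False)])
        assert F.hourly_summarize(events, "f", 0).faen_by_hour.sum() == 0
        assert F.hourly_summarize(events, "f", 0, retained_only=False).faen_by_hour.sum() == 1

    def test_matches_brute_force_tally(self, small_cohort):
        cfg, plate, truth = small_cohort
        events = F.segment_plate(plate)
        for fly, day in {(e.fly_id, e.day_index) for e in events}:
            s = F.hourly_summarize(events, fly, day)
            rows = [(e.onset_zt_s, e.duration_s) for e in events
                    if e.fly_id == fly and e.day_index == day]
            faen, faert = tally_hourly(rows)
            assert s.faen_by_hour.tolist() == faen
            assert s.faert_by_hour.tolist() == faert


class TestWindowSummarize:
    def test_single_event_in_morning_window(self):
        events = make_events([("f", 0, 3600, 100)])  # ZT 1
        out = {w.window: w for w in F.window_summarize(events)}
        assert out["morning_peak"].per_fly["faert_s"].iloc[0] == 100
        for name in ("day_time", "evening_peak", "night_time"):
            assert out[name].per_fly["faert_s"].iloc[0] == 0

    def test_windows_consistent_with_hourly_cells(self, small_cohort):
        cfg, plate, truth = small_cohort
        events = F.apply_band_filter(F.segment_plate(plate))
        windows = F.window_summarize(events)
        summaries = F.hourly_summaries(events)
        for w in windows:
            h0, h1 = w.start_s // 3600, w.end_s // 3600
            for _, row in w.per_fly.iterrows():
                expected = sum(
                    s.faert_by_hour[h0:h1].sum()
                    for s in summaries if s.fly_id == row["fly_id"]
                )
                assert row["faert_s"] == expected

    def test_day_night_partition_sums_to_whole_day(self, small_cohort):
        cfg, plate, truth = small_cohort
        events = F.apply_band_filter(F.segment_plate(plate))
        dn = F.window_summarize(events, DAY_NIGHT_WINDOWS)
        total = F.window_summarize(events, {"all": (0, 86400)})
        combined = sum(w.per_fly["faert_s"].sum() for w in dn)
        assert combined == total[0].per_fly["faert_s"].sum()

    def test_overlapping_windows_rejected(self):
        events = make_events([("f", 0, 10, 5)])
        with pytest.raises(ValueError, match="overlap"):
            F.window_summarize(events, {"a": (0, 7200), "b": (3600, 10800)})
        F.window_summarize(events, {"a": (0, 7200), "b": (3600, 10800)},
                           allow_overlap=True)

    def test_canonical_windows_partition_day(self):
        spans = sorted(CANONICAL_WINDOWS.values())
        assert spans[0][0] == 0 and spans[-1][1] == 86400
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))


class TestGroupAggregate:
    def _summaries(self, faen_hour0):
        return [
            F.HourlySummary(f"f{i}", 0,
                            np.array([v] + [0] * 23),
                            np.array([float(v)] + [0.0] * 23))
            for i, v in enumerate(faen_hour0)
        ]

    def test_two_fly_mean_and_sem(self):
        curve = F.group_aggregate(self._summaries([2, 4]))["all"]
        assert curve.faen_mean[0] == 3 and curve.faen_sem[0] == 1
        assert curve.n_flies == 2

    def test_identical_flies_zero_sem(self):
        curve = F.group_aggregate(self._summaries([5, 5, 5]))["all"]
        assert curve.faen_sem[0] == 0

    def test_single_fly_sem_undefined(self):
        curve = F.group_aggregate(self._summaries([3]))["all"]
        assert np.isnan(curve.faen_sem).all() and curve.n_flies == 1

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            F.group_aggregate(self._summaries([1, 2]), groups={"f0": "a", "f1": "a", "ghost": "b"})

    def test_days_averaged_within_fly_first(self):
        sums = [
            F.HourlySummary("f0", 0, np.array([4] + [0] * 23), np.zeros(24)),
            F.HourlySummary("f0", 1, np.array([0] + [0] * 23), np.zeros(24)),
            F.HourlySummary("f1", 0, np.array([2] + [0] * 23), np.zeros(24)),
        ]
        curve = F.group_aggregate(sums)["all"]
        assert curve.n_flies == 2
        assert curve.faen_mean[0] == 2.0  # mean of (4+0)/2 and 2

    def test_permutation_invariance(self, small_cohort):
        cfg, plate, truth = small_cohort
        summaries = F.hourly_summaries(F.apply_band_filter(F.segment_plate(plate)))
        a = F.group_aggregate(summaries)["all"]
        b = F.group_aggregate(list(reversed(summaries)))["all"]
        np.testing.assert_allclose(a.faert_mean, b.faert_mean)
        np.testing.assert_allclose(a.faert_sem, b.faert_sem)

    def test_matches_brute_force_mean_sem(self, small_cohort):
        cfg, plate, truth = small_cohort
        summaries = F.hourly_summaries(F.apply_band_filter(F.segment_plate(plate)))
        curve = F.group_aggregate(summaries)["all"]
        flies = sorted({s.fly_id for s in summaries})
        for h in (0, 7, 13):
            vals = []
            for f in flies:
                per_day = [s.faert_by_hour[h] for s in summaries if s.fly_id == f]
                vals.append(sum(per_day) / len(per_day))
            mean = sum(vals) / len(vals)
            sd = (sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
            assert curve.faert_mean[h] == pytest.approx(mean)
            assert curve.faert_sem[h] == pytest.approx(sd / len(vals) ** 0.5)


class TestCompareGroups:
    def test_identical_samples(self):
        rep = F.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.statistic == 0.0 and rep.p_value == 1.0
        assert rep.stars == "n.s."

    def test_extreme_separation_four_stars(self):
        rep = F.compare_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert rep.p_value < 1e-4 and rep.stars == "****"

    def test_one_way_anova_with_tukey(self, rng):
        groups = [rng.normal(m, 1, 12) for m in (0, 0, 3)]
        rep = F.compare_groups(groups=groups, design="one_way",
                               labels=["a", "b", "c"])
        assert rep.p_value < 1e-3
        assert len(rep.pairwise) == 3
        ac = rep.pairwise.query("group1 == 'a' and group2 == 'c'").iloc[0]
        assert float(ac["p-adj"]) < 0.01

    def test_two_way_anova_interaction(self, rng):
        rows = []
        for a in ("wt", "mut"):
            for b in ("LD", "DD"):
                shift = 3.0 if (a == "mut" and b == "DD") else 0.0
                for v in rng.normal(shift, 1, 10):
                    rows.append({"value": v, "factor_a": a, "factor_b": b})
        rep = F.compare_groups(data=pd.DataFrame(rows), design="two_way")
        assert rep.design == "two_way" and rep.p_value < 0.01
        assert {"term"} <= set(rep.table.columns)

    def test_two_way_empty_cell_error(self):
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0, 4.0],
                           "factor_a": ["x", "x", "y", "y"],
                           "factor_b": ["p", "p", "q", "q"]})  # x:q and y:p empty
        with pytest.raises(ValueError, match="cell"):
            F.compare_groups(data=df, design="two_way")

    def test_significance_star_levels(self):
        assert F.significance_stars(0.04) == "*"
        assert F.significance_stars(0.009) == "**"
        assert F.significance_stars(0.0009) == "***"
        assert F.significance_stars(0.00009) == "****"
        assert F.significance_stars(0.2) == "n.s."
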