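"""Regularization, resting-bout detection, trimming and activity metrics."""

import numpy as np
import pandas as pd
import pytest

from energyscape.acceleration import odba_records
from energyscape.tracks import (
    ActivityBout,
    activity_metrics,
    activity_score,
    detect_rest_bouts,
    label_records,
    regularize,
    trim_deployment,
    urbanization_correlations,
)

TS = pd.Timestamp("2021-03-01 00:00:00+00:00")


def _track(minutes, activity, schedule="dynamic", x=None):
    n = len(minutes)
    return pd.DataFrame(
        {
            "individual_id": "A",
            "timestamp": [TS + pd.Timedelta(minutes=m) for m in minutes],
            "x": np.arange(n, dtype=float) if x is None else np.asarray(x, float),
            "y": 0.0,
            "schedule_flag": schedule,
            "synthetic_flag": False,
            "activity": activity,
        }
    )


class TestRegularize:
    def test_inactive_gap_filled(self):
        tr = _track([0, 60], ["rest", "rest"], x=[5.0, 5.0])
        out = regularize(tr)
        inserted = out.loc[out["synthetic_flag"]]
        assert len(inserted) == 5  # 10..50 min inside the gap
        assert (inserted["x"] == 5.0).all()
        gaps = out["timestamp"].diff().dt.total_seconds().dropna()
        assert (gaps == 600.0).all()

    def test_fixed_schedule_untouched(self):
        tr = _track([0, 10, 20], ["active"] * 3, schedule="fixed10")
        pd.testing.assert_frame_equal(regularize(tr), tr)

    def test_two_minute_runs_thinned(self):
        tr = _track(list(range(0, 60, 2)), ["active"] * 30)
        out = regularize(tr)
        gaps = out["timestamp"].diff().dt.total_seconds().dropna()
        assert (gaps >= 600.0).all()

    def test_unlabeled_rejected(self):
        tr = _track([0, 10], ["active", "active"]).drop(columns=["activity"])
        with pytest.raises(ValueError, match="activity"):
            regularize(tr)

    def test_regularized_on_simulated_track(self, one_individual):
        track, _, _ = one_individual
        out = regularize(track)
        gaps = out["timestamp"].diff().dt.total_seconds().dropna()
        assert (gaps >= 600.0 - 1e-9).all()


def _records(hours, scores):
    """One burst every 3 min across `hours`, with per-hour scores."""
    rows, sc = [], []
    for h, s in zip(hours, scores):
        for m in range(0, 60, 3):
            rows.append({"timestamp": TS + pd.Timedelta(hours=h, minutes=m)})
            sc.append(s)
    return pd.DataFrame(rows), np.array(sc, float)


class TestDetectRestBouts:
    def test_clean_diurnal_block(self):
        hours = list(range(48))
        scores = [0.01 if (9 <= h % 24 < 15) else 2.0 for h in hours]
        rec, sc = _records(hours, scores)
        bouts = detect_rest_bouts(rec, sc)
        rest = [b for b in bouts if b.state == "rest"]
        assert len(rest) == 2
        for b in rest:
            assert b.duration == pytest.approx(6 * 3600, abs=2 * 180 + 60)

    def test_all_active(self):
        rec, sc = _records(range(24), [2.0] * 24)
        assert all(b.state == "active" for b in detect_rest_bouts(rec, sc))

    def test_short_low_block_not_rest(self):
        hours = list(range(24))
        scores = [0.01 if 10 <= h < 13 else 2.0 for h in hours]  # 3 h block
        rec, sc = _records(hours, scores)
        assert all(b.state == "active" for b in detect_rest_bouts(rec, sc))

    def test_night_extension_still_rest(self):
        # low block 14:00 - 21:00 intersects the day window, extends past it
        hours = list(range(24))
        scores = [0.01 if 14 <= h < 21 else 2.0 for h in hours]
        rec, sc = _records(hours, scores)
        rest = [b for b in detect_rest_bouts(rec, sc) if b.state == "rest"]
        assert len(rest) == 1

    def test_short_record_warns(self):
        rec, sc = _records(range(2), [0.01, 0.01])
        with pytest.warns(UserWarning):
            bouts = detect_rest_bouts(rec, sc)
        assert all(b.state == "active" for b in bouts)

    def test_recall_on_simulated_individual(self, small_cfg, world, one_individual):
        _, truth = world
        _, bursts, bt = one_individual
        rec = odba_records(bursts)
        scores = np.array([activity_score(b) for b in bursts])
        bouts = detect_rest_bouts(rec, scores, burst_period=small_cfg.burst_period)
        lab = label_records(rec, bouts)
        ts = pd.to_datetime(lab["timestamp"])
        true_rest = np.zeros(len(ts), bool)
        for s, e in truth.true_rest_intervals["S01"]:
            true_rest |= ((ts >= s) & (ts < e)).to_numpy()
        detected = (lab["activity"] == "rest").to_numpy()
        recall = detected[true_rest].mean()
        assert recall >= 0.95


class TestTrimDeployment:
    def test_default_48h(self):
        tr = _track(np.arange(0, 10 * 1440, 60), ["active"] * 240)
        out = trim_deployment(tr)
        assert out["timestamp"].min() >= TS + pd.Timedelta(hours=48)

    def test_short_record_empties_with_warning(self):
        tr = _track([0, 60], ["active"] * 2)
        with pytest.warns(UserWarning):
            assert len(trim_deployment(tr)) == 0

    def test_zero_hours_identity(self):
        tr = _track([0, 60], ["active"] * 2)
        pd.testing.assert_frame_equal(trim_deployment(tr, hours=0), tr)


class TestActivityMetrics:
    def test_stationary_day_zero_distance(self):
        tr = _track([0, 300, 600], ["active"] * 3, x=[1.0, 1.0, 1.0])
        out = activity_metrics(tr, [], day_boundary=0)
        assert (out["cumulative_distance"] == 0).all()

    def test_two_fixes_distance(self):
        tr = _track([0, 10], ["active"] * 2, x=[0.0, 300.0])
        out = activity_metrics(tr, [], day_boundary=0)
        assert out["cumulative_distance"].iloc[0] == pytest.approx(300.0)

    def test_bouts_counted_by_start_day(self):
        bouts = [
            ActivityBout(TS + pd.Timedelta(hours=2), TS + pd.Timedelta(hours=4), "active"),
            ActivityBout(TS + pd.Timedelta(hours=30), TS + pd.Timedelta(hours=31), "active"),
        ]
        tr = _track([0, 10], ["active"] * 2)
        out = activity_metrics(tr, bouts, day_boundary=0).set_index("day")
        assert (out["n_active_bouts"] == 1).all() and len(out) == 2


class TestUrbanizationCorrelations:
    def test_identity_metric(self):
        urb = pd.Series([0.1, 0.2, 0.4, 0.5], index=list("abcd"))
        metrics = pd.DataFrame({"m": urb})
        out = urbanization_correlations(metrics, urb)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)

    def test_slope_recovery(self, rng):
        urb = pd.Series(rng.uniform(0, 0.5, 12), index=[f"i{k}" for k in range(12)])
        y = 2.0 * urb + rng.normal(0, 0.02, 12)
        out = urbanization_correlations(pd.DataFrame({"m": y}), urb).iloc[0]
        assert abs(out["slope"] - 2.0) <= 3 * out["slope_se"]

    def test_null_metric_small_r(self, rng):
        urb = pd.Series(np.linspace(0, 0.5, 12), index=[f"i{k}" for k in range(12)])
        rs = []
        for _ in range(50):
            y = pd.DataFrame({"m": rng.normal(size=12)}, index=urb.index)
            rs.append(urbanization_correlations(y, urb)["pearson_r"].iloc[0])
        assert abs(np.mean(rs)) < 0.15

    def test_zero_variance_rejected(self):
        urb = pd.Series([0.2, 0.2, 0.2], index=list("abc"))
        with pytest.raises(ValueError):
            urbanization_correlations(pd.DataFrame({"m": [1.0, 2.0, 3.0]}, index=urb.index), urb)

    def test_too_few_individuals_rejected(self):
        urb = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError):
            urbanization_correlations(pd.DataFrame({"m": [1.0, 2.0]}, index=urb.index), urb)
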