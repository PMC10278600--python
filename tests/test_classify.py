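"""Circularity classes, invasive-phenotype calls, QC and period summaries."""

import numpy as np
import pandas as pd
import pytest

from pamp.classify import (CircularityClass, call_invasive, classify_circularity,
                           invasive_fraction, period_summaries, qc_control)


def straight_track(total_um, n=25, t0=0.0, dt_h=1.0):
    xy = np.column_stack([np.linspace(0, total_um, n), np.zeros(n)])
    return t0 + dt_h * np.arange(n), xy


class TestCircularityClasses:
    @pytest.mark.parametrize("value,expected", [
        (30.0, CircularityClass.ELONGATED),
        (80.0, CircularityClass.ROUNDED),
        (25.0, CircularityClass.ELONGATED),   # boundary assigned upward
        (50.0, CircularityClass.OVAL),
        (75.0, CircularityClass.ROUNDED),
        (100.0, CircularityClass.ROUNDED),
        (0.5, CircularityClass.VERY_ELONGATED),
    ])
    def test_binning(self, value, expected):
        assert classify_circularity(value) is expected

    @pytest.mark.parametrize("value", [0.0, -5.0, 100.1])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_circularity(value)

    def test_bins_partition_valid_range(self):
        for value in np.linspace(0.01, 100.0, 997):
            cls = classify_circularity(float(value))
            assert cls.lo <= value <= cls.hi

    def test_state_annotations(self):
        assert "invasive" in CircularityClass.VERY_ELONGATED.state
        assert "migratory" in CircularityClass.ELONGATED.state.lower()


class TestInvasiveCall:
    def test_far_and_straight_is_invasive(self):
        # euclid 141.4 µm, meandering 70.7%
        t = np.arange(5, dtype=float)
        xy = np.column_stack([np.linspace(0, 100, 5), np.linspace(0, 100, 5)])
        call = call_invasive(t, xy, eval_time_h=4.0)
        assert call.euclid_um == pytest.approx(141.42, abs=0.1)
        assert call.invasive

    def test_short_displacement_not_invasive(self):
        # high meandering but only 50 µm of net displacement
        t, xy = straight_track(50.0)
        call = call_invasive(t, xy, eval_time_h=t[-1])
        assert call.meandering_pct == pytest.approx(100.0)
        assert not call.invasive

    def test_boundaries_are_strict(self):
        # exactly 100 µm and exactly 25% both fail the strict thresholds
        t, xy = straight_track(100.0)
        assert not call_invasive(t, xy, eval_time_h=t[-1]).invasive
        # net 120 µm over 480 µm of path: meandering exactly 25%
        legs = np.array([[0.0, 0.0], [300.0, 0.0], [120.0, 0.0]])
        t3 = np.arange(3, dtype=float)
        call = call_invasive(t3, np.column_stack([legs[:, 0], legs[:, 1]]), eval_time_h=2.0)
        assert call.meandering_pct == pytest.approx(25.0)
        assert not call.invasive

    def test_evaluation_uses_history_up_to_time(self):
        # far by 10 h, returns to origin by 20 h
        t = np.linspace(0, 20, 41)
        x = np.concatenate([np.linspace(0, 200, 21), np.linspace(190, 0, 20)])
        xy = np.column_stack([x, np.zeros(41)])
        assert call_invasive(t, xy, eval_time_h=10.0).invasive
        assert not call_invasive(t, xy, eval_time_h=20.0).invasive


class TestInvasiveFraction:
    def _table(self, tracks):
        rows = []
        for tid, (t, xy) in enumerate(tracks):
            for fr, (x, y) in enumerate(xy):
                rows.append({"frame": fr, "track_id": tid, "x_um": x, "y_um": y})
        return pd.DataFrame(rows)

    def test_three_of_ten(self):
        dt_h = 0.5
        tracks = []
        for i in range(10):
            total = 300.0 if i < 3 else 10.0
            xy = np.column_stack([np.linspace(0, total, 41), np.zeros(41)])
            tracks.append((None, xy))
        table = self._table(tracks)
        frac, calls = invasive_fraction(table, frame_interval_min=30.0, eval_time_h=20.0)
        assert frac == pytest.approx(30.0)
        assert len(calls) == 10

    def test_stationary_population_is_zero(self):
        tracks = [(None, np.zeros((41, 2))) for _ in range(5)]
        frac, _ = invasive_fraction(self._table(tracks), 30.0, 20.0)
        assert frac == 0.0

    def test_no_eligible_tracks_is_nan(self):
        tracks = [(None, np.zeros((3, 2)))]  # ends long before eval time
        frac, calls = invasive_fraction(self._table(tracks), 5.0, 20.0)
        assert np.isnan(frac) and calls == []

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        tracks = [(None, np.cumsum(rng.normal(0, 8, (41, 2)), axis=0)) for _ in range(40)]
        table = self._table(tracks)
        f_loose, _ = invasive_fraction(table, 30.0, 20.0,
                                       euclid_threshold_um=20.0, meandering_threshold_pct=5.0)
        f_mid, _ = invasive_fraction(table, 30.0, 20.0,
                                     euclid_threshold_um=60.0, meandering_threshold_pct=5.0)
        f_tight, _ = invasive_fraction(table, 30.0, 20.0,
                                       euclid_threshold_um=60.0, meandering_threshold_pct=40.0)
        assert f_loose >= f_mid >= f_tight


def _features(masses, areas, circ=70.0):
    """Feature table with one cell per (frame, value) pair."""
    rows = []
    for frame, (m_list, a_list) in enumerate(zip(masses, areas)):
        for tid, (m, a) in enumerate(zip(m_list, a_list)):
            rows.append({"track_id": tid, "frame": frame, "time_h": frame * 0.5,
                         "mass_pg": m, "area_um2": a, "perimeter_um": 100.0,
                         "circularity_pct": circ, "density_pg_per_um2": m / a,
                         "x_um": 0.0, "y_um": 0.0, "border": False})
    return pd.DataFrame(rows)


class TestQCControl:
    def _tracks(self, speed_1, speed_2, n_cells=8):
        """Constant-speed tracks: speed_1 µm/h before 10 h, speed_2 after."""
        rows = []
        for tid in range(n_cells):
            x = 0.0
            for fr in range(241):
                t = fr * 5.0 / 60.0
                rows.append({"frame": fr, "track_id": tid, "x_um": x, "y_um": 0.0})
                x += (speed_1 if t < 10 else speed_2) * 5.0 / 60.0
        return pd.DataFrame(rows)

    def test_healthy_control_raises_no_flags(self):
        n_frames = 41
        masses = [[200.0 + 0.1 * f] * (4 + f // 20) for f in range(n_frames)]
        areas = [[600.0] * (4 + f // 20) for f in range(n_frames)]
        report = qc_control(_features(masses, areas), self._tracks(20.0, 22.0),
                            frame_interval_min=5.0)
        assert not report.flag_count_decrease
        assert not report.flag_morphology_drift
        assert not report.flag_speed_drift

    def test_death_scenario_raises_count_and_morphology_flags(self):
        n_frames = 41
        masses, areas = [], []
        for f in range(n_frames):
            n = 8 if f < 20 else 4  # count halves
            shrink = 1.0 - 0.5 * f / n_frames  # cells shrink
            masses.append([200.0 * shrink] * n)
            areas.append([600.0 * shrink] * n)
        report = qc_control(_features(masses, areas), self._tracks(20.0, 20.0),
                            frame_interval_min=5.0)
        assert report.flag_count_decrease
        assert report.flag_morphology_drift

    def test_speed_drift_flagged(self):
        n_frames = 41
        masses = [[200.0] * 5] * n_frames
        areas = [[600.0] * 5] * n_frames
        report = qc_control(_features(masses, areas), self._tracks(10.0, 30.0),
                            frame_interval_min=5.0)
        assert report.flag_speed_drift
        assert not report.flag_count_decrease


class TestPeriodSummaries:
    def _density_features(self, density_of_time):
        rows = []
        for frame in range(241):
            t = frame * 5.0 / 60.0
            d = density_of_time(t)
            rows.append({"track_id": 0, "frame": frame, "time_h": t,
                         "mass_pg": d * 500.0, "area_um2": 500.0, "perimeter_um": 90.0,
                         "circularity_pct": 60.0, "density_pg_per_um2": d,
                         "x_um": 0.0, "y_um": 0.0, "border": False})
        return pd.DataFrame(rows)

    def test_constant_density_zero_changes(self):
        _, snaps = period_summaries(self._density_features(lambda t: 0.35))
        row = snaps.iloc[0]
        assert row["change_0_10_pct"] == pytest.approx(0.0)
        assert row["change_10_20_pct"] == pytest.approx(0.0)
        assert row["change_0_20_pct"] == pytest.approx(0.0)

    def test_linear_doubling_is_plus_100(self):
        _, snaps = period_summaries(self._density_features(lambda t: 0.2 * (1 + t / 20.0)))
        assert snaps.iloc[0]["change_0_20_pct"] == pytest.approx(100.0)

    def test_exponential_growth_closed_form(self):
        # 3%/h for 10 h → 100·(e^0.3 − 1) ≈ +34.99%
        _, snaps = period_summaries(self._density_features(lambda t: 0.2 * np.exp(0.03 * t)))
        assert snaps.iloc[0]["change_0_10_pct"] == pytest.approx(
            100.0 * (np.exp(0.3) - 1.0), rel=0.03)

    def test_pooled_periods_partition_samples(self):
        feats = self._density_features(lambda t: 0.3)
        pooled, _ = period_summaries(feats)
        assert set(pooled.period) == {0, 1}
        assert len(pooled) >= len(feats)  # frame at 10 h enters both windows

    def test_border_cells_excluded(self):
        feats = self._density_features(lambda t: 0.3)
        feats.loc[feats.frame == 0, "border"] = True
        pooled, _ = period_summaries(feats)
        assert 0.0 not in pooled.time_h.values
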