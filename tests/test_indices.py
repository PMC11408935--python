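"""VPD/SVP, the air-temperature window, the three stress indices, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fruitherm import (svp, vpd, air_temp_avg, fwsi_irmak, fwsi_jones,
                       fwsi_norm, delta_t, index_records, summarize,
                       make_weather, MissingDataError)

finite_t = st.floats(min_value=-30.0, max_value=60.0)


class TestSVPandVPD:
    def test_svp_at_zero_is_the_magnus_constant(self):
        assert svp(0.0) == 610.7

    def test_svp_at_20_matches_hand_evaluation(self):
        # 610.7 * 10^(150 / 257.3)
        assert svp(20.0) == pytest.approx(610.7 * 10 ** (150.0 / 257.3))
        assert svp(20.0) == pytest.approx(2338.0, rel=2e-3)

    def test_svp_monotone(self):
        assert svp(25.0) > svp(20.0)

    def test_svp_domain_error(self):
        with pytest.raises(ValueError):
            svp(-240.0)

    def test_vpd_zero_iff_saturated(self):
        assert vpd(20.0, 100.0) == 0.0
        for rh in (0.0, 35.0, 99.9):
            assert vpd(20.0, rh) > 0.0

    def test_vpd_full_deficit_anchor(self):
        assert vpd(0.0, 0.0) == pytest.approx(0.6107)

    def test_vpd_hand_evaluation(self):
        assert vpd(20.0, 50.0) == pytest.approx(1.169, abs=0.001)

    def test_vpd_rejects_bad_humidity(self):
        with pytest.raises(ValueError):
            vpd(20.0, 101.0)


class TestAirTempAverage:
    def _weather(self, hourly_means):
        rows = []
        for h, t in hourly_means.items():
            for m in (0, 15, 30, 45):
                rows.append({"timestamp": f"2022-09-21 {h:02d}:{m:02d}",
                             "t_air_c": t})
        return pd.DataFrame(rows)

    def test_constant_series(self):
        w = self._weather({h: 20.0 for h in range(24)})
        assert air_temp_avg(w, 13) == 20.0

    def test_window_is_hours_minus5_to_minus2(self):
        w = self._weather({8: 10.0, 9: 12.0, 10: 14.0, 11: 16.0, 12: 99.0})
        assert air_temp_avg(w, 13) == pytest.approx(13.0)

    def test_missing_hour_is_named(self):
        w = self._weather({8: 10.0, 9: 12.0, 11: 16.0})
        with pytest.raises(MissingDataError, match=r"\[10\]"):
            air_temp_avg(w, 13)

    def test_sub_hourly_records_averaged_within_hour(self):
        w = make_weather(seed=2)
        ts = pd.to_datetime(w["timestamp"])
        expect = np.mean([w.loc[ts.dt.hour == h, "t_air_c"].mean()
                          for h in (8, 9, 10, 11)])
        assert air_temp_avg(w, 13) == pytest.approx(expect)


class TestIndices:
    def test_irmak_anchors_and_arithmetic(self):
        assert fwsi_irmak(20.0, 20.0, 28.0) == 0.0
        assert fwsi_irmak(33.0, 20.0, 28.0) == pytest.approx(1.0)  # T_a + 5
        assert fwsi_irmak(30.0, 20.0, 28.0) == pytest.approx(10.0 / 13.0)

    def test_irmak_monotone_in_fruit_and_air_temperature(self):
        assert fwsi_irmak(31.0, 20.0, 28.0) > fwsi_irmak(30.0, 20.0, 28.0)
        assert fwsi_irmak(30.0, 20.0, 29.0) < fwsi_irmak(30.0, 20.0, 28.0)

    def test_irmak_degenerate_day(self):
        with pytest.raises(ZeroDivisionError):
            fwsi_irmak(25.0, 25.0, 20.0)  # T_a + 5 == minT

    def test_jones_anchors_and_midpoint(self):
        assert fwsi_jones(20.0, 20.0, 30.0) == 0.0
        assert fwsi_jones(30.0, 20.0, 30.0) == 1.0
        assert fwsi_jones(25.0, 20.0, 30.0) == 0.5

    def test_jones_outside_unit_interval_is_flagged_not_rejected(self):
        with pytest.warns(UserWarning, match="outside"):
            assert fwsi_jones(40.0, 20.0, 30.0) == pytest.approx(2.0)

    def test_jones_degenerate_references(self):
        with pytest.raises(ValueError, match="degenerate"):
            fwsi_jones(25.0, 24.0, 24.05)

    def test_norm_anchors_and_midpoint(self):
        assert fwsi_norm(20.0, 20.0, 30.0) == 0.0
        assert fwsi_norm(30.0, 20.0, 30.0) == 1.0
        assert fwsi_norm(25.0, 20.0, 30.0) == 0.5

    def test_norm_on_own_extremes_attains_exactly_zero_and_one(self, rng):
        t = rng.uniform(10, 40, 200)
        v = fwsi_norm(t, t.min(), t.max())
        assert v.max() == 1.0 and v.min() == 0.0
        assert ((v >= 0) & (v <= 1)).all()

    @given(t=finite_t, lo=finite_t, hi=finite_t,
           a=st.floats(min_value=0.1, max_value=5.0),
           b=st.floats(min_value=-20.0, max_value=20.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_norm_invariant_under_common_affine_transform(self, t, lo, hi, a, b):
        if not hi > lo + 1e-6:
            return
        t = min(max(t, lo), hi)
        v1 = fwsi_norm(t, lo, hi)
        v2 = fwsi_norm(a * t + b, a * lo + b, a * hi + b)
        assert v2 == pytest.approx(v1, abs=1e-6)

    def test_delta_t_antisymmetry(self):
        assert delta_t(30.0, 25.0) == 5.0
        assert delta_t(25.0, 25.0) == 0.0
        assert delta_t(25.0, 30.0) == -delta_t(30.0, 25.0)


class TestIndexRecords:
    def _fruit(self, rng, n=40):
        return pd.DataFrame({
            "fruit_id": np.arange(1, n + 1),
            "t_est_c": rng.uniform(18, 32, n),
            "height_m": rng.uniform(0.8, 2.8, n),
            "timestamp": pd.Timestamp("2022-09-21 13:00"),
        })

    def test_norm_always_present_others_need_weather(self, rng):
        rec = index_records(self._fruit(rng))
        assert "fwsi_n" in rec.columns
        assert "fwsi_i" not in rec.columns and "vpd_kpa" not in rec.columns
        rec2 = index_records(self._fruit(rng), t_a=22.0, vpd_kpa=1.2)
        assert {"fwsi_i", "delta_t_c", "t_a_c", "vpd_kpa"} <= set(rec2.columns)

    def test_jones_marked_not_recommended(self, rng):
        rec = index_records(self._fruit(rng), wet_t=15.0, dry_t=35.0)
        assert "fwsi_j" in rec.columns
        assert "not recommended" in rec.attrs["fwsi_j_note"]

    def test_mean_of_pointwise_equals_index_of_mean_with_shared_extremes(self, rng):
        # linearity of the normalized index under day-shared extremes
        t = rng.uniform(15, 35, 100)
        lo, hi = t.min(), t.max()
        assert np.mean(fwsi_norm(t, lo, hi)) == pytest.approx(
            fwsi_norm(float(t.mean()), lo, hi))


class TestSummarize:
    def _records(self, rng):
        n = 120
        return pd.DataFrame({
            "fruit_id": np.arange(n),
            "t_est_c": rng.uniform(15, 35, n),
            "fwsi_n": rng.uniform(0, 1, n),
            "height_m": rng.uniform(0.7, 3.0, n),
            "timestamp": pd.to_datetime("2022-09-21")
            + pd.to_timedelta(rng.integers(7, 19, n), unit="h"),
        })

    def test_grouped_means_match_flat_recomputation(self, rng):
        rec = self._records(rng)
        table = summarize(rec, by="hour")
        for _, row in table.iterrows():
            sub = rec[pd.to_datetime(rec["timestamp"]).dt.hour == row["hour"]]
            assert row["fwsi_n_mean"] == pytest.approx(sub["fwsi_n"].mean())
            assert row["fwsi_n_n"] == len(sub)
            assert row["t_est_c_max"] == pytest.approx(sub["t_est_c"].max())

    def test_height_bins_span_the_configured_range(self, rng):
        table = summarize(self._records(rng), by="height_bin",
                          height_bin_width=0.35, height_range=(0.7, 3.0))
        assert table["fwsi_n_n"].sum() > 0
        assert len(table) <= int(np.ceil((3.0 - 0.7) / 0.35))

    def test_single_record_group_has_zero_like_sd(self, rng):
        rec = self._records(rng).iloc[:1]
        table = summarize(rec, by="date")
        assert table["fwsi_n_mean"].iloc[0] == rec["fwsi_n"].iloc[0]
        assert np.isnan(table["fwsi_n_std"].iloc[0]) or table["fwsi_n_std"].iloc[0] == 0.0

    def test_two_values_mean(self):
        rec = pd.DataFrame({"fwsi_n": [0.4, 0.6],
                            "timestamp": ["2022-09-21 12:00"] * 2})
        assert summarize(rec, by="date")["fwsi_n_mean"].iloc[0] == pytest.approx(0.5)

    def test_unknown_grouping_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown grouping"):
            summarize(self._records(rng), by="tree")
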