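"""Instrument-log parsing, alignment, window averaging and filter maths."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nephqc import (
    AlignmentError,
    CoLocationSample,
    FilterSample,
    FormatError,
    InputError,
    WindowError,
    align_series,
    duplicate_precision,
    gravimetric_concentration,
    read_campaign,
    read_neph_log,
    read_rh_log,
    window_average,
    write_campaign,
)
from nephqc.sample_io import NephTimeSeries, RHTimeSeries, write_neph_log, write_rh_log
from nephqc.synthetic import GeneratorConfig, generate_campaign, generate_timeseries


def _ts(n, start="2014-03-01T06:00:00", step_s=10):
    return pd.date_range(start, periods=n, freq=f"{step_s}s")


class TestReadNephLog:
    def test_parses_rows_in_order(self, tmp_path):
        p = tmp_path / "neph.csv"
        p.write_text(
            "timestamp,pm_ugm3\n"
            "2014-03-01T06:00:00,100\n2014-03-01T06:00:10,200\n2014-03-01T06:00:20,300\n"
        )
        s = read_neph_log(p, "A")
        assert len(s) == 3
        assert s.pm.mean() == 200

    def test_drops_blank_pm_cells(self, tmp_path, caplog):
        p = tmp_path / "neph.csv"
        p.write_text(
            "timestamp,pm_ugm3\n"
            "2014-03-01T06:00:00,100\n2014-03-01T06:00:10,\n"
            "2014-03-01T06:00:20,300\n2014-03-01T06:00:30,500\n"
        )
        with caplog.at_level("WARNING"):
            s = read_neph_log(p, "A")
        assert len(s) == 3
        assert "dropped 1" in caplog.text

    def test_bad_header_is_format_error(self, tmp_path):
        p = tmp_path / "neph.csv"
        p.write_text("time,pm\n2014-03-01T06:00:00,100\n")
        with pytest.raises(FormatError):
            read_neph_log(p, "A")

    def test_all_rows_unparseable_is_input_error(self, tmp_path):
        p = tmp_path / "neph.csv"
        p.write_text("timestamp,pm_ugm3\nnot-a-time,x\n")
        with pytest.raises(InputError):
            read_neph_log(p, "A")


class TestReadRHLog:
    @pytest.mark.parametrize(
        "values,expected",
        [([45, 60, 80], [0.45, 0.60, 0.80]), ([0.45, 0.60, 0.80], [0.45, 0.60, 0.80])],
        ids=["percent-autodetected", "fraction-unchanged"],
    )
    def test_unit_autodetection(self, tmp_path, values, expected):
        p = tmp_path / "rh.csv"
        rows = "\n".join(
            f"2014-03-01T06:00:{i:02d},25,{v}" for i, v in enumerate(values)
        )
        p.write_text("timestamp,temp_c,rh\n" + rows + "\n")
        s = read_rh_log(p, "A")
        assert np.allclose(s.rh, expected)

    def test_saturated_rh_clamped_to_cap(self, tmp_path, caplog):
        p = tmp_path / "rh.csv"
        p.write_text("timestamp,temp_c,rh\n2014-03-01T06:00:00,25,100\n"
                     "2014-03-01T06:00:10,25,50\n")
        with caplog.at_level("WARNING"):
            s = read_rh_log(p, "A")
        assert s.rh[0] == 0.99
        assert "clamped 1" in caplog.text

    def test_percent_header_with_fractional_values_is_ambiguous(self, tmp_path):
        p = tmp_path / "rh.csv"
        p.write_text("timestamp,temp_c,rh_pct\n2014-03-01T06:00:00,25,0.45\n")
        with pytest.raises(FormatError):
            read_rh_log(p, "A")


class TestAlignSeries:
    def _series(self, offset_s=0, n=6, step_s=60):
        # coarse spacing so an offset beyond tolerance has no near neighbour
        neph = NephTimeSeries("A", _ts(n, step_s=step_s), np.linspace(100, 600, n))
        rh = RHTimeSeries(
            "A", _ts(n, step_s=step_s) + pd.Timedelta(seconds=offset_s), np.full(n, 0.5)
        )
        return neph, rh

    def test_identical_timestamps_all_match(self):
        aligned = align_series(*self._series(0))
        assert len(aligned) == 6

    @pytest.mark.parametrize("offset", [3, -3])
    def test_small_offset_within_tolerance_matches_all(self, offset):
        aligned = align_series(*self._series(offset), tolerance=5)
        assert len(aligned) == 6

    def test_offset_beyond_tolerance_raises(self):
        with pytest.raises(AlignmentError):
            align_series(*self._series(12), tolerance=5)

    @given(offset=st.integers(min_value=-5, max_value=5))
    def test_symmetric_in_offset_sign(self, offset):
        n_pos = len(align_series(*self._series(offset), tolerance=5))
        n_neg = len(align_series(*self._series(-offset), tolerance=5))
        assert n_pos == n_neg


class TestWindowAverage:
    def _aligned(self, n=11):
        return pd.DataFrame(
            {"timestamp": _ts(n), "pm": np.arange(n) * 100.0, "rh": np.full(n, 0.6)}
        )

    def test_mean_over_window(self):
        df = pd.DataFrame(
            {"timestamp": _ts(2), "pm": [100.0, 300.0], "rh": [0.5, 0.7]}
        )
        mean_pm, mean_rh, n = window_average(df, _ts(2)[0], _ts(2)[-1])
        assert mean_pm == 200
        assert mean_rh == pytest.approx(0.6)
        assert n == 2

    def test_partial_window_uses_only_contained_rows(self):
        df = self._aligned(11)
        mean_pm, _, n = window_average(df, df["timestamp"][0], df["timestamp"][4])
        assert n == 5
        assert mean_pm == np.mean(np.arange(5) * 100.0)

    def test_empty_window_raises(self):
        df = self._aligned(3)
        with pytest.raises(WindowError):
            window_average(df, "2020-01-01", "2020-01-02")

    def test_thirty_minute_event_has_181_inclusive_ticks(self):
        # 1800 s at 10-s spacing, inclusive ends: 1800/10 + 1
        neph, rh = generate_timeseries(1.0, events=((10.0, 40.0),), seed=0)
        aligned = align_series(neph, rh)
        start = neph.timestamps[0] + pd.Timedelta(minutes=10)
        end = neph.timestamps[0] + pd.Timedelta(minutes=40)
        _, _, n = window_average(aligned, start, end)
        assert n == 181


class TestGravimetricConcentration:
    def test_hand_computed_concentration(self):
        # net 480 µg over 4 L/min × 30 min = 0.12 m³ -> 4000 µg/m³
        f = FilterSample("F1", pre_weight=1000, post_weight=1482, duration=30)
        conc, below = gravimetric_concentration(f)
        assert conc == pytest.approx(4000.0)
        assert not below

    def test_net_mass_under_lod_is_flagged(self):
        f = FilterSample("F2", pre_weight=1000, post_weight=1006, duration=30)
        conc, below = gravimetric_concentration(f)
        assert below
        assert conc == pytest.approx(4.0 / 0.12)

    def test_zero_and_negative_net_mass(self):
        f0 = FilterSample("F3", pre_weight=1000, post_weight=1002, duration=30)
        assert gravimetric_concentration(f0) == (0.0, True)
        fneg = FilterSample("F4", pre_weight=1000, post_weight=1000, duration=30)
        assert gravimetric_concentration(fneg) == (0.0, True)

    def test_invalid_filter_inputs(self):
        with pytest.raises(InputError):
            FilterSample("F5", 1000, 1100, duration=0)
        with pytest.raises(InputError):
            FilterSample("F6", 1000, 900, duration=30)

    @given(
        net=st.floats(min_value=10, max_value=5000),
        duration=st.floats(min_value=5, max_value=480),
    )
    def test_linear_in_mass_inverse_in_duration(self, net, duration):
        f = FilterSample("F", 0.0, net + 2.0, duration=duration)
        f2x = FilterSample("F", 0.0, 2 * net + 2.0, duration=duration)
        fslow = FilterSample("F", 0.0, net + 2.0, duration=2 * duration)
        c = gravimetric_concentration(f)[0]
        assert gravimetric_concentration(f2x)[0] == pytest.approx(2 * c)
        assert gravimetric_concentration(fslow)[0] == pytest.approx(c / 2)


class TestDuplicatePrecision:
    @pytest.mark.parametrize(
        "pairs,expected_mean",
        [
            ([(100.0, 100.0)], 0.0),
            ([(90.0, 110.0)], 20.0),
            ([(100.0, 100.0), (90.0, 110.0)], 10.0),
        ],
    )
    def test_hand_computed_precision(self, pairs, expected_mean):
        mean, _ = duplicate_precision(pairs)
        assert mean == pytest.approx(expected_mean)

    def test_empty_list_raises(self):
        with pytest.raises(InputError):
            duplicate_precision([])


class TestRoundTrips:
    def test_campaign_csv_round_trip_is_bit_identical(self, tmp_path):
        samples = generate_campaign(GeneratorConfig(seed=2, n_samples=20))
        p = tmp_path / "campaign.csv"
        write_campaign(samples, p)
        back = read_campaign(p)
        assert [s.neph_pm for s in back] == [s.neph_pm for s in samples]
        assert [s.grav_pm for s in back] == [s.grav_pm for s in samples]
        assert [s.rh for s in back] == [s.rh for s in samples]
        assert [s.covariates["fuel_type"] for s in back] == [
            s.covariates["fuel_type"] for s in samples
        ]

    def test_instrument_log_round_trip(self, tmp_path):
        neph, rh = generate_timeseries(0.5, events=((5.0, 20.0),), seed=4)
        write_neph_log(neph, tmp_path / "n.csv")
        write_rh_log(rh, tmp_path / "r.csv")
        neph2 = read_neph_log(tmp_path / "n.csv", "TS001")
        rh2 = read_rh_log(tmp_path / "r.csv", "TS001")
        assert np.array_equal(neph2.pm, neph.pm)
        assert np.array_equal(rh2.rh, rh.rh)
        assert (neph2.timestamps == neph.timestamps).all()


class TestCoLocationSample:
    def test_invariants_enforced(self):
        with pytest.raises(InputError):
            CoLocationSample("x", neph_pm=-1, grav_pm=100, rh=0.5)
        with pytest.raises(InputError):
            CoLocationSample("x", neph_pm=100, grav_pm=0, rh=0.5)
        with pytest.raises(InputError):
            CoLocationSample("x", neph_pm=100, grav_pm=100, rh=1.0)
        # below-LOD samples may carry a zero gravimetric value
        s = CoLocationSample("x", neph_pm=100, grav_pm=0, rh=0.5, below_lod=True)
        assert s.below_lod


class TestFilterRecords:
    def test_read_filter_record_csv(self, tmp_path):
        from nephqc.sample_io import read_filter_records

        p = tmp_path / "filters.csv"
        p.write_text(
            "filter_id,pre_ug,post_ug,blank_ug,flow_lpm,duration_min\n"
            "F1,1000,1482,2,4,30\nF2,900,906,2,4,30\n"
        )
        filters = read_filter_records(p)
        assert len(filters) == 2
        conc, below = gravimetric_concentration(filters[0])
        assert conc == pytest.approx(4000.0)
        assert not below
        assert gravimetric_concentration(filters[1])[1]  # 4 µg net < 5 µg LOD
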