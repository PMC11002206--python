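"""Trace I/O and slope estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflux.errors import (
    InsufficientDataError,
    TraceFormatError,
    TraceValidationError,
)
from mitoflux.signals import (
    ChannelKind,
    EventLabel,
    SlopeMode,
    TimeSeriesTrace,
    estimate_slope,
    read_trace,
    write_trace,
)


def _trace(times, values, **kw):
    return TimeSeriesTrace(ChannelKind.OXYGEN_CONC, np.asarray(times),
                           np.asarray(values), **kw)


class TestReadTrace:
    def test_minimal_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value,event\n0,200,\n30,195,\n60,190,\n")
        tr = read_trace(p, ChannelKind.OXYGEN_CONC)
        assert len(tr.times) == 3
        assert tr.events == []
        np.testing.assert_allclose(tr.values, [200, 195, 190])

    def test_event_cell_becomes_injection_event(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value,event\n0,200,\n300,195,ADP\n600,190,\n")
        tr = read_trace(p, ChannelKind.OXYGEN_CONC)
        assert len(tr.events) == 1
        assert tr.events[0].time == 300
        assert tr.events[0].label == EventLabel.ADP

    def test_nonmonotonic_time_names_offending_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("time_s,value,event\n0,200,\n60,195,\n30,190,\n")
        with pytest.raises(TraceValidationError, match="row 3"):
            read_trace(p, ChannelKind.OXYGEN_CONC)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,v\n0,200\n30,195\n")
        with pytest.raises(TraceFormatError, match="time_s"):
            read_trace(p, ChannelKind.OXYGEN_CONC)

    def test_roundtrip_through_write_trace(self, tmp_path):
        tr = _trace([0, 10, 20, 30], [5, 4, 3, 2],
                    events=[__import__("mitoflux").InjectionEvent(10, "ADP")])
        p = tmp_path / "w.csv"
        write_trace(tr, p)
        back = read_trace(p, ChannelKind.OXYGEN_CONC)
        np.testing.assert_allclose(back.times, tr.times)
        np.testing.assert_allclose(back.values, tr.values)
        assert back.events[0].label == EventLabel.ADP


class TestTraceValidation:
    def test_too_short(self):
        with pytest.raises(TraceValidationError):
            _trace([0.0], [1.0])

    def test_nonfinite_values(self):
        with pytest.raises(TraceValidationError):
            _trace([0, 1, 2], [1.0, np.nan, 2.0])

    def test_event_outside_span(self):
        from mitoflux import InjectionEvent
        with pytest.raises(TraceValidationError, match="outside"):
            _trace([0, 1, 2], [1, 2, 3],
                   events=[InjectionEvent(99.0, EventLabel.ADP)])


class TestEstimateSlope:
    def test_flat_signal_slope_zero(self):
        tr = _trace(np.arange(0, 100, 2.0), np.ones(50))
        est = estimate_slope(tr)
        assert est.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovers_per_minute_slope(self):
        # v(t) = 5 - 0.1 t (t in seconds) -> -6 units/min
        t = np.arange(0, 121, 2.0)
        tr = _trace(t, 5 - 0.1 * t)
        est = estimate_slope(tr, window=(0, 120))
        assert est.slope == pytest.approx(-6.0, rel=1e-12)
        assert est.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_window_with_fewer_than_3_points(self):
        tr = _trace([0, 10, 20, 30], [1, 2, 3, 4])
        with pytest.raises(InsufficientDataError):
            estimate_slope(tr, window=(0, 10))

    def test_steepest_window_finds_fast_phase(self):
        # slope -1/min for 0-300 s, then -6/min for 300-600 s
        t = np.arange(0, 601, 2.0)
        v = np.where(t <= 300, 10 - t / 60, 10 - 300 / 60 - 6 * (t - 300) / 60)
        tr = _trace(t, v)
        est = estimate_slope(tr, mode=SlopeMode.STEEPEST_WINDOW,
                             steepest_length_s=120)
        assert 300 <= est.window[0] and est.window[1] <= 600
        assert est.slope == pytest.approx(-6.0, rel=1e-9)

    def test_steepest_beats_every_fixed_window(self):
        """Exhaustive check: no fixed window of equal length has a
        steeper slope than the steepest_window result."""
        rng = np.random.default_rng(3)
        t = np.arange(0, 200, 4.0)
        v = np.cumsum(rng.normal(0, 1, t.size))
        tr = _trace(t, v)
        best = estimate_slope(tr, mode=SlopeMode.STEEPEST_WINDOW,
                              steepest_length_s=40)
        for start in t:
            if start + 40 > t[-1]:
                break
            fixed = estimate_slope(tr, window=(start, start + 40))
            assert abs(best.slope) >= abs(fixed.slope) - 1e-9

    @given(slope=st.floats(-50, 50), intercept=st.floats(-100, 100),
           offset=st.floats(-1000, 1000))
    @settings(max_examples=50, deadline=None)
    def test_offset_invariance_and_exact_line(self, slope, intercept, offset):
        """OLS reproduces a generating line and ignores constant shifts."""
        t = np.linspace(0, 60, 31)
        v = intercept + slope * t / 60.0
        tr1 = _trace(t, v)
        tr2 = _trace(t, v + offset)
        e1, e2 = estimate_slope(tr1), estimate_slope(tr2)
        assert e1.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
        assert e2.slope == pytest.approx(e1.slope, rel=1e-9, abs=1e-9)
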