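"""Assay trace data model, CSV I/O and slope estimation.

A :class:`TimeSeriesTrace` holds one instrument channel (oxygen
concentration, Amplex-Red fluorescence, or absorbance) sampled over time,
together with the injection events (homogenate, ADP, substrate, ...) that
delimit the analysis windows.  All downstream quantification — oxygen
fluxes, H2O2 rates, enzyme activities — reduces to an ordinary
least-squares slope over a time window of one of these traces, so the
slope estimator lives here and is shared by every stage.

Units convention: input times are in seconds; every reported slope is in
channel units **per minute**, because the physiological rates of interest
(nmol O2/min, nmol H2O2/min, nmol substrate/min) are per-minute
quantities.  The seconds-to-minutes conversion happens in exactly one
place (:func:`estimate_slope`) to avoid 60-fold unit mistakes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, TraceFormatError, TraceValidationError

__all__ = [
    "ChannelKind",
    "EventLabel",
    "InjectionEvent",
    "TimeSeriesTrace",
    "SlopeEstimate",
    "SlopeMode",
    "TraceDialect",
    "read_trace",
    "write_trace",
    "estimate_slope",
]


class ChannelKind(str, Enum):
    """What the trace's value column measures."""

    OXYGEN_CONC = "oxygen_conc"  # nmol O2 / mL
    FLUORESCENCE = "fluorescence"  # arbitrary units
    ABSORBANCE = "absorbance"  # absorbance units


class EventLabel(str, Enum):
    """Controlled vocabulary for injection annotations."""

    HOMOGENATE = "homogenate"
    ADP = "ADP"
    SUBSTRATE = "substrate"
    INHIBITOR = "inhibitor"
    CALIBRANT = "calibrant"
    OTHER = "other"


class SlopeMode(str, Enum):
    FIXED_WINDOW = "fixed_window"
    STEEPEST_WINDOW = "steepest_window"


#: Default length of the scanning window for steepest-slope extraction, in
#: seconds.  Covers >= 10 samples at a typical 2 s sampling interval.
DEFAULT_STEEPEST_WINDOW_S = 30.0


@dataclass(frozen=True)
class InjectionEvent:
    """A titration into the chamber/cuvette at a known time."""

    time: float  # seconds
    label: EventLabel
    note: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise TraceValidationError(f"event time must be finite, got {self.time}")
        if not isinstance(self.label, EventLabel):
            object.__setattr__(self, "label", EventLabel(self.label))


@dataclass
class TimeSeriesTrace:
    """One assay channel over time with its injection events.

    Parameters
    ----------
    channel_kind
        Which physical quantity the values represent.
    times
        Sample times in seconds, strictly increasing, length >= 2.
    values
        Channel values, same length as ``times``, all finite.
    events
        Injection events; each must fall inside the trace's time span.
    metadata
        Free-form assay context (chamber volume in mL, pathlength in cm,
        tissue grams, temperature, ...).  Keys used by downstream stages:
        ``chamber_volume_ml``, ``assay_volume_ml``, ``pathlength_cm``,
        ``sample_volume_ul``, ``tissue_grams``.
    """

    channel_kind: ChannelKind
    times: np.ndarray
    values: np.ndarray
    events: list[InjectionEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_kind = ChannelKind(self.channel_kind)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise TraceValidationError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise TraceValidationError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "differ in length"
            )
        if len(self.times) < 2:
            raise TraceValidationError("a trace needs at least 2 samples")
        diffs = np.diff(self.times)
        if np.any(diffs <= 0):
            row = int(np.argmax(diffs <= 0)) + 1
            raise TraceValidationError(
                f"times must be strictly increasing; violation at row {row + 1} "
                f"(t={self.times[row]} after t={self.times[row - 1]})"
            )
        if not np.all(np.isfinite(self.values)):
            raise TraceValidationError("trace values must be finite")
        lo, hi = self.times[0], self.times[-1]
        for ev in self.events:
            if not (lo <= ev.time <= hi):
                raise TraceValidationError(
                    f"event {ev.label.value!r} at t={ev.time}s lies outside the "
                    f"trace span [{lo}, {hi}]"
                )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def events_labelled(self, label: EventLabel | str) -> list[InjectionEvent]:
        label = EventLabel(label)
        return [ev for ev in self.events if ev.label == label]

    def first_event(self, label: EventLabel | str) -> Optional[InjectionEvent]:
        evs = self.events_labelled(label)
        return evs[0] if evs else None


@dataclass(frozen=True)
class SlopeEstimate:
    """An OLS slope over a trace window, in channel units per minute."""

    slope: float  # channel units / min
    window: tuple[float, float]  # [t_start, t_end] seconds
    r_squared: float
    mode: SlopeMode
    n_points: int

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise TraceValidationError(
                f"window start {self.window[0]} must precede end {self.window[1]}"
            )


@dataclass(frozen=True)
class TraceDialect:
    """Column layout of a trace CSV export.

    The default matches the pipeline's own exports: comma-separated with a
    header row and columns ``time_s``, ``value``, ``event`` (event cells
    may be empty).  Instrument exports are adapted by overriding the
    column names — never by guessing.
    """

    delimiter: str = ","
    time_column: str = "time_s"
    value_column: str = "value"
    event_column: Optional[str] = "event"


DEFAULT_DIALECT = TraceDialect()


def read_trace(
    path: str | Path,
    channel_kind: ChannelKind | str,
    dialect: TraceDialect = DEFAULT_DIALECT,
    metadata: Optional[dict] = None,
) -> TimeSeriesTrace:
    """Read a trace CSV into a validated :class:`TimeSeriesTrace`.

    Rows whose event cell is non-empty become :class:`InjectionEvent`
    objects anchored at that row's time.  Unknown event labels map to
    ``EventLabel.OTHER`` with the original text kept in ``note``.

    Raises
    ------
    TraceFormatError
        If the file lacks the dialect's required columns.
    TraceValidationError
        If times are non-monotonic (the message names the first offending
        row) or values are non-finite.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=dialect.delimiter)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot read trace file {path}: {exc}") from exc

    for col in (dialect.time_column, dialect.value_column):
        if col not in df.columns:
            raise TraceFormatError(
                f"{path}: missing required column {col!r} "
                f"(found {list(df.columns)})"
            )

    events: list[InjectionEvent] = []
    if dialect.event_column is not None and dialect.event_column in df.columns:
        ev_col = df[dialect.event_column]
        for t, raw in zip(df[dialect.time_column], ev_col):
            if pd.isna(raw) or str(raw).strip() == "":
                continue
            text = str(raw).strip()
            try:
                label = EventLabel(text)
                note = ""
            except ValueError:
                label, note = EventLabel.OTHER, text
            events.append(InjectionEvent(time=float(t), label=label, note=note))

    return TimeSeriesTrace(
        channel_kind=ChannelKind(channel_kind),
        times=df[dialect.time_column].to_numpy(dtype=float),
        values=df[dialect.value_column].to_numpy(dtype=float),
        events=events,
        metadata=dict(metadata or {}),
    )


def write_trace(
    trace: TimeSeriesTrace,
    path: str | Path,
    dialect: TraceDialect = DEFAULT_DIALECT,
) -> None:
    """Write a trace in the CSV dialect consumed by :func:`read_trace`.

    Events that do not coincide with a sample time are attached to the
    nearest sample row.
    """
    event_cells = [""] * len(trace.times)
    for ev in trace.events:
        idx = int(np.argmin(np.abs(trace.times - ev.time)))
        event_cells[idx] = ev.note if ev.label == EventLabel.OTHER and ev.note else ev.label.value
    df = pd.DataFrame(
        {
            dialect.time_column: trace.times,
            dialect.value_column: trace.values,
            (dialect.event_column or "event"): event_cells,
        }
    )
    df.to_csv(path, sep=dialect.delimiter, index=False)


def _ols_slope_per_min(t_s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """OLS slope (units/min) and r^2 of v against time in seconds."""
    slope_per_s, _intercept = np.polyfit(t_s, v, 1)
    fitted = np.polyval((slope_per_s, _intercept), t_s)
    ss_res = float(np.sum((v - fitted) ** 2))
    ss_tot = float(np.sum((v - np.mean(v)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope_per_s) * 60.0, r2


def estimate_slope(
    trace: TimeSeriesTrace,
    window: Optional[Sequence[float]] = None,
    mode: SlopeMode | str = SlopeMode.FIXED_WINDOW,
    steepest_length_s: float = DEFAULT_STEEPEST_WINDOW_S,
) -> SlopeEstimate:
    """Estimate the trace slope in channel units per minute.

    ``fixed_window`` fits one OLS line over ``window`` (defaults to the
    full trace).  ``steepest_window`` scans every contiguous window of
    duration ``steepest_length_s`` (each starting at a sample time) and
    returns the one with maximum ``|slope|``; ties break to the earliest
    start, so results are deterministic.  The steepest mode serves assays
    where the fastest post-injection rate is the quantity of interest,
    e.g. NADH oxidation immediately after the NADH addition.

    Raises
    ------
    InsufficientDataError
        If fewer than 3 samples fall inside a candidate window.
    """
    mode = SlopeMode(mode)
    t, v = trace.times, trace.values

    if mode == SlopeMode.FIXED_WINDOW:
        if window is None:
            window = (float(t[0]), float(t[-1]))
        w0, w1 = float(window[0]), float(window[1])
        mask = (t >= w0) & (t <= w1)
        n = int(mask.sum())
        if n < 3:
            raise InsufficientDataError(
                f"window [{w0}, {w1}] contains {n} samples; need >= 3"
            )
        slope, r2 = _ols_slope_per_min(t[mask], v[mask])
        return SlopeEstimate(slope=slope, window=(w0, w1), r_squared=r2,
                             mode=mode, n_points=n)

    # steepest_window: restrict the scan to `window` if one is given
    if window is not None:
        w0, w1 = float(window[0]), float(window[1])
        scan_mask = (t >= w0) & (t <= w1)
        t_scan, v_scan = t[scan_mask], v[scan_mask]
    else:
        t_scan, v_scan = t, v
    if len(t_scan) < 3:
        raise InsufficientDataError("fewer than 3 samples available for scan")

    best: Optional[SlopeEstimate] = None
    for i in range(len(t_scan)):
        w0 = float(t_scan[i])
        w1 = w0 + float(steepest_length_s)
        if w1 > float(t_scan[-1]) + 1e-12:
            break
        mask = (t_scan >= w0) & (t_scan <= w1 + 1e-12)
        n = int(mask.sum())
        if n < 3:
            continue
        slope, r2 = _ols_slope_per_min(t_scan[mask], v_scan[mask])
        cand = SlopeEstimate(slope=slope, window=(w0, w1), r_squared=r2,
                             mode=mode, n_points=n)
        if best is None or abs(cand.slope) > abs(best.slope) + 1e-15:
            best = cand
    if best is None:
        raise InsufficientDataError(
            f"no window of length {steepest_length_s}s holds >= 3 samples"
        )
    return best
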