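"""Oxygen fluxes, respiration-state segmentation and the RCR.

High-resolution respirometry records chamber oxygen concentration
(nmol O2/mL) over time.  Tissue homogenate injected into the closed
chamber starts state-2 respiration (substrate present, no ADP); adding
ADP starts state-3 (ATP-synthesis-coupled) respiration.  The negative of
the concentration slope times the chamber volume gives the whole-chamber
oxygen consumption flux J_O2 in nmol O2/min, and the respiratory control
ratio RCR = J_O2(state 3) / J_O2(state 2) indexes how well respiration is
coupled to phosphorylation: well-coupled colon mitochondria sit around 4,
uncoupled preparations approach 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import RcrUndefinedError, SegmentationError, TraceValidationError
from .signals import (
    ChannelKind,
    EventLabel,
    SlopeMode,
    TimeSeriesTrace,
    estimate_slope,
)

__all__ = [
    "OxygenFlux",
    "RespirationStates",
    "oxygen_flux",
    "segment_states",
    "rcr",
    "DEFAULT_SETTLE_TIME_S",
    "DEFAULT_STATE_WINDOW_S",
]

#: Seconds to wait after an injection before the measurement window
#: opens; injections transiently perturb the oxygen signal.
DEFAULT_SETTLE_TIME_S = 60.0

#: Length of each state's measurement window, seconds.
DEFAULT_STATE_WINDOW_S = 120.0


@dataclass(frozen=True)
class OxygenFlux:
    """Whole-chamber oxygen consumption, positive for consumption.

    ``per_gram`` (nmol O2/min/g tissue) is present only when the trace
    metadata carries enough information to normalise to tissue mass.
    """

    j_o2: float  # nmol O2/min, chamber total
    source_window: tuple[float, float]
    per_gram: Optional[float] = None
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.j_o2):
            raise TraceValidationError(f"oxygen flux must be finite, got {self.j_o2}")


@dataclass(frozen=True)
class RespirationStates:
    """State-2 and state-3 fluxes from one assay, with their ratio."""

    state2: OxygenFlux
    state3: OxygenFlux
    rcr: float
    qc_flags: tuple[str, ...] = ()


def oxygen_flux(
    slope: float,
    chamber_volume_ml: float,
    source_window: tuple[float, float] = (0.0, 0.0),
    tissue_grams: Optional[float] = None,
) -> OxygenFlux:
    """Convert a concentration slope (nmol/mL/min) into a chamber flux.

    J_O2 = -slope x chamber_volume, so a falling oxygen concentration
    yields a positive consumption flux.  A negative flux (oxygen rising)
    is physically suspect; it is returned unchanged but carries the QC
    flag ``"negative_flux"``.
    """
    if not math.isfinite(slope):
        raise TraceValidationError(f"slope must be finite, got {slope}")
    if chamber_volume_ml <= 0:
        raise TraceValidationError(
            f"chamber volume must be positive, got {chamber_volume_ml}"
        )
    j = -slope * chamber_volume_ml
    flags: tuple[str, ...] = ("negative_flux",) if j < 0 else ()
    per_gram = None
    if tissue_grams is not None and tissue_grams > 0:
        per_gram = j / tissue_grams
    window = source_window if source_window[0] < source_window[1] else (0.0, 1e-9)
    return OxygenFlux(j_o2=j, source_window=(float(window[0]), float(window[1])),
                      per_gram=per_gram, qc_flags=flags)


def rcr(state3: OxygenFlux, state2: OxygenFlux) -> float:
    """Respiratory control ratio: state-3 flux over state-2 flux.

    Raises :class:`RcrUndefinedError` when state-2 flux is non-positive.
    """
    if state2.j_o2 <= 0:
        raise RcrUndefinedError(
            f"RCR undefined: state-2 flux {state2.j_o2} nmol O2/min is not positive"
        )
    return state3.j_o2 / state2.j_o2


def _tissue_grams_from_metadata(metadata: dict) -> Optional[float]:
    """Tissue mass in the chamber, from homogenate aliquot metadata.

    Requires ``sample_volume_ul`` (aliquot injected) and
    ``tissue_g_per_ml_homogenate``; alternatively an explicit
    ``tissue_grams``.
    """
    if "tissue_grams" in metadata:
        g = float(metadata["tissue_grams"])
        return g if g > 0 else None
    if "sample_volume_ul" in metadata and "tissue_g_per_ml_homogenate" in metadata:
        ml = float(metadata["sample_volume_ul"]) / 1000.0
        g = ml * float(metadata["tissue_g_per_ml_homogenate"])
        return g if g > 0 else None
    return None


def segment_states(
    trace: TimeSeriesTrace,
    settle_time_s: float = DEFAULT_SETTLE_TIME_S,
    window_length_s: float = DEFAULT_STATE_WINDOW_S,
    chamber_volume_ml: Optional[float] = None,
) -> RespirationStates:
    """Extract state-2 and state-3 fluxes and the RCR from one trace.

    The state-2 window is the ``window_length_s`` stretch immediately
    preceding the ADP event (truncated so it starts no earlier than
    ``settle_time_s`` after the homogenate injection); the state-3 window
    starts ``settle_time_s`` after the ADP event.  Both slopes are
    converted to fluxes with :func:`oxygen_flux` using the chamber volume
    from the argument or, failing that, trace metadata
    ``chamber_volume_ml``.

    Raises
    ------
    SegmentationError
        If the homogenate or ADP event is missing, or the windows do not
        fit inside the trace.
    RcrUndefinedError
        If the recovered state-2 flux is non-positive.
    """
    if trace.channel_kind != ChannelKind.OXYGEN_CONC:
        raise SegmentationError(
            f"respiration segmentation needs an oxygen trace, got "
            f"{trace.channel_kind.value}"
        )
    hom = trace.first_event(EventLabel.HOMOGENATE)
    if hom is None:
        raise SegmentationError("missing required injection event: homogenate")
    adp = trace.first_event(EventLabel.ADP)
    if adp is None:
        raise SegmentationError("missing required injection event: ADP")
    if adp.time <= hom.time:
        raise SegmentationError(
            f"ADP event (t={adp.time}s) must follow homogenate (t={hom.time}s)"
        )

    if chamber_volume_ml is None:
        chamber_volume_ml = trace.metadata.get("chamber_volume_ml")
    if chamber_volume_ml is None:
        raise SegmentationError(
            "chamber volume not given and absent from trace metadata "
            "('chamber_volume_ml')"
        )

    s2_end = adp.time
    s2_start = max(adp.time - window_length_s, hom.time + settle_time_s)
    if s2_start >= s2_end:
        raise SegmentationError(
            f"no state-2 window fits between homogenate+settle "
            f"(t={hom.time + settle_time_s}s) and ADP (t={adp.time}s)"
        )
    s3_start = adp.time + settle_time_s
    s3_end = min(s3_start + window_length_s, trace.span[1])
    if s3_end <= s3_start:
        raise SegmentationError(
            f"trace ends at {trace.span[1]}s, before the state-3 window "
            f"opening at {s3_start}s"
        )

    tissue_g = _tissue_grams_from_metadata(trace.metadata)
    s2_slope = estimate_slope(trace, window=(s2_start, s2_end),
                              mode=SlopeMode.FIXED_WINDOW)
    s3_slope = estimate_slope(trace, window=(s3_start, s3_end),
                              mode=SlopeMode.FIXED_WINDOW)
    state2 = oxygen_flux(s2_slope.slope, chamber_volume_ml,
                         source_window=s2_slope.window, tissue_grams=tissue_g)
    state3 = oxygen_flux(s3_slope.slope, chamber_volume_ml,
                         source_window=s3_slope.window, tissue_grams=tissue_g)
    ratio = rcr(state3, state2)
    flags = tuple(f"state2:{f}" for f in state2.qc_flags) + tuple(
        f"state3:{f}" for f in state3.qc_flags
    )
    return RespirationStates(state2=state2, state3=state3, rcr=ratio,
                             qc_flags=flags)
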