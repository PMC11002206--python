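"""Extinction-coefficient enzyme kinetics and mitochondrial-content
normalization.

Spectrophotometric ETC-complex assays report an absorbance slope; the
Beer–Lambert law (A = epsilon * c * l) converts it into a substrate
turnover rate:

    rate [mM/min]   = |dA/dt| / (epsilon * pathlength)
    rate [nmol/min] = rate [mM/min] * assay_volume_mL * 1000

Complex I follows NADH oxidation at 340 nm (epsilon 6.22 mM^-1 cm^-1),
complex II DCPIP reduction loss at 600 nm (19.1), complex III cytochrome
c reduction at 550 nm (18.7), and citrate synthase the DTNB thiolate at
412 nm (13.6).  Complex IV is measured polarographically as an oxygen
flux.  Non-enzymatic background rates (inhibitor-present traces) are
subtracted from total rates; negative nets are flagged, never clipped.

Rates are made comparable across enzymes by converting to electron flux
(nmol e-/min) with the carrier electron equivalences {NADH 2, DCPIP 2,
cytochrome c 1, O2 4}, and comparable across animals by normalizing
per-gram electron fluxes to citrate synthase activity, a marker of
mitochondrial content; the minutes cancel, leaving nmol e-/nmol citrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import (
    AssayConfigError,
    NormalizationError,
    SegmentationError,
    TraceValidationError,
)
from .respirometry import oxygen_flux
from .signals import (
    ChannelKind,
    EventLabel,
    SlopeMode,
    TimeSeriesTrace,
    estimate_slope,
)

__all__ = [
    "Enzyme",
    "Carrier",
    "Direction",
    "AssayConfig",
    "EnzymeActivity",
    "CsActivity",
    "NormalizedActivity",
    "ELECTRONS_PER_CARRIER",
    "DEFAULT_ASSAY_CONFIGS",
    "beer_lambert_rate",
    "subtract_background",
    "citrate_synthase_activity",
    "complex_iv_activity",
    "to_electron_flux",
    "normalize_to_cs",
]


class Enzyme(str, Enum):
    COMPLEX_I = "complex_I"
    COMPLEX_II = "complex_II"
    COMPLEX_III = "complex_III"
    COMPLEX_IV = "complex_IV"
    CITRATE_SYNTHASE = "citrate_synthase"


class Carrier(str, Enum):
    NADH = "NADH"
    DCPIP = "DCPIP"
    CYTOCHROME_C = "cytochrome_c"
    O2 = "O2"
    DTNB_THIOLATE = "DTNB_thiolate"


class Direction(str, Enum):
    DECREASE = "decrease"  # absorbance falls as the reaction proceeds
    INCREASE = "increase"


#: Electron equivalences per carrier molecule: NADH and DCPIP are
#: two-electron carriers, cytochrome c carries one, O2 accepts four on
#: full reduction to water.  DTNB thiolate (citrate synthase readout)
#: tracks citrate formation 1:1 and has no electron-flux meaning.
ELECTRONS_PER_CARRIER: dict[Carrier, float] = {
    Carrier.NADH: 2.0,
    Carrier.DCPIP: 2.0,
    Carrier.CYTOCHROME_C: 1.0,
    Carrier.O2: 4.0,
}


@dataclass(frozen=True)
class AssayConfig:
    """Optical and volumetric parameters of one enzyme assay."""

    enzyme: Enzyme
    epsilon_mm_cm: float  # extinction coefficient, mM^-1 cm^-1
    wavelength_nm: float
    pathlength_cm: float
    assay_volume_ml: float
    carrier: Carrier
    direction: Direction
    sample_volume_ul: Optional[float] = None

    def __post_init__(self) -> None:
        if self.epsilon_mm_cm <= 0:
            raise AssayConfigError(f"epsilon must be > 0, got {self.epsilon_mm_cm}")
        if self.pathlength_cm <= 0:
            raise AssayConfigError(f"pathlength must be > 0, got {self.pathlength_cm}")
        if self.assay_volume_ml <= 0:
            raise AssayConfigError(
                f"assay volume must be > 0, got {self.assay_volume_ml}"
            )


#: Published assay parameters.  The citrate synthase assay runs on a
#: plate reader whose effective pathlength depends on the well fill
#: volume; 1 cm and 0.25 mL are placeholders that real deployments must
#: override.
DEFAULT_ASSAY_CONFIGS: dict[Enzyme, AssayConfig] = {
    Enzyme.COMPLEX_I: AssayConfig(
        enzyme=Enzyme.COMPLEX_I, epsilon_mm_cm=6.22, wavelength_nm=340,
        pathlength_cm=1.0, assay_volume_ml=2.0, carrier=Carrier.NADH,
        direction=Direction.DECREASE, sample_volume_ul=100,
    ),
    Enzyme.COMPLEX_II: AssayConfig(
        enzyme=Enzyme.COMPLEX_II, epsilon_mm_cm=19.1, wavelength_nm=600,
        pathlength_cm=1.0, assay_volume_ml=0.2, carrier=Carrier.DCPIP,
        direction=Direction.DECREASE, sample_volume_ul=20,
    ),
    Enzyme.COMPLEX_III: AssayConfig(
        enzyme=Enzyme.COMPLEX_III, epsilon_mm_cm=18.7, wavelength_nm=550,
        pathlength_cm=1.0, assay_volume_ml=0.2, carrier=Carrier.CYTOCHROME_C,
        direction=Direction.INCREASE, sample_volume_ul=20,
    ),
    Enzyme.CITRATE_SYNTHASE: AssayConfig(
        enzyme=Enzyme.CITRATE_SYNTHASE, epsilon_mm_cm=13.6, wavelength_nm=412,
        pathlength_cm=1.0, assay_volume_ml=0.25, carrier=Carrier.DTNB_THIOLATE,
        direction=Direction.INCREASE, sample_volume_ul=200,
    ),
}


@dataclass(frozen=True)
class EnzymeActivity:
    """One complex's activity in substrate, electron-flux and
    normalized units."""

    enzyme: Enzyme
    rate_substrate: float  # nmol carrier/min
    electron_flux: float  # nmol e-/min
    rate_per_gram: Optional[float] = None  # nmol carrier/min/g
    electron_flux_per_gram: Optional[float] = None  # nmol e-/min/g
    background_subtracted: bool = False
    qc_flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CsActivity:
    """Citrate synthase rate per gram of tissue, the mitochondrial
    content marker."""

    rate: float  # nmol citrate/min/g tissue
    qc_flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not math.isfinite(self.rate):
            raise TraceValidationError("citrate synthase rate must be finite")
        if self.rate < 0 and "negative_rate" not in self.qc_flags:
            object.__setattr__(self, "qc_flags", self.qc_flags + ("negative_rate",))


@dataclass(frozen=True)
class NormalizedActivity:
    """Electron flux per unit citrate synthase: nmol e-/nmol citrate."""

    value: float
    label: str  # enzyme or respiration-condition label


def beer_lambert_rate(slope_au_per_min: float, config: AssayConfig) -> tuple[float, tuple[str, ...]]:
    """Absorbance slope -> substrate turnover rate in nmol carrier/min.

    Activity is reported positive when the slope runs in the assay's
    expected direction; a slope opposite to ``config.direction`` (beyond
    1e-9 AU/min) yields the QC flag ``"direction_mismatch"`` suggesting
    an inverted or mislabelled trace.

    Returns ``(rate_nmol_per_min, qc_flags)``.
    """
    if not math.isfinite(slope_au_per_min):
        raise TraceValidationError("absorbance slope must be finite")
    conc_rate_mm_per_min = abs(slope_au_per_min) / (
        config.epsilon_mm_cm * config.pathlength_cm
    )
    # mM/min * mL = umol/min / 1000 ... (mmol/L)*(mL) = umol; x1000 -> nmol
    rate = conc_rate_mm_per_min * config.assay_volume_ml * 1000.0
    expected_sign = -1.0 if config.direction == Direction.DECREASE else 1.0
    flags: tuple[str, ...] = ()
    if slope_au_per_min * expected_sign < -1e-9:
        flags = ("direction_mismatch",)
    return rate, flags


def subtract_background(
    total: float,
    background: float,
    enzyme: Optional[Enzyme] = None,
    background_enzyme: Optional[Enzyme] = None,
) -> tuple[float, tuple[str, ...]]:
    """Net enzymatic rate: total minus the inhibited non-enzymatic
    background, both in nmol/min from the same assay configuration.

    A negative net (background exceeding total) is returned as-is with
    the QC flag ``"negative_net_rate"`` — never clipped to zero, so the
    over-subtraction remains visible downstream.
    """
    if enzyme is not None and background_enzyme is not None and enzyme != background_enzyme:
        raise AssayConfigError(
            f"background trace is for {background_enzyme.value}, not {enzyme.value}"
        )
    net = total - background
    flags: tuple[str, ...] = ("negative_net_rate",) if net < 0 else ()
    return net, flags


def to_electron_flux(rate_nmol_per_min: float, carrier: Carrier | str) -> float:
    """Substrate rate -> electron flux via the carrier equivalence table."""
    carrier = Carrier(carrier)
    if carrier not in ELECTRONS_PER_CARRIER:
        raise AssayConfigError(
            f"no electron equivalence defined for carrier {carrier.value!r}"
        )
    return rate_nmol_per_min * ELECTRONS_PER_CARRIER[carrier]


def citrate_synthase_activity(
    trace: TimeSeriesTrace,
    config: AssayConfig,
    tissue_grams_in_aliquot: float,
    background_rate: float = 0.0,
) -> CsActivity:
    """Citrate synthase rate per gram of tissue from a DTNB trace.

    The 412 nm absorbance rises as CoASH reacts with DTNB; the
    Beer–Lambert rate divided by the grams of tissue in the assay
    aliquot gives nmol citrate/min/g.
    """
    if config.enzyme != Enzyme.CITRATE_SYNTHASE:
        raise AssayConfigError(
            f"expected a citrate_synthase config, got {config.enzyme.value}"
        )
    if tissue_grams_in_aliquot <= 0:
        raise TraceValidationError(
            f"tissue mass must be > 0 g, got {tissue_grams_in_aliquot}"
        )
    slope = estimate_slope(trace, mode=SlopeMode.FIXED_WINDOW)
    rate, flags = beer_lambert_rate(slope.slope, config)
    net, sub_flags = subtract_background(rate, background_rate)
    return CsActivity(rate=net / tissue_grams_in_aliquot, qc_flags=flags + sub_flags)


def complex_iv_activity(
    trace: TimeSeriesTrace,
    chamber_volume_ml: Optional[float] = None,
    settle_time_s: float = 60.0,
    tissue_grams: Optional[float] = None,
) -> EnzymeActivity:
    """Complex IV activity as post-injection oxygen consumption.

    Cytochrome c oxidase is assayed polarographically with
    ascorbate/TMPD keeping cytochrome c reduced; activity is the oxygen
    flux after the homogenate injection, and the electron flux is four
    electrons per O2.
    """
    if trace.channel_kind != ChannelKind.OXYGEN_CONC:
        raise SegmentationError("complex IV assay needs an oxygen trace")
    hom = trace.first_event(EventLabel.HOMOGENATE)
    if hom is None:
        raise SegmentationError("missing required injection event: homogenate")
    if chamber_volume_ml is None:
        chamber_volume_ml = trace.metadata.get("chamber_volume_ml")
    if chamber_volume_ml is None:
        raise SegmentationError(
            "chamber volume not given and absent from trace metadata"
        )
    w0 = hom.time + settle_time_s
    w1 = trace.span[1]
    slope = estimate_slope(trace, window=(w0, w1), mode=SlopeMode.FIXED_WINDOW)
    flux = oxygen_flux(slope.slope, chamber_volume_ml,
                       source_window=slope.window, tissue_grams=tissue_grams)
    eflux = to_electron_flux(flux.j_o2, Carrier.O2)
    return EnzymeActivity(
        enzyme=Enzyme.COMPLEX_IV,
        rate_substrate=flux.j_o2,
        electron_flux=eflux,
        rate_per_gram=flux.per_gram,
        electron_flux_per_gram=(
            to_electron_flux(flux.per_gram, Carrier.O2)
            if flux.per_gram is not None else None
        ),
        background_subtracted=False,
        qc_flags=flux.qc_flags,
    )


def spectrophotometric_activity(
    trace: TimeSeriesTrace,
    config: AssayConfig,
    background_trace: Optional[TimeSeriesTrace] = None,
    tissue_grams: Optional[float] = None,
    slope_mode: SlopeMode | str = SlopeMode.FIXED_WINDOW,
    steepest_length_s: float = 30.0,
) -> EnzymeActivity:
    """Full absorbance-trace workflow for complexes I–III.

    Estimates the slope (steepest-window mode suits the complex I assay,
    whose fastest rate follows the NADH addition), converts via
    Beer–Lambert, subtracts the inhibited background trace when given
    (otherwise background 0 with a QC note), and attaches electron-flux
    and per-gram values.
    """
    slope = estimate_slope(trace, mode=slope_mode,
                           steepest_length_s=steepest_length_s)
    total, flags = beer_lambert_rate(slope.slope, config)
    if background_trace is not None:
        bg_slope = estimate_slope(background_trace, mode=SlopeMode.FIXED_WINDOW)
        bg_rate, bg_flags = beer_lambert_rate(bg_slope.slope, config)
        flags += bg_flags
    else:
        bg_rate = 0.0
        flags += ("no_background_trace",)
    net, sub_flags = subtract_background(total, bg_rate)
    flags += sub_flags
    eflux = to_electron_flux(net, config.carrier)
    per_gram = net / tissue_grams if tissue_grams and tissue_grams > 0 else None
    return EnzymeActivity(
        enzyme=config.enzyme,
        rate_substrate=net,
        electron_flux=eflux,
        rate_per_gram=per_gram,
        electron_flux_per_gram=(eflux / tissue_grams
                                if tissue_grams and tissue_grams > 0 else None),
        background_subtracted=background_trace is not None,
        qc_flags=flags,
    )


def normalize_to_cs(
    electron_flux_per_gram: float, cs: CsActivity, label: str = ""
) -> NormalizedActivity:
    """Normalize a per-gram electron flux to mitochondrial content.

    Both quantities are per-minute and per-gram, so those units cancel
    and the result is nmol e- per nmol citrate.  Undefined for
    non-positive citrate synthase rates.
    """
    if cs.rate <= 0:
        raise NormalizationError(
            f"citrate synthase rate {cs.rate} <= 0; content normalization undefined"
        )
    return NormalizedActivity(value=electron_flux_per_gram / cs.rate, label=label)
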