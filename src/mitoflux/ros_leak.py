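"""Amplex-Red H2O2 calibration, superoxide stoichiometry and percent
electron leak.

The Amplex Red assay reports mitochondrial H2O2 production as a
fluorescence rate; a linear calibration against known H2O2 additions
converts AU/min into nmol H2O2/min.  With superoxide dismutase present,
two superoxide radicals dismutate to one H2O2, so the superoxide
production rate is exactly twice the measured H2O2 rate.  Each
superoxide carries one leaked electron, while each O2 reduced at complex
IV accepts four, giving the percent electron leak

    leak % = 100 * (2 * J_H2O2) / (4 * J_O2)

the fraction of electron flow diverted to superoxide instead of reaching
water.  Expressing mtROS this way makes rates comparable across animals
with different respiration rates.

The denominator convention — electrons delivered to O2, versus total
electrons including the leaked ones — is configurable; at physiological
leak (< 2 %) the two differ by under 0.05 percentage points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import CalibrationError, TraceValidationError, UndefinedLeakError

__all__ = [
    "H2o2Calibration",
    "RosResult",
    "LeakDenominator",
    "fit_calibration",
    "h2o2_rate",
    "so_rate",
    "percent_electron_leak",
    "ros_result",
]

#: Superoxide radicals produced per H2O2 detected (SOD dismutation).
SO_PER_H2O2 = 2.0

#: Electrons accepted per O2 fully reduced to water at complex IV.
ELECTRONS_PER_O2 = 4.0

#: Leaked electrons per superoxide radical.
ELECTRONS_PER_SO = 1.0


class LeakDenominator(str, Enum):
    """Which electron pool the leak percentage is taken against."""

    O2_ONLY = "o2_only"  # electrons that reached O2 (default)
    TOTAL = "total"  # O2 electrons plus the leaked electrons


@dataclass(frozen=True)
class H2o2Calibration:
    """Linear fluorescence response to H2O2 concentration.

    ``slope`` is AU per uM H2O2 and must be positive for a usable
    calibration; the intercept absorbs blank fluorescence and is not used
    in rate conversion.
    """

    slope: float  # AU / uM
    intercept: float  # AU
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise CalibrationError("calibration needs >= 2 points")
        if not math.isfinite(self.slope) or self.slope <= 0:
            raise CalibrationError(
                f"calibration slope must be positive, got {self.slope}"
            )


@dataclass(frozen=True)
class RosResult:
    """Calibrated ROS rates paired with the simultaneous oxygen flux."""

    j_h2o2: float  # nmol H2O2 / min
    j_so: float  # nmol superoxide / min (== 2 * j_h2o2)
    percent_leak: float  # %
    paired_j_o2: float  # nmol O2 / min


def fit_calibration(
    concentrations_um: Sequence[float], responses_au: Sequence[float]
) -> H2o2Calibration:
    """OLS line of fluorescence response against H2O2 concentration.

    Fitted with an intercept, since blanks fluoresce.  Raises
    :class:`CalibrationError` for fewer than 2 distinct concentrations or
    a non-positive fitted slope.
    """
    conc = np.asarray(concentrations_um, dtype=float)
    resp = np.asarray(responses_au, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise CalibrationError("concentrations and responses must be equal-length 1-D")
    if len(np.unique(conc)) < 2:
        raise CalibrationError(
            "calibration needs >= 2 distinct H2O2 concentrations"
        )
    slope, intercept = np.polyfit(conc, resp, 1)
    fitted = slope * conc + intercept
    ss_res = float(np.sum((resp - fitted) ** 2))
    ss_tot = float(np.sum((resp - resp.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    if slope <= 0:
        raise CalibrationError(
            f"fitted calibration slope {slope:.4g} AU/uM is not positive"
        )
    return H2o2Calibration(slope=float(slope), intercept=float(intercept),
                           r_squared=r2, n_points=len(conc))


def h2o2_rate(
    fluor_slope_au_per_min: float,
    calibration: H2o2Calibration,
    chamber_volume_ml: float,
) -> float:
    """Convert a fluorescence slope into an H2O2 production rate.

    AU/min divided by the calibration slope (AU/uM) gives uM/min; since
    1 uM = 1 nmol/mL, multiplying by the chamber volume in mL yields
    nmol H2O2/min.
    """
    if not math.isfinite(fluor_slope_au_per_min):
        raise TraceValidationError("fluorescence slope must be finite")
    if chamber_volume_ml <= 0:
        raise TraceValidationError(
            f"chamber volume must be positive, got {chamber_volume_ml}"
        )
    return (fluor_slope_au_per_min / calibration.slope) * chamber_volume_ml


def so_rate(j_h2o2: float) -> float:
    """Superoxide production rate: exactly twice the H2O2 rate."""
    if j_h2o2 < 0:
        raise TraceValidationError(f"H2O2 rate must be >= 0, got {j_h2o2}")
    return SO_PER_H2O2 * j_h2o2


def percent_electron_leak(
    j_h2o2: float,
    j_o2: float,
    denominator: LeakDenominator | str = LeakDenominator.O2_ONLY,
) -> float:
    """Percent of electron flow shunted to superoxide.

    Leaked electrons/min = 2 * J_H2O2 (one electron per superoxide);
    electrons reaching O2/min = 4 * J_O2.  The default denominator is the
    O2-bound electron flow; ``LeakDenominator.TOTAL`` adds the leaked
    electrons to the denominator.
    """
    if j_h2o2 < 0:
        raise TraceValidationError(f"H2O2 rate must be >= 0, got {j_h2o2}")
    if j_o2 <= 0:
        raise UndefinedLeakError(
            f"percent electron leak undefined for oxygen flux {j_o2} <= 0"
        )
    leaked = ELECTRONS_PER_SO * SO_PER_H2O2 * j_h2o2
    to_o2 = ELECTRONS_PER_O2 * j_o2
    denominator = LeakDenominator(denominator)
    denom = to_o2 + leaked if denominator == LeakDenominator.TOTAL else to_o2
    return 100.0 * leaked / denom


def ros_result(
    j_h2o2: float,
    j_o2: float,
    denominator: LeakDenominator | str = LeakDenominator.O2_ONLY,
) -> RosResult:
    """Bundle the calibrated H2O2 rate with its derived quantities."""
    return RosResult(
        j_h2o2=j_h2o2,
        j_so=so_rate(j_h2o2),
        percent_leak=percent_electron_leak(j_h2o2, j_o2, denominator),
        paired_j_o2=j_o2,
    )
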