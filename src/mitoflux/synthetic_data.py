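"""Synthetic assay traces, weight trajectories, and whole cohorts.

The generator forward-models what the analysis inverts, so zero-noise
roundtrips are exact and every pipeline stage can be exercised without
animal data:

* respirometry traces — piecewise-linear oxygen concentration whose
  segment slopes are implied by target state-2/state-3 fluxes and the
  chamber volume, with homogenate and ADP injection events;
* fluorescence traces — resorufin signal rising at the rate implied by a
  target H2O2 production rate and a linear calibration;
* absorbance traces — Beer–Lambert kinetics from a target enzyme
  activity plus a configurable non-enzymatic background rate;
* daily body-weight trajectories — disease curves dipping to a
  sex-specific nadir (8 % loss in males, 11 % in females) at days 2–3
  and recovering by day 7, against upward-drifting controls;
* cohorts — per-animal endpoint tables whose group means encode the
  study's sex x treatment effect structure (see ``DEFAULT_EFFECTS``)
  under mean-one lognormal between-animal noise.

Noise models: additive Gaussian on trace signals; multiplicative
lognormal on endpoints, because physiological endpoint values are
positive.  All randomness flows from an explicit integer seed, so the
same spec and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
import numpy as np
import pandas as pd

from .errors import SpecError
from .signals import ChannelKind, EventLabel, InjectionEvent, TimeSeriesTrace

__all__ = [
    "TraceKind",
    "TraceSpec",
    "CohortSpec",
    "DEFAULT_EFFECTS",
    "BASELINE_ENDPOINTS",
    "make_trace",
    "make_weight_trajectory",
    "make_cohort",
    "make_stool_observations",
]


class TraceKind(str, Enum):
    RESPIROMETRY = "respirometry"
    FLUORESCENCE = "fluorescence"
    ABSORBANCE = "absorbance"


@dataclass(frozen=True)
class TraceSpec:
    """Target parameters for one synthetic trace.

    Only the fields relevant to ``kind`` are read:

    respirometry
        ``state2_flux`` / ``state3_flux`` (nmol O2/min), ``volume_ml``,
        ``o2_start`` (nmol/mL), event schedule with homogenate then ADP.
    fluorescence
        ``j_h2o2`` (nmol/min), ``calibration_slope`` (AU/uM),
        ``volume_ml``, ``baseline_au``; production starts at the first
        event, or at t=0 when no events are given.
    absorbance
        ``activity`` and ``background_rate`` (nmol/min), ``epsilon``
        (mM^-1 cm^-1), ``pathlength_cm``, ``volume_ml``, ``direction``
        (+1 rising, -1 falling); kinetics start at the first event or
        t=0.
    """

    kind: TraceKind
    volume_ml: float = 2.0
    duration_s: float = 600.0
    sampling_interval_s: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0
    events: tuple[tuple[float, str], ...] = ()
    # respirometry
    state2_flux: float = 25.0
    state3_flux: float = 100.0
    o2_start: float = 400.0  # nmol/mL at t=0 (hyperoxygenated chamber)
    # fluorescence
    j_h2o2: float = 1.0
    calibration_slope: float = 10.0  # AU/uM
    baseline_au: float = 100.0
    # absorbance
    activity: float = 100.0
    background_rate: float = 0.0
    epsilon: float = 6.22
    pathlength_cm: float = 1.0
    direction: int = -1
    absorbance_start: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", TraceKind(self.kind))
        if self.noise_sd < 0:
            raise SpecError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.volume_ml <= 0:
            raise SpecError(f"volume must be > 0 mL, got {self.volume_ml}")
        if self.sampling_interval_s <= 0 or self.duration_s <= 0:
            raise SpecError("duration and sampling interval must be positive")
        times = [t for t, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SpecError("event schedule times must be strictly increasing")


#: Default injection schedule for respirometry traces: homogenate at
#: 60 s opens state 2, ADP at 360 s opens state 3.
RESPIROMETRY_EVENTS: tuple[tuple[float, str], ...] = (
    (60.0, "homogenate"),
    (360.0, "ADP"),
)


def _segment_slopes_per_min(spec: TraceSpec) -> list[tuple[float, float]]:
    """(start_time_s, latent slope in units/min) for each segment."""
    if spec.kind == TraceKind.RESPIROMETRY:
        events = spec.events or RESPIROMETRY_EVENTS
        hom = next((t for t, lab in events if lab == "homogenate"), None)
        adp = next((t for t, lab in events if lab == "ADP"), None)
        if hom is None or adp is None:
            raise SpecError(
                "respirometry spec needs homogenate and ADP events"
            )
        return [
            (0.0, 0.0),
            (hom, -spec.state2_flux / spec.volume_ml),
            (adp, -spec.state3_flux / spec.volume_ml),
        ]
    start = spec.events[0][0] if spec.events else 0.0
    if spec.kind == TraceKind.FLUORESCENCE:
        # uM/min of H2O2 accumulating in the chamber, times AU/uM
        au_per_min = spec.calibration_slope * spec.j_h2o2 / spec.volume_ml
        return [(0.0, 0.0), (start, au_per_min)] if start > 0 else [(0.0, au_per_min)]
    # absorbance: Beer-Lambert forward model
    total = spec.activity + spec.background_rate
    mm_per_min = total / (spec.volume_ml * 1000.0)
    au_per_min = spec.direction * mm_per_min * spec.epsilon * spec.pathlength_cm
    return [(0.0, 0.0), (start, au_per_min)] if start > 0 else [(0.0, au_per_min)]


def make_trace(spec: TraceSpec) -> TimeSeriesTrace:
    """Generate a synthetic trace: piecewise-linear latent signal plus
    i.i.d. Gaussian noise, deterministic for a given seed.

    Raises :class:`SpecError` when respirometry parameters would drive
    the chamber oxygen concentration negative before the trace ends.
    """
    times = np.arange(0.0, spec.duration_s + 1e-9, spec.sampling_interval_s)
    if len(times) < 2:
        raise SpecError("spec yields fewer than 2 samples")

    segments = _segment_slopes_per_min(spec)
    starts = {
        TraceKind.RESPIROMETRY: spec.o2_start,
        TraceKind.FLUORESCENCE: spec.baseline_au,
        TraceKind.ABSORBANCE: spec.absorbance_start,
    }
    latent = np.empty_like(times)
    value = starts[spec.kind]
    seg_idx = 0
    prev_t = 0.0
    for i, t in enumerate(times):
        # advance through any segment boundaries crossed since prev_t
        while seg_idx + 1 < len(segments) and segments[seg_idx + 1][0] <= t:
            boundary = segments[seg_idx + 1][0]
            value += segments[seg_idx][1] * (boundary - prev_t) / 60.0
            prev_t = boundary
            seg_idx += 1
        value += segments[seg_idx][1] * (t - prev_t) / 60.0
        prev_t = t
        latent[i] = value

    if spec.kind == TraceKind.RESPIROMETRY and latent.min() < 0:
        raise SpecError(
            f"spec is infeasible: oxygen concentration reaches "
            f"{latent.min():.1f} nmol/mL before the trace ends; shorten the "
            "trace, lower the fluxes, or raise o2_start"
        )

    rng = np.random.default_rng(spec.seed)
    noisy = latent + rng.normal(0.0, spec.noise_sd, size=latent.shape) \
        if spec.noise_sd > 0 else latent

    kinds = {
        TraceKind.RESPIROMETRY: ChannelKind.OXYGEN_CONC,
        TraceKind.FLUORESCENCE: ChannelKind.FLUORESCENCE,
        TraceKind.ABSORBANCE: ChannelKind.ABSORBANCE,
    }
    events = spec.events or (
        RESPIROMETRY_EVENTS if spec.kind == TraceKind.RESPIROMETRY else ()
    )
    return TimeSeriesTrace(
        channel_kind=kinds[spec.kind],
        times=times,
        values=noisy,
        events=[InjectionEvent(time=t, label=EventLabel(lab))
                for t, lab in events],
        metadata={"chamber_volume_ml": spec.volume_ml,
                  "assay_volume_ml": spec.volume_ml,
                  "pathlength_cm": spec.pathlength_cm},
    )


#: Sex-specific peak weight loss of diseased animals, as a fraction of
#: the day-0 baseline: males lose 8 %, females 11 %.
DISEASE_NADIR_FRACTION = {"male": 0.92, "female": 0.89}

#: Daily fractional growth of healthy young-adult controls.
CONTROL_GROWTH_PER_DAY = 0.005


def make_weight_trajectory(
    sex: str,
    group: str,
    baseline_g: float,
    seed: int = 0,
    n_days: int = 31,
    cv: float = 0.0,
    mt_arm: str = "none",
) -> pd.DataFrame:
    """Daily body weights for days 0..n_days-1.

    Disease trajectories fall linearly from the day-0 baseline to the
    sex-specific nadir at day 2, hold it through day 3, recover linearly
    to the healthy growth curve by day 7, and track it thereafter.
    Controls drift upward throughout.  mitoTEMPO arms in females halve
    the depth of the nadir (treatment effect on disease activity);
    male trajectories are unaffected by mitoTEMPO.

    Noise is multiplicative lognormal with coefficient of variation
    ``cv`` (mean-one, so zero-noise expectations are preserved).
    """
    if baseline_g <= 0:
        raise SpecError(f"baseline weight must be > 0, got {baseline_g}")
    if sex not in DISEASE_NADIR_FRACTION:
        raise SpecError(f"sex must be 'male' or 'female', got {sex!r}")
    days = np.arange(n_days)
    control_curve = baseline_g * (1.0 + CONTROL_GROWTH_PER_DAY * days)

    if group == "control":
        latent = control_curve
    elif group == "IBD":
        nadir_frac = DISEASE_NADIR_FRACTION[sex]
        if sex == "female" and mt_arm in ("MT_treatment", "MT_prophylaxis"):
            nadir_frac = 1.0 - (1.0 - nadir_frac) / 2.0
        nadir = baseline_g * nadir_frac
        latent = control_curve.astype(float).copy()
        for d in range(min(n_days, 8)):
            if d == 0:
                latent[d] = baseline_g
            elif d == 1:
                latent[d] = (baseline_g + nadir) / 2.0
            elif d in (2, 3):
                latent[d] = nadir
            else:  # days 4-7: linear recovery to the control curve at day 7
                frac = (d - 3) / 4.0
                latent[d] = nadir + frac * (control_curve[min(7, n_days - 1)] - nadir)
    else:
        raise SpecError(f"group must be 'control' or 'IBD', got {group!r}")

    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + cv * cv))
        noise = np.exp(rng.normal(0.0, sigma, size=n_days) - sigma * sigma / 2.0)
        weights = latent * noise
    else:
        weights = latent.astype(float)
    return pd.DataFrame({"day": days, "body_weight_g": weights})


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Control-female endpoint means.  Respiration and complex activities
#: are citrate-synthase-normalized (nmol e-/nmol citrate); leak is in
#: percent; citrate synthase in nmol/min/g tissue; antioxidant and
#: content markers in their assay units.
BASELINE_ENDPOINTS: dict[str, float] = {
    "cs_activity": 500.0,
    "cardiolipin": 10.0,
    "resp_complex_i": 2.0,
    "resp_complex_ii": 2.0,
    "resp_lcfa": 1.0,
    "resp_mcfa": 1.0,
    "rcr": 4.0,
    "leak_complex_i": 1.0,
    "leak_complex_ii": 1.0,
    "leak_lcfa": 1.0,
    "leak_mcfa": 1.0,
    "complex_i": 4.0,
    "complex_ii": 3.0,
    "complex_iii": 6.0,
    "complex_iv": 8.0,
    "catalase": 20.0,
}

#: Endpoints on which control males sit below control females
#: (sex-difference multiplier applied to every male group).
MALE_CONTROL_DEFICIT: dict[str, float] = {
    "resp_complex_i": 0.7,
    "resp_complex_ii": 0.7,
    "resp_mcfa": 0.7,
    "complex_ii": 0.7,
    "complex_iii": 0.7,
    "complex_iv": 0.7,
}

#: Disease-effect multipliers, keyed by (sex, mt_arm) for diseased
#: animals.  Males: mitochondrial-content (citrate synthase,
#: cardiolipin) and catalase losses with a roughly 2-fold leak increase
#: (1.4-fold on MCFA); females: respiration, RCR and complex I/IV
#: losses with 2-fold leak increases.  mitoTEMPO partially restores the
#: female defects but not the male ones.
DEFAULT_EFFECTS: dict[tuple[str, str], dict[str, float]] = {
    ("male", "none"): {
        "cs_activity": 0.6, "cardiolipin": 0.7, "catalase": 0.6,
        "leak_complex_i": 2.0, "leak_complex_ii": 2.0,
        "leak_lcfa": 2.0, "leak_mcfa": 1.4,
    },
    ("female", "none"): {
        "resp_complex_i": 0.5, "resp_complex_ii": 0.5,
        "resp_lcfa": 0.5, "resp_mcfa": 0.5, "rcr": 0.5,
        "complex_i": 0.6, "complex_iv": 0.6,
        "leak_complex_i": 2.0, "leak_complex_ii": 2.0,
        "leak_lcfa": 2.0, "leak_mcfa": 2.0,
    },
}
# mitoTEMPO arms: males keep the full disease effect; females recover
# most of the leak increase and part of the complex I/IV loss.
DEFAULT_EFFECTS[("male", "MT_treatment")] = dict(DEFAULT_EFFECTS[("male", "none")])
DEFAULT_EFFECTS[("male", "MT_prophylaxis")] = dict(DEFAULT_EFFECTS[("male", "none")])
for _arm in ("MT_treatment", "MT_prophylaxis"):
    _f = dict(DEFAULT_EFFECTS[("female", "none")])
    _f.update({
        "leak_complex_i": 1.2, "leak_complex_ii": 1.2,
        "leak_lcfa": 1.2, "leak_mcfa": 1.2,
        "complex_i": 0.9, "complex_iv": 0.9,
        "resp_complex_i": 0.8, "resp_complex_ii": 0.8,
        "resp_lcfa": 0.8, "resp_mcfa": 0.8, "rcr": 0.8,
    })
    DEFAULT_EFFECTS[("female", _arm)] = _f


@dataclass(frozen=True)
class CohortSpec:
    """Design and effect structure of a synthetic cohort.

    ``groups`` is a sequence of (sex, disease, mt_arm) triples with sex
    in {male, female}, disease in {control, IBD}, mt_arm in {none,
    MT_treatment, MT_prophylaxis}.  ``effects`` maps (sex, mt_arm) to
    endpoint multipliers applied to diseased animals;
    ``male_deficit`` multipliers apply to every male animal.
    """

    n_per_group: int = 8
    groups: tuple[tuple[str, str, str], ...] = (
        ("male", "control", "none"),
        ("male", "IBD", "none"),
        ("female", "control", "none"),
        ("female", "IBD", "none"),
    )
    cv: float = 0.15
    seed: int = 0
    baseline: dict = field(default_factory=lambda: dict(BASELINE_ENDPOINTS))
    effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_EFFECTS.items()
    })
    male_deficit: dict = field(default_factory=lambda: dict(MALE_CONTROL_DEFICIT))
    baseline_weight_g: dict = field(
        default_factory=lambda: {"male": 250.0, "female": 180.0}
    )

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SpecError("n_per_group must be >= 1")
        if not self.groups:
            raise SpecError("cohort spec needs at least one group")
        if self.cv < 0:
            raise SpecError("between-animal CV must be >= 0")
        for mult_map in self.effects.values():
            if any(m <= 0 for m in mult_map.values()):
                raise SpecError("effect multipliers must be > 0")


def group_mean(spec: CohortSpec, endpoint: str,
               sex: str, disease: str, mt_arm: str) -> float:
    """Latent (noise-free) group mean for one endpoint."""
    value = spec.baseline[endpoint]
    if sex == "male":
        value *= spec.male_deficit.get(endpoint, 1.0)
    if disease == "IBD":
        value *= spec.effects.get((sex, mt_arm), {}).get(endpoint, 1.0)
    return value


def _group_label(sex: str, disease: str, mt_arm: str) -> str:
    label = f"{sex}_{disease}"
    return label if mt_arm == "none" else f"{label}_{mt_arm}"


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-animal endpoint table with design labels.

    Each animal's endpoint value is its group mean times mean-one
    lognormal noise with coefficient of variation ``spec.cv``;
    reproducible from ``spec.seed``.  Columns: ``animal_id, sex,
    disease, mt_arm, group`` plus one column per endpoint.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.cv * spec.cv)) if spec.cv > 0 else 0.0
    endpoints = list(spec.baseline)
    rows = []
    counter = 0
    for sex, disease, mt_arm in spec.groups:
        for _ in range(spec.n_per_group):
            counter += 1
            row = {
                "animal_id": f"A{counter:03d}",
                "sex": sex,
                "disease": disease,
                "mt_arm": mt_arm,
                "group": _group_label(sex, disease, mt_arm),
            }
            for ep in endpoints:
                mu = group_mean(spec, ep, sex, disease, mt_arm)
                if sigma > 0:
                    noise = math.exp(rng.normal(0.0, sigma) - sigma * sigma / 2.0)
                else:
                    noise = 1.0
                row[ep] = mu * noise
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_trace_specs(
    cohort: pd.DataFrame,
    volume_ml: float = 2.1,
    state3_scale: float = 25.0,
    calibration_slope: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, dict[str, TraceSpec]]:
    """Per-animal respirometry + fluorescence trace specs consistent
    with each animal's complex-I-condition endpoints.

    The raw state-3 flux is the normalized respiration endpoint times
    ``state3_scale`` nmol O2/min per normalized unit; state-2 follows
    from the animal's RCR, and the H2O2 rate from its percent leak
    (leak % = 100 * 2 J_H2O2 / 4 J_O2 inverted).  Quantifying these
    traces therefore reproduces each animal's rcr and leak endpoints.
    """
    specs: dict[str, dict[str, TraceSpec]] = {}
    for i, row in cohort.iterrows():
        state3 = float(row["resp_complex_i"]) * state3_scale
        state2 = state3 / float(row["rcr"])
        j_h2o2 = float(row["leak_complex_i"]) / 100.0 * 4.0 * state3 / 2.0
        specs[row["animal_id"]] = {
            "respirometry": TraceSpec(
                kind=TraceKind.RESPIROMETRY, volume_ml=volume_ml,
                state2_flux=state2, state3_flux=state3,
                noise_sd=noise_sd, seed=seed + 2 * i,
            ),
            "fluorescence": TraceSpec(
                kind=TraceKind.FLUORESCENCE, volume_ml=volume_ml,
                j_h2o2=j_h2o2, calibration_slope=calibration_slope,
                noise_sd=noise_sd, seed=seed + 2 * i + 1,
                events=((60.0, "homogenate"),),
            ),
        }
    return specs


def make_stool_observations(
    cohort: pd.DataFrame,
    seed: int = 0,
    n_days: int = 8,
    weight_cv: float = 0.005,
) -> pd.DataFrame:
    """Daily observation table (weights + stool categories) for a cohort.

    Disease animals show loose-to-bloody stools around the day 2–3 peak
    and normalize during recovery; controls stay normal/brown.  Weight
    trajectories come from :func:`make_weight_trajectory` with each
    animal's sex, disease group and mitoTEMPO arm.
    """
    rows = []
    for i, row in cohort.iterrows():
        base = {"male": 250.0, "female": 180.0}[row["sex"]]
        traj = make_weight_trajectory(
            sex=row["sex"], group=row["disease"], baseline_g=base,
            seed=seed + i, n_days=n_days, cv=weight_cv, mt_arm=row["mt_arm"],
        )
        diseased = row["disease"] == "IBD"
        for _, day_row in traj.iterrows():
            day = int(day_row["day"])
            peak = diseased and day in (2, 3)
            recovering = diseased and day in (1, 4, 5)
            rows.append({
                "animal_id": row["animal_id"],
                "day": day,
                "body_weight_g": float(day_row["body_weight_g"]),
                "stool_consistency": ("diarrhea" if peak else
                                      "loose_pasty" if recovering else "normal"),
                "stool_color": ("bloody" if peak else
                                "dark_brown" if recovering else "brown"),
            })
    return pd.DataFrame(rows)
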