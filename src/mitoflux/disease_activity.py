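"""Composite colitis disease-activity scoring and colon morphometrics.

The disease activity index (DAI) sums three 0–3 subscores — percent
body-weight loss from baseline, stool consistency, and stool color — for
a total of 0–9.  Weight-loss bins: 0 for <= 2 %, 1 for 3–6 %, 2 for
7–12 %, 3 for > 12 %.  The bins are integer-labelled and leave gaps
(2–3 %, 6–7 %), so percent loss is rounded to the nearest integer before
lookup; weight gain scores 0.  Colon shortening and the colon
weight-to-body-weight and weight-to-length ratios serve as additional
macroscopic disease indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .errors import ScoringError

__all__ = [
    "StoolConsistency",
    "StoolColor",
    "DailyObservation",
    "DaiScore",
    "ColonMorphometrics",
    "weight_loss_subscore",
    "stool_subscore",
    "total_dai",
    "colon_morphometrics",
    "score_daily_table",
]


class StoolConsistency(str, Enum):
    NORMAL = "normal"
    SEMI_SOLID = "semi_solid"
    LOOSE_PASTY = "loose_pasty"
    DIARRHEA = "diarrhea"


class StoolColor(str, Enum):
    BROWN = "brown"
    DARK_BROWN = "dark_brown"
    BLACK = "black"
    BLOODY = "bloody"


_CONSISTENCY_SCORES = {
    StoolConsistency.NORMAL: 0,
    StoolConsistency.SEMI_SOLID: 1,
    StoolConsistency.LOOSE_PASTY: 2,
    StoolConsistency.DIARRHEA: 3,
}

_COLOR_SCORES = {
    StoolColor.BROWN: 0,
    StoolColor.DARK_BROWN: 1,
    StoolColor.BLACK: 2,
    StoolColor.BLOODY: 3,
}


@dataclass(frozen=True)
class DailyObservation:
    """One animal-day of monitoring data."""

    animal_id: str
    day: int
    body_weight_g: float
    stool_consistency: StoolConsistency
    stool_color: StoolColor

    def __post_init__(self) -> None:
        if self.body_weight_g <= 0:
            raise ScoringError(f"body weight must be > 0 g, got {self.body_weight_g}")
        if self.day < 0:
            raise ScoringError(f"day must be >= 0, got {self.day}")
        object.__setattr__(self, "stool_consistency",
                           StoolConsistency(self.stool_consistency))
        object.__setattr__(self, "stool_color", StoolColor(self.stool_color))


@dataclass(frozen=True)
class DaiScore:
    weight_subscore: int
    consistency_subscore: int
    color_subscore: int

    @property
    def total(self) -> int:
        return self.weight_subscore + self.consistency_subscore + self.color_subscore


@dataclass(frozen=True)
class ColonMorphometrics:
    """Colon size ratios used as macroscopic disease indicators."""

    length_cm: float
    colon_weight_g: float
    weight_to_body: float  # g colon / g body
    weight_to_length: float  # g colon / cm colon


def weight_loss_subscore(percent_loss: float) -> int:
    """Weight-loss component of the DAI.

    ``percent_loss`` is 100 * (baseline - current) / baseline; negative
    values (weight gain) count as 0 % loss.  The value is rounded to the
    nearest integer so every input falls into exactly one of the
    integer-labelled bins.
    """
    if not math.isfinite(percent_loss):
        raise ScoringError(f"percent loss must be finite, got {percent_loss}")
    loss = max(0.0, percent_loss)
    loss_int = int(round(loss))
    if loss_int <= 2:
        return 0
    if loss_int <= 6:
        return 1
    if loss_int <= 12:
        return 2
    return 3


def stool_subscore(kind: str, category: str) -> int:
    """Rubric lookup for the stool consistency or color subscore."""
    if kind == "consistency":
        try:
            return _CONSISTENCY_SCORES[StoolConsistency(category)]
        except ValueError:
            raise ScoringError(
                f"unknown stool consistency {category!r}; valid: "
                f"{[c.value for c in StoolConsistency]}"
            ) from None
    if kind == "color":
        try:
            return _COLOR_SCORES[StoolColor(category)]
        except ValueError:
            raise ScoringError(
                f"unknown stool color {category!r}; valid: "
                f"{[c.value for c in StoolColor]}"
            ) from None
    raise ScoringError(f"kind must be 'consistency' or 'color', got {kind!r}")


def total_dai(obs: DailyObservation, baseline_weight_g: float) -> DaiScore:
    """Total disease activity score for one observation.

    The baseline is the animal's day-0 weight (dosing starts on day 0).
    """
    if baseline_weight_g <= 0:
        raise ScoringError(f"baseline weight must be > 0, got {baseline_weight_g}")
    pct_loss = 100.0 * (baseline_weight_g - obs.body_weight_g) / baseline_weight_g
    return DaiScore(
        weight_subscore=weight_loss_subscore(pct_loss),
        consistency_subscore=_CONSISTENCY_SCORES[obs.stool_consistency],
        color_subscore=_COLOR_SCORES[obs.stool_color],
    )


def colon_morphometrics(
    colon_weight_g: float, body_weight_g: float, length_cm: float
) -> ColonMorphometrics:
    """Colon weight-to-body-weight and weight-to-length ratios."""
    for name, v in (("colon weight", colon_weight_g),
                    ("body weight", body_weight_g),
                    ("colon length", length_cm)):
        if not (math.isfinite(v) and v > 0):
            raise ScoringError(f"{name} must be a positive finite number, got {v}")
    return ColonMorphometrics(
        length_cm=length_cm,
        colon_weight_g=colon_weight_g,
        weight_to_body=colon_weight_g / body_weight_g,
        weight_to_length=colon_weight_g / length_cm,
    )


def score_daily_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Score a tidy daily-observation table.

    Expects columns ``animal_id, day, body_weight_g, stool_consistency,
    stool_color``; the baseline is each animal's day-0 weight.  Returns
    the table with subscore/total columns appended, plus a per-animal
    ``peak_dai`` convenience column (maximum total over days).
    """
    required = {"animal_id", "day", "body_weight_g", "stool_consistency",
                "stool_color"}
    missing = required - set(observations.columns)
    if missing:
        raise ScoringError(f"observation table missing columns: {sorted(missing)}")
    df = observations.copy()
    baselines = (
        df[df["day"] == 0].set_index("animal_id")["body_weight_g"].to_dict()
    )
    rows = []
    for _, r in df.iterrows():
        base = baselines.get(r["animal_id"])
        if base is None:
            raise ScoringError(f"animal {r['animal_id']!r} has no day-0 baseline")
        obs = DailyObservation(
            animal_id=str(r["animal_id"]), day=int(r["day"]),
            body_weight_g=float(r["body_weight_g"]),
            stool_consistency=StoolConsistency(r["stool_consistency"]),
            stool_color=StoolColor(r["stool_color"]),
        )
        s = total_dai(obs, base)
        rows.append((s.weight_subscore, s.consistency_subscore,
                     s.color_subscore, s.total))
    df[["weight_subscore", "consistency_subscore", "color_subscore",
        "dai_total"]] = pd.DataFrame(rows, index=df.index)
    df["peak_dai"] = df.groupby("animal_id")["dai_total"].transform("max")
    return df
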