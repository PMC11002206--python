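"""Pipeline orchestration: traces -> endpoints -> scores -> statistics.

A single YAML configuration drives the full quantification chain:

1. fit the Amplex-Red H2O2 calibration from the calibration CSV;
2. for every animal's respirometry trace, segment respiration states
   and compute state-2/state-3 fluxes and the RCR; when a paired
   fluorescence trace exists, convert its slope over the matched
   state-3 window into an H2O2 rate, the superoxide rate, and the
   percent electron leak;
3. score the daily-observation table into disease-activity indices;
4. run the group-comparison statistics over the endpoint table.

Outputs are tidy CSVs plus a run log carrying the config hash, the seed
and every QC flag raised anywhere in the run.  Identical config + seed
reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ros_leak
from .cohort_stats import compare_endpoints
from .disease_activity import score_daily_table
from .errors import ConfigError, MitofluxError
from .respirometry import (
    DEFAULT_SETTLE_TIME_S,
    DEFAULT_STATE_WINDOW_S,
    segment_states,
)
from .ros_leak import LeakDenominator, fit_calibration, h2o2_rate
from .signals import ChannelKind, SlopeMode, TraceDialect, estimate_slope, read_trace

__all__ = [
    "PipelineConfig",
    "load_config",
    "validate_config",
    "run_pipeline",
    "simulate_study",
]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    output_dir: Path
    seed: int = 0
    trace_dir: Optional[Path] = None
    cohort_csv: Optional[Path] = None
    daily_csv: Optional[Path] = None
    calibration_csv: Optional[Path] = None
    chamber_volume_ml: float = 2.1
    settle_time_s: float = DEFAULT_SETTLE_TIME_S
    state_window_s: float = DEFAULT_STATE_WINDOW_S
    leak_denominator: LeakDenominator = LeakDenominator.O2_ONLY
    posthoc: str = "tukey"
    dialect: TraceDialect = field(default_factory=TraceDialect)
    raw: dict = field(default_factory=dict)


def _violations(doc: dict) -> list[str]:
    """All schema problems in a parsed config document, not just the
    first."""
    problems: list[str] = []
    if not isinstance(doc, dict):
        return ["config root must be a mapping"]
    if "output_dir" not in doc:
        problems.append("missing required key: output_dir")
    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        problems.append(f"seed must be an integer, got {seed!r}")
    analysis = doc.get("analysis", {})
    if not isinstance(analysis, dict):
        problems.append("analysis must be a mapping")
        analysis = {}
    settle = analysis.get("settle_time_s", DEFAULT_SETTLE_TIME_S)
    if not isinstance(settle, (int, float)) or settle < 0:
        problems.append(f"analysis.settle_time_s must be >= 0, got {settle!r}")
    window = analysis.get("state_window_s", DEFAULT_STATE_WINDOW_S)
    if not isinstance(window, (int, float)) or window <= 0:
        problems.append(f"analysis.state_window_s must be > 0, got {window!r}")
    denom = analysis.get("leak_denominator", "o2_only")
    if denom not in ("o2_only", "total"):
        problems.append(
            f"analysis.leak_denominator must be 'o2_only' or 'total', got {denom!r}"
        )
    posthoc = analysis.get("posthoc", "tukey")
    if posthoc not in ("tukey", "pairwise_t"):
        problems.append(
            f"analysis.posthoc must be 'tukey' or 'pairwise_t', got {posthoc!r}"
        )
    vol = doc.get("traces", {}).get("chamber_volume_ml", 2.1) \
        if isinstance(doc.get("traces", {}), dict) else 2.1
    if not isinstance(vol, (int, float)) or vol <= 0:
        problems.append(f"traces.chamber_volume_ml must be > 0, got {vol!r}")
    for name, block in (doc.get("assays") or {}).items():
        if not isinstance(block, dict):
            problems.append(f"assays.{name} must be a mapping")
            continue
        for key in ("epsilon", "pathlength_cm", "assay_volume_ml"):
            if key not in block:
                problems.append(f"assays.{name}: missing required field {key!r}")
            elif not isinstance(block[key], (int, float)) or block[key] <= 0:
                problems.append(
                    f"assays.{name}.{key} must be > 0, got {block[key]!r}"
                )
    return problems


def validate_config(path: str | Path) -> list[str]:
    """Parse a config file and return every schema violation found.

    An empty list means the config is valid.  Raises
    :class:`ConfigError` (with the line number where available) if the
    file cannot be parsed at all.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse config {path}{line}: {exc}") from exc
    return _violations(doc or {})


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a pipeline config, raising on any violation."""
    path = Path(path)
    problems = validate_config(path)
    if problems:
        raise ConfigError(
            f"invalid config {path}:\n  " + "\n  ".join(problems)
        )
    doc = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def _resolve(key: str, sub: Optional[dict] = None,
                 subkey: Optional[str] = None) -> Optional[Path]:
        src = sub if sub is not None else doc
        k = subkey if subkey is not None else key
        if k not in src or src[k] is None:
            return None
        p = Path(src[k])
        return p if p.is_absolute() else base / p

    traces = doc.get("traces") or {}
    analysis = doc.get("analysis") or {}
    dialect_doc = doc.get("dialect") or {}
    dialect = TraceDialect(
        delimiter=dialect_doc.get("delimiter", ","),
        time_column=dialect_doc.get("time_column", "time_s"),
        value_column=dialect_doc.get("value_column", "value"),
        event_column=dialect_doc.get("event_column", "event"),
    )
    out = Path(doc["output_dir"])
    return PipelineConfig(
        output_dir=out if out.is_absolute() else base / out,
        seed=int(doc.get("seed", 0)),
        trace_dir=_resolve("traces", traces, "directory"),
        cohort_csv=_resolve("cohort_csv"),
        daily_csv=_resolve("daily_csv"),
        calibration_csv=_resolve("calibration_csv"),
        chamber_volume_ml=float(traces.get("chamber_volume_ml", 2.1)),
        settle_time_s=float(analysis.get("settle_time_s", DEFAULT_SETTLE_TIME_S)),
        state_window_s=float(analysis.get("state_window_s", DEFAULT_STATE_WINDOW_S)),
        leak_denominator=LeakDenominator(
            analysis.get("leak_denominator", "o2_only")
        ),
        posthoc=analysis.get("posthoc", "tukey"),
        dialect=dialect,
        raw=doc,
    )


def _quantify_traces(config: PipelineConfig, qc_log: list[str]) -> pd.DataFrame:
    """State-2/state-3 fluxes, RCR and (when paired) ROS per animal.

    Trace files are discovered as ``<animal_id>_respirometry.csv`` with
    optional ``<animal_id>_fluorescence.csv`` companions.
    """
    calibration = None
    if config.calibration_csv is not None:
        if not config.calibration_csv.exists():
            raise MitofluxError(
                f"stage quantify: calibration file not found: "
                f"{config.calibration_csv}"
            )
        cal_df = pd.read_csv(config.calibration_csv)
        calibration = fit_calibration(cal_df["conc_uM"], cal_df["response_au"])

    rows = []
    resp_files = sorted(config.trace_dir.glob("*_respirometry.csv"))
    if not resp_files:
        raise MitofluxError(
            f"stage quantify: no *_respirometry.csv traces in {config.trace_dir}"
        )
    for resp_path in resp_files:
        animal_id = resp_path.name[: -len("_respirometry.csv")]
        try:
            trace = read_trace(resp_path, ChannelKind.OXYGEN_CONC,
                               dialect=config.dialect)
            states = segment_states(
                trace,
                settle_time_s=config.settle_time_s,
                window_length_s=config.state_window_s,
                chamber_volume_ml=config.chamber_volume_ml,
            )
        except MitofluxError as exc:
            raise MitofluxError(
                f"stage quantify, file {resp_path.name}: {exc}"
            ) from exc
        row = {
            "animal_id": animal_id,
            "state2_j_o2": states.state2.j_o2,
            "state3_j_o2": states.state3.j_o2,
            "rcr": states.rcr,
            "j_h2o2": np.nan,
            "j_so": np.nan,
            "percent_leak": np.nan,
            "qc_flags": ";".join(states.qc_flags),
        }
        for flag in states.qc_flags:
            qc_log.append(f"{animal_id}:{flag}")

        fluor_path = resp_path.with_name(f"{animal_id}_fluorescence.csv")
        if fluor_path.exists():
            if calibration is None:
                raise MitofluxError(
                    f"stage quantify, file {fluor_path.name}: fluorescence "
                    "trace present but no calibration_csv configured"
                )
            ftrace = read_trace(fluor_path, ChannelKind.FLUORESCENCE,
                                dialect=config.dialect)
            # measure over the window matched to the state-3 segment,
            # clipped to the fluorescence trace span
            w0, w1 = states.state3.source_window
            w1 = min(w1, ftrace.span[1])
            fslope = estimate_slope(ftrace, window=(w0, w1),
                                    mode=SlopeMode.FIXED_WINDOW)
            j_h2o2 = h2o2_rate(fslope.slope, calibration,
                               config.chamber_volume_ml)
            res = ros_leak.ros_result(max(0.0, j_h2o2), states.state3.j_o2,
                                      denominator=config.leak_denominator)
            if j_h2o2 < 0:
                qc_log.append(f"{animal_id}:negative_h2o2_rate")
                row["qc_flags"] = ";".join(
                    filter(None, [row["qc_flags"], "negative_h2o2_rate"])
                )
            row.update({"j_h2o2": res.j_h2o2, "j_so": res.j_so,
                        "percent_leak": res.percent_leak})
        rows.append(row)
    return pd.DataFrame(rows)


def _default_contrasts(cohort: pd.DataFrame) -> list[tuple[str, str]]:
    """Within-sex disease contrasts plus the control sex contrast."""
    groups = set(cohort["group"])
    contrasts = []
    for sex in ("male", "female"):
        if {f"{sex}_control", f"{sex}_IBD"} <= groups:
            contrasts.append((f"{sex}_control", f"{sex}_IBD"))
    if {"male_control", "female_control"} <= groups:
        contrasts.append(("male_control", "female_control"))
    for sex in ("male", "female"):
        for arm in ("MT_treatment", "MT_prophylaxis"):
            if {f"{sex}_IBD", f"{sex}_IBD_{arm}"} <= groups:
                contrasts.append((f"{sex}_IBD", f"{sex}_IBD_{arm}"))
    return contrasts


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage and write the results bundle.

    Returns a mapping of output name -> written path.  Any stage error
    propagates as :class:`MitofluxError` naming the stage and file.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc_log: list[str] = []
    written: dict[str, Path] = {}

    if config.trace_dir is not None:
        quant = _quantify_traces(config, qc_log)
        p = out / "quantification.csv"
        quant.to_csv(p, index=False)
        written["quantification"] = p

    if config.daily_csv is not None:
        if not config.daily_csv.exists():
            raise MitofluxError(
                f"stage score: daily observation file not found: "
                f"{config.daily_csv}"
            )
        daily = pd.read_csv(config.daily_csv)
        scored = score_daily_table(daily)
        p = out / "dai_scores.csv"
        scored.to_csv(p, index=False)
        written["dai_scores"] = p

    if config.cohort_csv is not None:
        if not config.cohort_csv.exists():
            raise MitofluxError(
                f"stage stats: cohort endpoint file not found: "
                f"{config.cohort_csv}"
            )
        cohort = pd.read_csv(config.cohort_csv)
        comparisons = compare_endpoints(
            cohort, group_column="group",
            contrasts=_default_contrasts(cohort),
        )
        p = out / "comparisons.csv"
        comparisons.to_csv(p, index=False)
        written["comparisons"] = p

    config_hash = hashlib.sha256(
        json.dumps(config.raw, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    log = {
        "config_hash": config_hash,
        "seed": config.seed,
        "outputs": {k: str(v) for k, v in written.items()},
        "qc_flags": sorted(set(qc_log)),
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2) + "\n")
    written["run_log"] = log_path
    return written


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 8,
    cv: float = 0.15,
    trace_noise_sd: float = 0.0,
    include_mt_arms: bool = False,
) -> Path:
    """Write a complete synthetic study directory and its pipeline
    config.

    Produces per-animal respirometry + fluorescence trace CSVs, the
    cohort endpoint table, daily observations, the H2O2 calibration
    points, and a ready-to-run ``config.yaml``.  Returns the config
    path.
    """
    from .signals import write_trace
    from .synthetic_data import (
        CohortSpec,
        cohort_trace_specs,
        make_cohort,
        make_stool_observations,
        make_trace,
    )

    out = Path(out_dir)
    traces_dir = out / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)

    groups = [
        ("male", "control", "none"), ("male", "IBD", "none"),
        ("female", "control", "none"), ("female", "IBD", "none"),
    ]
    if include_mt_arms:
        groups += [
            ("male", "IBD", "MT_treatment"), ("male", "IBD", "MT_prophylaxis"),
            ("female", "IBD", "MT_treatment"),
            ("female", "IBD", "MT_prophylaxis"),
        ]
    spec = CohortSpec(n_per_group=n_per_group, cv=cv, seed=seed,
                      groups=tuple(groups))
    cohort = make_cohort(spec)
    cohort.to_csv(out / "cohort.csv", index=False)

    daily = make_stool_observations(cohort, seed=seed + 1)
    daily.to_csv(out / "daily.csv", index=False)

    cal_slope = 10.0  # AU per uM H2O2
    concs = [0.0, 0.5, 1.0, 2.0, 4.0]
    cal = pd.DataFrame({"conc_uM": concs,
                        "response_au": [50.0 + cal_slope * c for c in concs]})
    cal.to_csv(out / "calibration.csv", index=False)

    specs = cohort_trace_specs(cohort, volume_ml=2.1,
                               calibration_slope=cal_slope,
                               noise_sd=trace_noise_sd, seed=seed + 2)
    for animal_id, pair in specs.items():
        for kind, tspec in pair.items():
            write_trace(make_trace(tspec), traces_dir / f"{animal_id}_{kind}.csv")

    config_doc = {
        "seed": seed,
        "output_dir": "results",
        "traces": {"directory": "traces", "chamber_volume_ml": 2.1},
        "cohort_csv": "cohort.csv",
        "daily_csv": "daily.csv",
        "calibration_csv": "calibration.csv",
        "analysis": {
            "settle_time_s": DEFAULT_SETTLE_TIME_S,
            "state_window_s": DEFAULT_STATE_WINDOW_S,
            "leak_denominator": "o2_only",
            "posthoc": "tukey",
        },
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config_doc, sort_keys=False))
    return config_path
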