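"""End-to-end analysis pipeline and its file I/O schemas.

Stage order: design -> synth (or load) -> qc -> metrics -> trend +
asymmetry.  All inter-stage data are plain tabular files with documented
columns; timestamps are seconds relative to perturbation onset (t = 0).

Outputs written to the run directory:

- ``conditions.csv``    one row per perturbation condition
- ``waveforms/<id>.csv``  platform command per condition
  (time_s, accel_dps2, vel_dps, pos_deg)
- ``qc_report.csv``     per-trial keep/exclude decision and reasons
- ``qc_summary.csv``    per-animal exclusion counts/fractions
- ``metrics.csv``       tidy per-trial, per-channel response metrics
- ``trend.csv``         ANOVA + gated regression per axis/direction/
  channel/window/stimulus set
- ``asymmetry.csv``     per (axis, channel, animal, profile) index and
  p-value, plus Fisher-combined p per (axis, channel)
- ``manifest.json``     config hash, seed, package version, row counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asymmetry import asymmetry_index, fisher_combine
from .design import (
    PerturbationSpec,
    ProtocolConfig,
    design_waveform,
    enumerate_conditions,
)
from .metrics import metrics_table
from .qc import QCThresholds, TrialRecord, qc_trial, summarize_exclusions
from .stats import trend_analysis
from .synth import GeneratorSpec, generate_trial_set, ground_truth_table

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("tiltpost")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one pipeline run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    generator: GeneratorSpec | None = None  # defaults to protocol conditions + seed
    qc: QCThresholds = field(default_factory=QCThresholds)
    seed: int = 0
    n_trials: int = 20
    contamination_rate: float = 0.1
    direction_asymmetry: float = 1.0
    asymmetry_channels: tuple[str, ...] = ("angvel", "cop")
    log_level: str = "INFO"

    def generator_spec(self) -> GeneratorSpec:
        if self.generator is not None:
            return self.generator
        return GeneratorSpec(
            conditions=tuple(enumerate_conditions(self.protocol)),
            n_trials=self.n_trials,
            contamination_rate=self.contamination_rate,
            direction_asymmetry=self.direction_asymmetry,
            seed=self.seed,
        )


def _from_mapping(cls, data: dict):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(data)
    for key in ("velocities", "accelerations", "axes", "conditions", "asymmetry_channels"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping")
    kwargs: dict = {}
    if "protocol" in raw:
        kwargs["protocol"] = _from_mapping(ProtocolConfig, raw.pop("protocol"))
    if "qc" in raw:
        kwargs["qc"] = _from_mapping(QCThresholds, raw.pop("qc"))
    if "generator" in raw:
        kwargs["generator"] = _from_mapping(GeneratorSpec, raw.pop("generator"))
    kwargs.update(raw)
    return _from_mapping(RunConfig, kwargs)


def _conditions_frame(conditions: list[PerturbationSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_id": _condition_id(c),
                "axis": c.axis,
                "direction": c.direction,
                "peak_accel_dps2": c.peak_accel,
                "peak_vel_dps": c.peak_vel,
                "displacement_deg": c.displacement,
                "motion_duration_s": c.motion_duration,
            }
            for c in conditions
        ]
    )


def _condition_id(c: PerturbationSpec) -> str:
    return f"{c.axis}-{c.direction}-a{c.peak_accel:g}-v{c.peak_vel:g}"


def _write_waveforms(conditions: list[PerturbationSpec], out: Path) -> None:
    wdir = out / "waveforms"
    wdir.mkdir(parents=True, exist_ok=True)
    for c in conditions:
        w = design_waveform(c)
        pd.DataFrame(
            {"time_s": w.time, "accel_dps2": w.accel, "vel_dps": w.vel, "pos_deg": w.pos}
        ).to_csv(wdir / f"{_condition_id(c)}.csv", index=False)


def _motion_span_trace(trial: TrialRecord, channel: str) -> np.ndarray:
    from .kinetics import compute_cop

    mask = (trial.time >= 0.0) & (trial.time <= trial.motion_end + 0.5 / trial.rate)
    if channel == "angvel":
        return trial.angvel_channel()[mask]
    if channel == "linacc":
        return trial.linacc_channel()[mask]
    if channel == "cop":
        return compute_cop(trial.forces).channel(trial.condition.axis)[mask]
    raise ValueError(f"unknown channel {channel!r}")


def _trend_stage(metrics: pd.DataFrame, protocol: ProtocolConfig) -> pd.DataFrame:
    """ANOVA-gated trend tests per axis/direction/channel/window and set."""
    rows = []
    sets = {
        "velocity": ("peak_vel_dps", metrics["peak_accel_dps2"] == protocol.base_acceleration),
        "acceleration": ("peak_accel_dps2", metrics["peak_vel_dps"] == protocol.base_velocity),
    }
    for (axis, direction, channel), grp in metrics.groupby(["axis", "direction", "channel"]):
        for set_name, (pred, set_mask) in sets.items():
            sub = grp[set_mask.loc[grp.index]]
            if sub[pred].nunique() < 2 or sub["animal_id"].nunique() < 2:
                continue
            for window in ("short_mean", "medium_mean"):
                table = sub[["animal_id", pred, window]].rename(columns={window: "value"})
                res = trend_analysis(table, pred)
                rows.append(
                    {
                        "axis": axis,
                        "direction": direction,
                        "channel": channel,
                        "window": "short" if window == "short_mean" else "medium",
                        "stimulus_set": set_name,
                        "n": len(sub),
                        "anova_p_condition": res.anova_p_condition,
                        "anova_p_animal": res.anova_p_animal,
                        "condition_significant": res.condition_significant,
                        "slope": res.regression_slope,
                        "slope_se": res.regression_slope_se,
                        "regression_p": res.regression_p,
                        "trend_significant": res.trend_significant,
                    }
                )
    return pd.DataFrame(rows)


def _asymmetry_stage(
    trials: list[TrialRecord], channels: tuple[str, ...]
) -> pd.DataFrame:
    """Per (axis, channel, animal, profile) asymmetry + Fisher-combined p."""
    groups: dict[tuple, dict[int, list[TrialRecord]]] = {}
    for tr in trials:
        c = tr.condition
        key = (c.axis, tr.animal_id, c.profile_key)
        groups.setdefault(key, {}).setdefault(c.sign, []).append(tr)
    rows = []
    for (axis, animal, profile), sides in sorted(groups.items()):
        if len(sides.get(+1, [])) < 2 or len(sides.get(-1, [])) < 2:
            continue
        for channel in channels:
            pos = [_motion_span_trace(t, channel) for t in sides[+1]]
            neg = [_motion_span_trace(t, channel) for t in sides[-1]]
            res = asymmetry_index(pos, neg)
            rows.append(
                {
                    "axis": axis,
                    "channel": channel,
                    "animal_id": animal,
                    "peak_accel_dps2": profile[0],
                    "peak_vel_dps": profile[1],
                    "index": res.index,
                    "p_value": res.p_value,
                    "n_within": len(res.within_mapes),
                    "n_across": len(res.across_mapes),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    combined = [
        {
            "axis": axis,
            "channel": channel,
            "animal_id": "all",
            "peak_accel_dps2": np.nan,
            "peak_vel_dps": np.nan,
            "index": grp["index"].mean(),
            "p_value": fisher_combine(list(grp["p_value"])),
            "n_within": grp["n_within"].sum(),
            "n_across": grp["n_across"].sum(),
        }
        for (axis, channel), grp in df.groupby(["axis", "channel"])
    ]
    return pd.concat([df, pd.DataFrame(combined)], ignore_index=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write per-stage tables plus a manifest.

    Returns the manifest (also written as ``manifest.json``).  The run is
    deterministic for a fixed config and seed.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    conditions = list(enumerate_conditions(config.protocol))
    log.info("design: %d conditions", len(conditions))
    cond_df = _conditions_frame(conditions)
    cond_df.to_csv(out / "conditions.csv", index=False)
    _write_waveforms(conditions, out)

    gen = config.generator_spec()
    trials = generate_trial_set(gen)
    log.info("synth: %d trials", len(trials))
    ground_truth_table(trials).to_csv(out / "ground_truth.csv", index=False)

    qc_results = [qc_trial(tr, config.qc) for tr in trials]
    qc_df = pd.DataFrame(
        [
            {
                "trial_id": r.trial_id,
                "animal_id": r.animal_id,
                "keep": r.keep,
                "reasons": ";".join(r.reasons),
            }
            for r in qc_results
        ]
    )
    qc_df.to_csv(out / "qc_report.csv", index=False)
    summary = summarize_exclusions(qc_results)
    summary.to_csv(out / "qc_summary.csv", index=False)
    kept_ids = {r.trial_id for r in qc_results if r.keep}
    kept = [tr for tr in trials if tr.trial_id in kept_ids]
    log.info("qc: kept %d / %d trials", len(kept), len(trials))

    metrics = metrics_table(kept)
    metrics.to_csv(out / "metrics.csv", index=False)

    trend = _trend_stage(metrics, config.protocol)
    trend.to_csv(out / "trend.csv", index=False)

    asym = _asymmetry_stage(kept, config.asymmetry_channels)
    asym.to_csv(out / "asymmetry.csv", index=False)

    cfg_repr = repr(config).encode()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_repr).hexdigest(),
        "n_conditions": len(conditions),
        "n_trials_generated": len(trials),
        "n_trials_kept": len(kept),
        "n_metric_rows": len(metrics),
        "n_trend_rows": len(trend),
        "n_asymmetry_rows": len(asym),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("pipeline complete: %s", out)
    return manifest
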