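"""End-to-end runs: simulate -> detect -> metrics -> game stats -> models.

Every run is driven by a single :class:`RunConfig`; with a fixed seed the
emitted event tables and metrics are byte-identical across runs.  All
artifact files are listed in the JSON run report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import DetectionConfig, detect_arm_lifts, detect_steps, derive_single_support
from .errors import ConfigError, RunFailed
from .gamelog import (
    GameEventLog,
    chi_square_2x2,
    mean_errors_per_trial,
    read_log,
    score_trial,
    tally_errors,
    write_log,
)
from .lmm import LmmSpec, SIDE_METRICS, assemble_metrics_table, fit_lmm
from .metrics import compute_trial_metrics
from .mocap_io import fill_gaps, load_recording, validate_recording
from .simulator import PolicyPopulation, iter_cohort


@dataclass
class RunConfig:
    seed: int = 0
    n_participants: int = 15
    trial_duration: float = 120.0
    noise_sd: float = 0.002
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    responses: tuple[str, ...] = SIDE_METRICS
    out_dir: str = "exerstep_run"
    settings_overrides: dict = field(default_factory=dict)
    population: PolicyPopulation = field(default_factory=PolicyPopulation)
    save_recordings: bool = False
    heatmap_figure: bool = True

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.trial_duration <= 0:
            raise ConfigError("trial_duration must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        unknown = set(self.responses) - set(SIDE_METRICS)
        if unknown:
            raise ConfigError(f"unknown responses: {sorted(unknown)}")


def _trial_id(meta) -> str:
    return f"{meta.participant}_{meta.speed}_{meta.obstacles}_r{meta.repetition}"


def _event_rows(trial_id: str, steps, lifts, support):
    rows = []
    for foot, evs in steps.items():
        for e in evs:
            rows.append((trial_id, "step", foot, e.start, e.end, e.size))
    for e in lifts:
        rows.append((trial_id, "arm_lift", e.side, e.start, e.end, math.nan))
    for foot, ivs in support.items():
        for iv in ivs:
            rows.append((trial_id, "single_support", foot, iv.start, iv.end, math.nan))
    return rows


def _analyze_recording(rec, cfg: RunConfig):
    steps = detect_steps(rec, cfg.detection)
    lifts = detect_arm_lifts(rec, cfg.detection)
    support = derive_single_support(steps, rec.duration)
    metrics = compute_trial_metrics(rec, steps, support, lifts)
    return steps, lifts, support, metrics


def _score_table(logs: list[GameEventLog]) -> pd.DataFrame:
    rows = []
    for log in logs:
        s = score_trial(log)
        rows.append({
            "participant": log.meta.participant, "speed": log.meta.speed,
            "obstacles": log.meta.obstacles, "repetition": log.meta.repetition,
            "score": s.score, "pct_grapes": s.pct_grapes_caught,
            "pct_chickens": s.pct_chickens_caught,
            "pct_branches_hit": s.pct_branches_hit,
        })
    df = pd.DataFrame(rows)
    return (df.groupby(["speed", "obstacles"])
              [["score", "pct_grapes", "pct_chickens", "pct_branches_hit"]]
              .mean().reset_index())


def _write_lmm_report(fit, path: Path) -> None:
    out = fit.effects.copy()
    out["converged"] = fit.converged
    out["df_method"] = fit.df_method
    out.to_csv(path, sep="\t", float_format="%.6g")


def run_synthetic_study(cfg: RunConfig) -> dict:
    """Simulate a cohort and run the full analysis chain; return the report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    manifest_rows = []
    event_rows = []
    all_metrics = []
    logs = []
    heat = None
    heat_total = 0

    n_trials = 0
    for trial in iter_cohort(
            cfg.n_participants, cfg.seed, cfg.population,
            trial_duration=cfg.trial_duration, noise_sd=cfg.noise_sd,
            settings_overrides=cfg.settings_overrides):
        rec = trial.recording
        tid = _trial_id(rec.meta)
        steps, lifts, support, metrics = _analyze_recording(rec, cfg)
        event_rows += _event_rows(tid, steps, lifts, support)
        all_metrics.append(metrics)
        logs.append(trial.log)
        log_path = out / f"log_{tid}.jsonl"
        write_log(trial.log, log_path)
        artifacts.append(log_path.name)
        if metrics.heatmap is not None:
            heat = metrics.heatmap.grid if heat is None else heat + metrics.heatmap.grid
            heat_total += metrics.heatmap.total
        manifest_rows.append({
            "trial_id": tid, **rec.meta.as_dict(),
            "duration": rec.duration, "score": trial.log.score,
            "n_steps_true": len(trial.truth.steps),
            "n_lifts_true": len(trial.truth.arm_lifts),
            "n_errors": len(trial.log.errors),
        })
        n_trials += 1

    if n_trials == 0:
        _write_report(out, artifacts, cfg, {"n_trials": 0})
        return {"n_trials": 0, "out_dir": str(out)}

    pd.DataFrame(manifest_rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    pd.DataFrame(event_rows, columns=[
        "trial_id", "event", "side", "start", "end", "size"
    ]).to_csv(out / "events.tsv", sep="\t", index=False, float_format="%.6f")
    artifacts += ["manifest.tsv", "events.tsv"]

    table = assemble_metrics_table(all_metrics)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    artifacts.append("metrics.tsv")

    _score_table(logs).to_csv(out / "scores.tsv", sep="\t", index=False,
                              float_format="%.2f")
    artifacts.append("scores.tsv")

    tally = tally_errors(logs)
    err_df = pd.DataFrame(tally.table(),
                          index=["low", "high"], columns=["without", "with"])
    err_df.to_csv(out / "errors.tsv", sep="\t")
    artifacts.append("errors.tsv")
    error_stats: dict = {"total": tally.total, "valid_trials": tally.valid_trials}
    if tally.valid_trials:
        error_stats["per_trial"] = mean_errors_per_trial(tally)
    if (err_df.to_numpy().sum(axis=0) > 0).all() and (err_df.to_numpy().sum(axis=1) > 0).all():
        stat, dof, p = chi_square_2x2(err_df.to_numpy())
        error_stats["chi2"] = {"statistic": stat, "df": dof, "p": p}

    if heat is not None:
        np.savetxt(out / "heatmap_counts.tsv", heat, fmt="%d", delimiter="\t")
        artifacts.append("heatmap_counts.tsv")
        if cfg.heatmap_figure:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots(figsize=(5, 5))
            ax.imshow(heat.T, origin="lower", extent=(-1.5, 1.5, -1.5, 1.5),
                      cmap="viridis")
            ax.add_patch(plt.Rectangle((-1, -1), 2, 2, fill=False,
                                       edgecolor="white", linewidth=1.5))
            ax.set_xlabel("X (m)")
            ax.set_ylabel("Y (m)")
            fig.savefig(out / "heatmap.png", dpi=120)
            plt.close(fig)
            artifacts.append("heatmap.png")

    model_summaries = {}
    if cfg.n_participants >= 2:
        for response in cfg.responses:
            fit = fit_lmm(table, LmmSpec(response=response))
            name = f"lmm_{response}.tsv"
            _write_lmm_report(fit, out / name)
            artifacts.append(name)
            model_summaries[response] = {
                "converged": fit.converged, "n_obs": fit.n_obs,
                "n_dropped": fit.n_dropped,
            }
    else:
        model_summaries["skipped"] = "fewer than 2 participants"

    summary = {
        "n_trials": n_trials,
        "n_participants": cfg.n_participants,
        "errors": error_stats,
        "models": model_summaries,
        "detection": dataclasses.asdict(cfg.detection),
    }
    _write_report(out, artifacts, cfg, summary)
    summary["out_dir"] = str(out)
    return summary


def _write_report(out: Path, artifacts: list[str], cfg: RunConfig, summary: dict):
    report = {
        "seed": cfg.seed,
        "config": {
            "n_participants": cfg.n_participants,
            "trial_duration": cfg.trial_duration,
            "noise_sd": cfg.noise_sd,
        },
        "artifacts": sorted(artifacts) + ["report.json"],
        "summary": summary,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))


def run_on_recordings(
    paths: list[str], cfg: RunConfig, log_paths: list[str] | None = None
) -> dict:
    """Run the analysis chain on existing trajectory files (plus optional logs).

    Per-file failures are logged and skipped; the run fails only when no
    trial succeeds.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    failures: list[dict] = []
    all_metrics = []
    event_rows = []

    for path in paths:
        try:
            rec = load_recording(path)
            rec, _ = fill_gaps(rec)
            report = validate_recording(rec)
            if not report.ok:
                raise ConfigError(
                    f"validation failed: missing={report.missing_markers}")
            tid = Path(path).stem
            steps, lifts, support, metrics = _analyze_recording(rec, cfg)
            event_rows += _event_rows(tid, steps, lifts, support)
            all_metrics.append(metrics)
        except Exception as exc:
            failures.append({"path": str(path), "error": f"{type(exc).__name__}: {exc}"})

    if not all_metrics:
        raise RunFailed(f"no trial could be processed ({len(failures)} failures)")

    pd.DataFrame(event_rows, columns=[
        "trial_id", "event", "side", "start", "end", "size"
    ]).to_csv(out / "events.tsv", sep="\t", index=False, float_format="%.6f")
    table = assemble_metrics_table(all_metrics)
    table.to_csv(out / "metrics.tsv", sep="\t", index=False, float_format="%.6f")
    artifacts += ["events.tsv", "metrics.tsv"]

    logs = []
    for lp in log_paths or []:
        try:
            logs.append(read_log(lp))
        except Exception as exc:
            failures.append({"path": str(lp), "error": f"{type(exc).__name__}: {exc}"})
    error_stats: dict = {}
    if logs:
        tally = tally_errors(logs)
        error_stats = {"total": tally.total, "valid_trials": tally.valid_trials}

    summary = {
        "n_trials": len(all_metrics),
        "failures": failures,
        "errors": error_stats,
    }
    _write_report(out, artifacts, cfg, summary)
    summary["out_dir"] = str(out)
    return summary
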