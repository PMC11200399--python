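"""End-to-end post-detection pipeline: threshold, budget, filter, posture.

Mirrors the study workflow downstream of the detector: apply the confidence
threshold, build the model-side time budget, correct Locomotion via the
plateau filter, derive the posture channel, and compare against the manual
coding — everything written out as CSV plus a text summary so a run is
fully inspectable and reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from ._rounding import round_half_up
from .budget import (
    BudgetComparison,
    TimeBudget,
    apply_confidence_threshold,
    budget_from_detections,
    budget_from_manual,
    compare_budgets,
    labeled_fraction,
)
from .io import read_detections_csv, read_manual_csv, write_detections_csv
from .locomotion import (
    CorrectedResult,
    PlateauConfig,
    corrected_budget,
    detect_plateaus,
    extract_coordinate_series,
    reclassify_false_positives,
)
from .posture import PostureSeries, RatioConfig, posture_series

logger = logging.getLogger("ethotrack")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one pipeline run (echoed to the output)."""

    detections_path: Path
    manual_path: Optional[Path] = None
    out_dir: Path = Path("ethotrack_out")
    tau: float = 0.8
    plateau: PlateauConfig = field(default_factory=PlateauConfig)
    ratio: RatioConfig = field(default_factory=RatioConfig)
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return {
            "detections_path": str(self.detections_path),
            "manual_path": str(self.manual_path) if self.manual_path else None,
            "out_dir": str(self.out_dir),
            "tau": self.tau,
            "plateau": {
                "epsilon_x": self.plateau.epsilon_x,
                "epsilon_y": self.plateau.epsilon_y,
                "min_run": self.plateau.min_run,
                "max_gap": self.plateau.max_gap,
                "require_both_axes_still": self.plateau.require_both_axes_still,
            },
            "ratio": {
                "upper_limit": self.ratio.upper_limit,
                "lower_limit": self.ratio.lower_limit,
            },
            "log_level": self.log_level,
        }


@dataclass
class RunReport:
    """Everything a pipeline run produced, with file paths."""

    raw_budget: TimeBudget
    corrected: CorrectedResult
    corrected_budget: TimeBudget
    postures: PostureSeries
    comparison_raw: Optional[BudgetComparison]
    comparison_corrected: Optional[BudgetComparison]
    files: dict[str, Path]


def write_budget_csv(budget: TimeBudget, path: Path) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["category", "count", "percent"])
        rounded = budget.rounded()
        for name, count in budget.counts.items():
            writer.writerow([name, count, rounded[name]])
    return path


def write_plateau_report_csv(runs, path: Path) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["start", "end", "n_frames", "x_range", "y_range"])
        for run in runs:
            writer.writerow(
                [run.start_frame, run.end_frame, run.n_frames,
                 repr(run.x_range), repr(run.y_range)]
            )
    return path


def write_posture_csv(series: PostureSeries, path: Path) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["frame", "ratio", "posture"])
        for call in series.calls:
            writer.writerow([call.frame_index, repr(call.ratio), call.posture.value])
    return path


def write_comparison_csv(comparison: BudgetComparison, path: Path) -> Path:
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["category", "manual_percent", "model_percent", "difference"])
        for name, row in comparison.rounded_rows().items():
            writer.writerow([name, row[0], row[1], row[2]])
        writer.writerow(
            ["total_disagreement", "", "",
             round_half_up(comparison.total_disagreement, 1)]
        )
    return path


def format_budget_text(budget: TimeBudget, title: str) -> str:
    lines = [title, "-" * len(title)]
    rounded = budget.rounded()
    width = max(len(n) for n in budget.counts)
    for name, count in budget.counts.items():
        lines.append(f"{name:<{width}}  {count:>8d}  {rounded[name]:>6.1f}%")
    lines.append(f"{'total':<{width}}  {budget.total_frames:>8d}   100.0%")
    return "\n".join(lines)


def run_full_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every post-detection stage and write the report bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    logger.info("stage: read detections %s", cfg.detections_path)
    track = read_detections_csv(cfg.detections_path)

    logger.info("stage: confidence threshold tau=%s", cfg.tau)
    thresholded = apply_confidence_threshold(track, cfg.tau)
    files["thresholded_detections"] = write_detections_csv(
        thresholded, out / "thresholded_detections.csv"
    )

    logger.info("stage: raw time budget")
    raw_budget = budget_from_detections(thresholded)
    files["budget_raw"] = write_budget_csv(raw_budget, out / "budget_raw.csv")

    logger.info("stage: plateau filter")
    series = extract_coordinate_series(thresholded)
    runs = detect_plateaus(series, cfg.plateau)
    result = reclassify_false_positives(thresholded, runs)
    corr_budget = corrected_budget(result, raw_budget)
    files["plateau_report"] = write_plateau_report_csv(runs, out / "plateau_report.csv")
    files["corrected_detections"] = write_detections_csv(
        result.corrected_track, out / "corrected_detections.csv"
    )
    files["budget_corrected"] = write_budget_csv(
        corr_budget, out / "budget_corrected.csv"
    )

    logger.info("stage: posture series")
    postures = posture_series(thresholded, cfg.ratio)
    files["posture"] = write_posture_csv(postures, out / "posture.csv")

    comparison_raw = comparison_corrected = None
    if cfg.manual_path is not None:
        logger.info("stage: manual comparison %s", cfg.manual_path)
        coding = read_manual_csv(cfg.manual_path)
        manual_budget = budget_from_manual(coding)
        files["budget_manual"] = write_budget_csv(
            manual_budget, out / "budget_manual.csv"
        )
        comparison_raw = compare_budgets(manual_budget, raw_budget)
        comparison_corrected = compare_budgets(manual_budget, corr_budget)
        files["comparison_raw"] = write_comparison_csv(
            comparison_raw, out / "comparison_raw.csv"
        )
        files["comparison_corrected"] = write_comparison_csv(
            comparison_corrected, out / "comparison_corrected.csv"
        )

    files["config"] = _write_config_echo(cfg, out / "effective_config.yaml")
    files["summary"] = _write_summary(
        cfg, raw_budget, result, corr_budget, postures,
        comparison_raw, out / "summary.txt"
    )
    return RunReport(
        raw_budget=raw_budget,
        corrected=result,
        corrected_budget=corr_budget,
        postures=postures,
        comparison_raw=comparison_raw,
        comparison_corrected=comparison_corrected,
        files=files,
    )


def _write_config_echo(cfg: RunConfig, path: Path) -> Path:
    import yaml

    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# ethotrack {__version__} effective configuration\n")
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)
    return path


def _write_summary(cfg, raw_budget, result, corr_budget, postures,
                   comparison, path: Path) -> Path:
    lines = [
        f"ethotrack {__version__} pipeline summary",
        f"detections: {cfg.detections_path}",
        f"tau: {cfg.tau}",
        "",
        format_budget_text(raw_budget, "Model time budget (thresholded)"),
        "",
        format_budget_text(corr_budget, "Model time budget (Locomotion corrected)"),
        "",
        f"labeled fraction: {labeled_fraction(raw_budget)}%",
        f"plateau runs: {len(result.runs)}",
        f"false-positive Locomotion frames: {result.fp_count} "
        f"({round_half_up(result.fp_percent_of_total, 1)}% of session)",
        f"retained Locomotion: "
        f"{round_half_up(result.corrected_locomotion_percent, 1)}% of session",
        f"posture counts: "
        + ", ".join(f"{p.value}={c}" for p, c in postures.counts.items()),
    ]
    if comparison is not None:
        lines += [
            "",
            f"manual-vs-model total disagreement (detector categories): "
            f"{round_half_up(comparison.total_disagreement, 1)} percentage points",
        ]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


__all__ = ["RunConfig", "RunReport", "run_full_pipeline",
           "write_budget_csv", "write_plateau_report_csv",
           "write_posture_csv", "write_comparison_csv", "format_budget_text"]
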