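"""Replicate sweeps over angle / split / learning-rate / batch-size grids.

A sweep runs the full pipeline once per (condition, replicate seed), then
summarises each metric across conditions as mean +/- sample SD, the extremum
(maximum, or minimum for loss), and the condition achieving it - the same
shape as a hyperparameter-scan report table.  Replicates are averaged within
a condition before the across-condition statistics are taken.  Replicate
defaults follow the screening protocol: 3 replicates for angle and split
sweeps, 2 for learning-rate sweeps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import SplitRatio
from .evaluator import MetricsReport
from .molecule_prep import MoleculeRecord
from .pipeline import ExperimentConfig, run_experiment

logger = logging.getLogger(__name__)

AXES = ("angle", "split", "lr", "bs")

#: replicate counts per sweep axis (N=3 for angle/split, N=2 for lr)
DEFAULT_REPLICATES = {"angle": 3, "split": 3, "lr": 2, "bs": 2}

#: metrics whose reported extremum is the minimum
MINIMIZED_METRICS = {"loss"}

SUMMARY_METRICS = ("roc_auc", "pr_auc", "bac", "acc", "f", "mcc", "loss")


@dataclass(frozen=True)
class SweepCondition:
    axis: str
    value: object  # angle in degrees, "t:v:t" split, lr, or bs
    replicate_seeds: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ValueError(f"axis must be one of {AXES}, got {self.axis!r}")
        if len(self.replicate_seeds) < 1:
            raise ValueError("need at least one replicate seed")

    @property
    def name(self) -> str:
        return f"{self.axis}={self.value}"


@dataclass
class SweepResult:
    reports: dict[str, list[MetricsReport]]  # condition name -> replicates
    failures: dict[str, list[str]] = field(default_factory=dict)

    def summary(self) -> dict[str, dict]:
        return summarize_sweep(self.reports)


def make_grid(axis: str, values: Sequence[object],
              seeds: Sequence[int] | None = None) -> list[SweepCondition]:
    """Convenience constructor for a single-axis grid."""
    if seeds is None:
        seeds = tuple(range(DEFAULT_REPLICATES[axis]))
    return [SweepCondition(axis, v, tuple(seeds)) for v in values]


def _apply_condition(base: ExperimentConfig, cond: SweepCondition,
                     seed: int) -> ExperimentConfig:
    config = replace(base, seed=seed)
    if cond.axis == "angle":
        return replace(config, increment=float(cond.value))
    if cond.axis == "split":
        ratio = (cond.value if isinstance(cond.value, SplitRatio)
                 else SplitRatio.parse(str(cond.value)))
        return replace(config, ratio=ratio)
    if cond.axis == "lr":
        return replace(config, hp=replace(config.hp,
                                          learning_rate=float(cond.value)))
    return replace(config, hp=replace(config.hp, batch_size=int(cond.value)))


def _config_key(records: Sequence[MoleculeRecord], config: ExperimentConfig) -> str:
    payload = {
        "ids": [r.id for r in records],
        "increment": config.increment,
        "ratio": str(config.ratio),
        "hp": dataclasses.asdict(config.hp),
        "arch": config.arch,
        "seed": config.seed,
        "eval": config.eval_partition,
        "stratify": config.stratify,
    }
    blob = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_sweep(grid: Sequence[SweepCondition],
              records: Sequence[MoleculeRecord],
              base: ExperimentConfig | None = None,
              cache_dir: str | Path | None = None) -> SweepResult:
    """Execute the pipeline for every condition x replicate seed.

    Per-condition failures are recorded and do not abort the sweep; only a
    sweep in which *every* condition failed raises.  With ``cache_dir``,
    finished (condition, seed) reports are stored as JSON keyed on a config
    hash, making interrupted sweeps resumable.
    """
    if not grid:
        raise ValueError("sweep grid is empty")
    base = base or ExperimentConfig()
    result = SweepResult(reports={}, failures={})
    for cond in grid:
        for seed in cond.replicate_seeds:
            config = _apply_condition(base, cond, seed)
            report = None
            cache_file = None
            if cache_dir is not None:
                cache_file = Path(cache_dir) / f"{_config_key(records, config)}.json"
                if cache_file.exists():
                    report = _report_from_dict(json.loads(cache_file.read_text()))
            if report is None:
                try:
                    report = run_experiment(records, config).report
                except Exception as exc:
                    logger.warning("sweep condition %s seed %d failed: %s",
                                   cond.name, seed, exc)
                    result.failures.setdefault(cond.name, []).append(str(exc))
                    continue
                if cache_file is not None:
                    cache_file.parent.mkdir(parents=True, exist_ok=True)
                    cache_file.write_text(json.dumps(report.to_dict()))
            result.reports.setdefault(cond.name, []).append(report)
    if not result.reports:
        raise RuntimeError("every sweep condition failed")
    return result


def _report_from_dict(d: dict) -> MetricsReport:
    from .evaluator import ConfusionMatrix

    conf = ConfusionMatrix(**d.pop("confusion"))
    return MetricsReport(confusion=conf, **d)


def summarize_sweep(reports: dict[str, list[MetricsReport]]) -> dict[str, dict]:
    """Per-metric mean +/- SD across conditions, extremum, arg-extremum.

    Replicates are first averaged within each condition; the mean and sample
    (n-1) SD are then taken across condition means.  For loss the extremum
    is the minimum, for every other metric the maximum.
    """
    if not reports or not any(reports.values()):
        raise ValueError("no reports to summarize")
    condition_means: dict[str, dict[str, float]] = {}
    for name, reps in sorted(reports.items()):
        if not reps:
            continue
        condition_means[name] = {
            m: float(np.mean([getattr(r, m) for r in reps]))
            for m in SUMMARY_METRICS
        }
    out: dict[str, dict] = {}
    for metric in SUMMARY_METRICS:
        values = {name: means[metric] for name, means in condition_means.items()}
        arr = np.array(list(values.values()))
        minimize = metric in MINIMIZED_METRICS
        # iterate names in sorted order so ties resolve independently of
        # report insertion order
        chooser = min if minimize else max
        best_name = chooser(sorted(values), key=lambda n: values[n])
        out[metric] = {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            ("min" if minimize else "max"): values[best_name],
            "arg": best_name,
        }
    return out


def write_summary_tsv(summary: dict[str, dict], path: str | Path) -> None:
    """Emit the summary as a metric x {average, extremum, arg} TSV table."""
    lines = ["metric\taverage\tsd\textremum\targ_condition"]
    for metric, row in summary.items():
        ext_key = "min" if metric in MINIMIZED_METRICS else "max"
        lines.append(f"{metric}\t{row['mean']:.6g}\t{row['sd']:.6g}"
                     f"\t{row[ext_key]:.6g}\t{row['arg']}")
    Path(path).write_text("\n".join(lines) + "\n")
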