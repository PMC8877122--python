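"""End-to-end experiment: conformers -> snapshots -> split -> train -> evaluate.

One :func:`run_experiment` call is one experimental condition: it embeds the
library, captures snapshot images at the configured angle increment, splits
molecules (not images) into train/valid/test, trains the classifier, and
reports metrics on the requested partition.  All randomness flows from the
single ``seed`` in the config.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import SplitRatio, split_dataset
from .errors import EmbeddingError
from .evaluator import MetricsReport, evaluate
from .molecule_prep import MoleculeRecord, embed_3d
from .render import RenderStyle, SnapshotSet, load_snapshot, snapshot_molecule
from .trainer import (Hyperparams, TrainHistory, TrainedModel,
                      preprocess_images, train)

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    increment: float = 360.0
    ratio: SplitRatio = field(default_factory=lambda: SplitRatio(7, 1, 2))
    hp: Hyperparams = field(default_factory=Hyperparams)
    arch: str = "tinycnn"
    seed: int = 0
    style: RenderStyle = field(default_factory=RenderStyle)
    eval_partition: str = "test"
    stratify: bool = True


@dataclass
class ExperimentResult:
    report: MetricsReport
    history: TrainHistory
    model: TrainedModel
    splits: dict[str, list[MoleculeRecord]]
    snapshot_sets: list[SnapshotSet]


def snapshot_library(records: Sequence[MoleculeRecord], increment: float,
                     style: RenderStyle, outdir: str | Path,
                     seed: int = 0) -> list[SnapshotSet]:
    """Embed and snapshot every molecule; embedding failures are skipped."""
    outdir = Path(outdir)
    sets: list[SnapshotSet] = []
    for rec in records:
        try:
            conf = embed_3d(rec, seed=seed)
        except EmbeddingError as exc:
            logger.warning("snapshot_library: %s", exc)
            continue
        sets.append(snapshot_molecule(conf, increment, style, outdir))
    return sets


def _partition_arrays(snapshot_sets: Sequence[SnapshotSet],
                      mol_ids: set[str], labels: dict[str, int],
                      input_size: int) -> tuple[np.ndarray, np.ndarray]:
    images, y = [], []
    for sset in snapshot_sets:
        if sset.molecule_id not in mol_ids:
            continue
        for _, path in sset.items:
            images.append(load_snapshot(path))
            y.append(labels[sset.molecule_id])
    if not images:
        return np.empty((0, input_size, input_size, 3)), np.empty(0, dtype=int)
    return preprocess_images(images, input_size), np.asarray(y, dtype=int)


def run_experiment(records: Sequence[MoleculeRecord],
                   config: ExperimentConfig,
                   workdir: str | Path | None = None) -> ExperimentResult:
    """Run the full pipeline for one condition on a labeled library."""
    tmp = None
    if workdir is None:
        tmp = tempfile.TemporaryDirectory(prefix="snapqsar_")
        workdir = tmp.name
    workdir = Path(workdir)
    try:
        sets = snapshot_library(records, config.increment, config.style,
                                workdir / "imgs", seed=config.seed)
        rendered = {s.molecule_id for s in sets}
        usable = [r for r in records if r.id in rendered]
        splits = split_dataset(usable, config.ratio, seed=config.seed,
                               stratify=config.stratify)
        labels01 = {r.id: int(r.label == "active") for r in usable}

        x_tr, y_tr = _partition_arrays(sets, {r.id for r in splits["train"]},
                                       labels01, config.hp.input_size)
        x_va, y_va = _partition_arrays(sets, {r.id for r in splits["valid"]},
                                       labels01, config.hp.input_size)
        model, history = train(x_tr, y_tr, x_va, y_va, hp=config.hp,
                               arch=config.arch, seed=config.seed)

        part = splits[config.eval_partition]
        report = evaluate(model, sets, {r.id: r.label for r in usable},
                          partition_ids=[r.id for r in part])
        return ExperimentResult(report=report, history=history, model=model,
                                splits=splits, snapshot_sets=sets)
    finally:
        if tmp is not None:
            tmp.cleanup()
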