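"""Activity-score normalisation, labelling, assay summaries, and data splits.

Screening scores come from reporter-gene assays normalised per titration
point against the DMSO-only wells and the positive-control wells:

    % activity = (V_compound - V_dmso) / (V_pos - V_dmso) * 100

A compound is *active* when its 0-100 activity score is >= 40 and *inactive*
below 40.  Libraries of this kind are heavily imbalanced (roughly 1-5%
actives), so the train/valid/test split is stratified by label; the split is
keyed on molecule identifiers, not input order, and all snapshot images of a
molecule inherit its partition so that rotated views of one structure never
leak across partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateControlError
from .molecule_prep import MoleculeRecord

logger = logging.getLogger(__name__)

ACTIVE_THRESHOLD = 40.0  # score >= 40 -> active

PARTITIONS = ("train", "valid", "test")


@dataclass(frozen=True)
class WellMeasurement:
    """Raw reporter-assay well values for one compound titration point."""

    v_compound: float
    v_dmso: float  # median of the DMSO-only wells
    v_pos: float   # median of the positive-control wells


@dataclass(frozen=True)
class SplitRatio:
    train: int
    valid: int
    test: int

    def __post_init__(self) -> None:
        if min(self.train, self.valid, self.test) < 1:
            raise ValueError("split ratio parts must all be >= 1")

    @classmethod
    def parse(cls, text: str) -> "SplitRatio":
        parts = [int(p) for p in text.split(":")]
        if len(parts) != 3:
            raise ValueError(f"expected train:valid:test, got {text!r}")
        return cls(*parts)

    def __str__(self) -> str:
        return f"{self.train}:{self.valid}:{self.test}"


@dataclass(frozen=True)
class AssaySummary:
    n_total: int
    n_active: int
    n_inactive: int
    pct_active: float
    pct_inactive: float


def percent_activity(w: WellMeasurement) -> float:
    """Normalise a well value to the 0-100 %-activity scale."""
    if w.v_pos == w.v_dmso:
        raise DegenerateControlError(
            "positive-control and DMSO medians coincide; % activity undefined")
    return 100.0 * (w.v_compound - w.v_dmso) / (w.v_pos - w.v_dmso)


def label_activity(score: float) -> str:
    """Binary label from an activity score: active iff score >= 40."""
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"activity score must be in [0, 100], got {score}")
    return "active" if score >= ACTIVE_THRESHOLD else "inactive"


def label_records(records: Sequence[MoleculeRecord]) -> list[MoleculeRecord]:
    """Attach labels to all records that carry an activity score."""
    out = []
    for rec in records:
        if rec.activity_score is None:
            raise ValueError(f"record {rec.id} has no activity score")
        out.append(replace(rec, label=label_activity(rec.activity_score)))
    return out


def summarize_assay(records: Sequence[MoleculeRecord]) -> AssaySummary:
    """Active/inactive counts and percentages (2 decimals) for one assay."""
    labels = []
    for rec in records:
        if rec.label not in ("active", "inactive"):
            raise ValueError(f"record {rec.id} is unlabeled")
        labels.append(rec.label)
    n_total = len(labels)
    n_active = sum(1 for x in labels if x == "active")
    n_inactive = n_total - n_active
    pct_active = round(100.0 * n_active / n_total, 2) if n_total else 0.0
    pct_inactive = round(100.0 * n_inactive / n_total, 2) if n_total else 0.0
    return AssaySummary(n_total, n_active, n_inactive, pct_active, pct_inactive)


def cross_assay_stats(summaries: Sequence[AssaySummary]) -> dict[str, tuple[float, float]]:
    """Mean and sample (n-1) SD of totals, actives and %active across assays.

    Counts are rounded to integers and percentages to 2 decimals, the
    rounding used when such numbers are reported alongside assay tables.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 assay summaries")
    totals = np.array([s.n_total for s in summaries], dtype=float)
    actives = np.array([s.n_active for s in summaries], dtype=float)
    pcts = np.array([s.pct_active for s in summaries], dtype=float)

    def stat(values: np.ndarray, decimals: int | None) -> tuple[float, float]:
        mean = float(values.mean())
        sd = float(values.std(ddof=1))
        if decimals is None:
            return float(round(mean)), float(round(sd))
        return round(mean, decimals), round(sd, decimals)

    return {
        "n_total": stat(totals, None),
        "n_active": stat(actives, None),
        "pct_active": stat(pcts, 2),
    }


def _largest_remainder(total: int, weights: Sequence[int]) -> list[int]:
    """Apportion `total` proportionally to integer weights.

    Residue goes to the largest fractional remainders, ties broken in listed
    order (train before valid before test).
    """
    wsum = sum(weights)
    quotas = [total * w / wsum for w in weights]
    sizes = [int(np.floor(q)) for q in quotas]
    residue = total - sum(sizes)
    remainders = sorted(range(len(weights)),
                        key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in remainders[:residue]:
        sizes[i] += 1
    return sizes


def split_dataset(records: Sequence[MoleculeRecord], ratio: SplitRatio,
                  seed: int, stratify: bool = True,
                  fixed_test_ids: Iterable[str] | None = None,
                  ) -> dict[str, list[MoleculeRecord]]:
    """Partition molecules into train/valid/test at the given ratio.

    The assignment is a function of the molecule ids and the seed only, so
    permuting the input order does not change any molecule's partition.  With
    ``stratify`` (default) actives and inactives are apportioned separately
    by the largest-remainder rule, keeping every partition's active fraction
    within one molecule of the global fraction.

    ``fixed_test_ids`` pins a previously drawn foldout test set: those
    molecules go to ``test`` verbatim and only train/valid are re-split from
    the remainder, so the held-out evaluation set never moves between ratio
    changes.
    """
    n = len(records)
    if n < ratio.train + ratio.valid + ratio.test:
        raise ValueError(f"{n} records cannot fill ratio {ratio}")
    by_id = {rec.id: rec for rec in records}
    if len(by_id) != n:
        raise ValueError("molecule ids must be unique for splitting")

    result: dict[str, list[MoleculeRecord]] = {p: [] for p in PARTITIONS}
    pool = sorted(by_id)  # id-keyed determinism
    weights = [ratio.train, ratio.valid, ratio.test]
    parts: list[str] = list(PARTITIONS)

    if fixed_test_ids is not None:
        fixed = sorted(set(fixed_test_ids))
        unknown = [i for i in fixed if i not in by_id]
        if unknown:
            raise ValueError(f"fixed test ids not in library: {unknown[:5]}")
        result["test"] = [by_id[i] for i in fixed]
        pool = [i for i in pool if i not in set(fixed)]
        weights = weights[:2]
        parts = ["train", "valid"]

    rng = np.random.default_rng(seed)
    sizes = _largest_remainder(len(pool), weights)

    if stratify:
        groups = {
            "active": [i for i in pool if by_id[i].label == "active"],
            "inactive": [i for i in pool if by_id[i].label != "active"],
        }
        n_pool = len(pool)
        # per-partition active quota by largest remainder on the active count
        active_sizes = _largest_remainder(
            len(groups["active"]),
            sizes if sum(sizes) else weights,
        ) if n_pool else [0] * len(parts)
        for cls, ids in groups.items():
            ids = list(ids)
            rng.shuffle(ids)
            if cls == "active":
                cls_sizes = active_sizes
            else:
                cls_sizes = [sizes[k] - active_sizes[k] for k in range(len(parts))]
            start = 0
            for part, cnt in zip(parts, cls_sizes):
                result[part].extend(by_id[i] for i in ids[start:start + cnt])
                start += cnt
    else:
        ids = list(pool)
        rng.shuffle(ids)
        start = 0
        for part, cnt in zip(parts, sizes):
            result[part].extend(by_id[i] for i in ids[start:start + cnt])
            start += cnt

    for part in parts:
        labels = {r.label for r in result[part]}
        for cls in ("active", "inactive"):
            if result[part] and cls not in labels:
                logger.warning("split: partition %r received no %s molecules",
                               part, cls)
    # stable output order within each partition
    for part in result:
        result[part].sort(key=lambda r: r.id)
    return result


def write_manifest(splits: dict[str, list[MoleculeRecord]],
                   path: str | Path) -> None:
    """Write a (molecule id, partition) TSV manifest."""
    lines = ["id\tpartition"]
    for part in PARTITIONS:
        for rec in splits.get(part, []):
            lines.append(f"{rec.id}\t{part}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a split manifest back as an id -> partition map."""
    out: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        mol_id, part = line.split("\t")
        out[mol_id] = part
    return out
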