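"""Participant-level train/validation partitioning.

All images from one participant land in exactly one subset; splitting by
image would leak near-identical frames of the same wrist into both sets
and inflate validation accuracy.  The split is stratified by class: per
class, round(ratio * n_class) participants go to training, with
round-half-away-from-zero rounding (the convention that yields 13 of 19
and 15 of 21 training participants at a 70% ratio).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic import LABELS, CohortDataset

__all__ = [
    "SplitPlan",
    "SplitIntegrityError",
    "round_half_away",
    "split_cohort",
    "verify_no_leakage",
    "planned_counts",
]

SUBSETS = ("train", "validation")


class SplitIntegrityError(ValueError):
    """A split plan refers to ids absent from the dataset."""


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (0.5 -> 1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -round_half_away(-x)


@dataclass
class SplitPlan:
    """Disjoint participant assignment plus the per-image materialization.

    ``image_subsets`` maps (participant_id, frame_index) to its subset; it
    is derived from the participant sets but stored explicitly so that
    integrity checks can detect a corrupted (image-level) assignment.
    """

    train_participants: frozenset[str]
    validation_participants: frozenset[str]
    ratio: float
    seed: int
    image_subsets: dict[tuple[str, int], str] = field(default_factory=dict)

    def subset_of(self, participant_id: str) -> str:
        if participant_id in self.train_participants:
            return "train"
        if participant_id in self.validation_participants:
            return "validation"
        raise SplitIntegrityError(f"unknown participant id: {participant_id}")

    def counts(self, dataset: CohortDataset) -> dict[str, int]:
        """Image counts per subset under this plan."""
        out = {s: 0 for s in SUBSETS}
        for p in dataset:
            out[self.subset_of(p.participant_id)] += p.n_items
        return out


def split_cohort(dataset: CohortDataset, ratio: float = 0.70, seed: int = 0) -> SplitPlan:
    """Stratified participant-level split; selection uniform at random by seed."""
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must be in [0, 1]")
    by_label: dict[str, list[str]] = {lab: [] for lab in LABELS}
    for p in dataset:
        by_label[p.label].append(p.participant_id)
    for lab, ids in by_label.items():
        if 0 < len(ids) < 2:
            raise ValueError(f"class '{lab}' needs at least 2 participants to split")

    rng = np.random.default_rng(seed)
    train: set[str] = set()
    for lab in LABELS:  # fixed label order keeps the draw reproducible
        ids = sorted(by_label[lab])
        n_train = round_half_away(ratio * len(ids))
        chosen = rng.choice(len(ids), size=n_train, replace=False) if ids else []
        train.update(ids[i] for i in chosen)

    validation = set(dataset.participant_ids) - train
    plan = SplitPlan(frozenset(train), frozenset(validation), ratio, seed)
    for p in dataset:
        subset = "train" if p.participant_id in train else "validation"
        for idx, item in enumerate(p.items):
            frame_index = getattr(item, "frame_index", idx)
            plan.image_subsets[(p.participant_id, frame_index)] = subset
    return plan


def verify_no_leakage(plan: SplitPlan, dataset: CohortDataset) -> bool:
    """True iff every participant's images fall entirely in one subset.

    Checks the materialized image assignment against the participant sets,
    so a plan corrupted at the image level is detected.  Ids in the plan
    that are absent from the dataset raise :class:`SplitIntegrityError`.
    """
    known = set(dataset.participant_ids)
    for pid in plan.train_participants | plan.validation_participants:
        if pid not in known:
            raise SplitIntegrityError(f"plan references unknown participant: {pid}")
    if plan.train_participants & plan.validation_participants:
        return False
    for (pid, _), subset in plan.image_subsets.items():
        if pid not in known:
            raise SplitIntegrityError(f"plan references unknown participant: {pid}")
        if subset != plan.subset_of(pid):
            return False
    return True


def planned_counts(
    n_fracture: int, n_sprain: int, frames_per_participant: int, ratio: float = 0.70
) -> dict[str, dict[str, int]]:
    """Configuration-driven image accounting for a stratified split.

    Pure arithmetic (participants x frames); useful for verifying a plan's
    bookkeeping without generating pixels.
    """
    out: dict[str, dict[str, int]] = {"train": {}, "validation": {}}
    for lab, n in (("fracture", n_fracture), ("sprain", n_sprain)):
        k = round_half_away(ratio * n)
        out["train"][lab] = k * frames_per_participant
        out["validation"][lab] = (n - k) * frames_per_participant
    for subset in out:
        out[subset]["total"] = sum(out[subset].values())
    return out


def write_split_manifest(plan: SplitPlan, dataset: CohortDataset, path: str | Path) -> None:
    """CSV: participant_id, label, subset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "label", "subset"])
        for p in dataset:
            writer.writerow([p.participant_id, p.label, plan.subset_of(p.participant_id)])
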