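"""Minority-class oversampling by window slicing.

Distressed recordings are roughly four times rarer than normal ones, so the
distressed class is oversampled by slicing: in addition to the base
labor-stage window, two further windows of the same length are taken with
their start shifted backward (toward earlier time) by five minutes each.
For stage 1 the base window is anchored so that all shifted windows stay
inside the recording (starts at 2·shift, shifting down toward sample 0);
for stage 2 the base window is the final one and shifts move its start
earlier.  Each slice is an exact contiguous sub-window of the cleaned
signal — no samples are ever fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DatasetError, SegmentTooShortError
from .preprocess import FHRSignal, Segment, Stage, clean
from .record_io import ClassLabel, CTGRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SlicePlan:
    """How the minority class is oversampled."""

    shift_seconds: float = 300.0
    n_slices: int = 2

    def __post_init__(self) -> None:
        if self.n_slices < 0 or self.shift_seconds <= 0:
            raise ValueError("n_slices must be >= 0 and shift_seconds > 0")

    @property
    def multiplier(self) -> int:
        """Segments produced per source signal: the base window plus slices."""
        return 1 + self.n_slices


def slice_offsets(
    signal_length: int, stage: Stage, fs: float, plan: SlicePlan
) -> list[int]:
    """Start indices of the base window and its backward-shifted slices.

    Offsets that would fall outside the signal are dropped (never padded);
    the returned list is ordered base first, most-shifted last.
    """
    window = stage.window_samples(fs)
    shift = int(round(plan.shift_seconds * fs))
    if stage is Stage.STAGE1:
        base = plan.n_slices * shift
        candidates = [base - k * shift for k in range(plan.n_slices + 1)]
    else:
        base = signal_length - window
        candidates = [base - k * shift for k in range(plan.n_slices + 1)]
    return [o for o in candidates if 0 <= o and o + window <= signal_length]


def slice_augment(
    signal: FHRSignal,
    stage: Stage,
    plan: SlicePlan = SlicePlan(),
    record_id: str = "",
) -> list[Segment]:
    """Cut the base window plus ``plan.n_slices`` backward-shifted copies."""
    window = stage.window_samples(signal.fs)
    if len(signal) < window:
        raise SegmentTooShortError(
            f"signal of {len(signal)} samples shorter than {window}-sample window"
        )
    offsets = slice_offsets(len(signal), stage, signal.fs, plan)
    if len(offsets) < plan.multiplier:
        logger.warning(
            "record %s: signal of %d samples fits only %d of %d slices",
            record_id, len(signal), len(offsets), plan.multiplier,
        )
    return [
        Segment(
            signal.samples[o : o + window],
            stage=stage,
            record_id=record_id,
            start_index=o,
            fs=signal.fs,
        )
        for o in offsets
    ]


@dataclass
class DatasetItem:
    item_id: str
    record_id: str
    stage: Stage
    offset: int
    label: ClassLabel
    segment: Segment | None = None


@dataclass
class LabeledDataset:
    """Labeled segments ready for time-frequency conversion."""

    items: list[DatasetItem] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_normal, n_distressed)."""
        n_d = sum(1 for it in self.items if it.label is ClassLabel.DISTRESSED)
        return len(self.items) - n_d, n_d

    def labels(self) -> list[ClassLabel]:
        return [it.label for it in self.items]


def expected_counts(
    n_normal: int,
    n_distressed: int,
    plan: SlicePlan = SlicePlan(),
    n_experiments: int = 1,
) -> tuple[int, int]:
    """Dataset size law: normal records contribute one segment per experiment,
    distressed records ``1 + n_slices``; returns (n_normal_items, n_distressed_items)."""
    return (
        n_normal * n_experiments,
        n_distressed * plan.multiplier * n_experiments,
    )


def build_dataset(
    records: Iterable[tuple[CTGRecord, ClassLabel]],
    stage: Stage,
    augment_minority: bool = True,
    plan: SlicePlan = SlicePlan(),
) -> LabeledDataset:
    """Clean each record and collect labeled segments for one labor stage.

    Normal records contribute their single stage window; distressed records
    are slice-augmented when ``augment_minority`` is on.  Records whose
    cleaned signal is too short for the window are skipped with a warning.
    """
    items: list[DatasetItem] = []
    for record, label in records:
        try:
            sig = clean(record)
        except Exception as exc:  # cleaning failures skip the record
            logger.warning("record %s skipped: %s", record.record_id, exc)
            continue
        use_plan = (
            plan
            if (augment_minority and label is ClassLabel.DISTRESSED)
            else SlicePlan(shift_seconds=plan.shift_seconds, n_slices=0)
        )
        try:
            segments = slice_augment(sig, stage, use_plan, record.record_id)
        except SegmentTooShortError as exc:
            logger.warning("record %s skipped: %s", record.record_id, exc)
            continue
        for seg in segments:
            items.append(
                DatasetItem(
                    item_id=f"{record.record_id}_s{stage.value}_o{seg.start_index}",
                    record_id=record.record_id,
                    stage=stage,
                    offset=seg.start_index,
                    label=label,
                    segment=seg,
                )
            )
    ds = LabeledDataset(items)
    n_norm, n_dist = ds.class_counts
    if n_norm == 0 or n_dist == 0:
        raise DatasetError(
            f"degenerate dataset: class counts ({n_norm}, {n_dist})"
        )
    return ds


def write_manifest(dataset: LabeledDataset, path) -> None:
    """TSV manifest of (item_id, record_id, stage, offset, label)."""
    with open(path, "w") as fh:
        fh.write("item_id\trecord_id\tstage\toffset\tlabel\n")
        for it in dataset.items:
            fh.write(
                f"{it.item_id}\t{it.record_id}\t{it.stage.value}"
                f"\t{it.offset}\t{it.label.value}\n"
            )
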