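"""End-to-end experiment driver: records -> scalograms -> classifier -> metrics.

Glues the stages together the way the two labor-stage experiments are run:
clean and segment every labeled record, slice-augment the distressed class,
convert each segment to a Morse scalogram image, split per class, train the
softmax head on backbone features, and evaluate on the held-out test items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .augment import LabeledDataset, SlicePlan, build_dataset
from .classify import (
    Backbone,
    ConfusionMatrix,
    Metrics,
    SplitIndices,
    TrainConfig,
    TrainedModel,
    evaluate,
    metrics,
    stratified_split,
    train_classifier,
)
from .morse import MorseParams, build_filterbank, cwt, render_scalogram
from .preprocess import Stage
from .record_io import ClassLabel, CTGRecord

logger = logging.getLogger(__name__)


def dataset_images(
    dataset: LabeledDataset,
    params: MorseParams = MorseParams(),
    image_size: tuple[int, int] = (224, 224),
    colormap: str = "jet",
    voices_per_octave: int = 12,
) -> np.ndarray:
    """Render every segment of a dataset to a scalogram image (n, H, W, 3)."""
    banks: dict[int, object] = {}
    images = []
    for it in dataset.items:
        seg = it.segment
        if seg is None:
            raise ValueError(f"item {it.item_id} carries no segment samples")
        n = len(seg)
        if n not in banks:
            banks[n] = build_filterbank(
                n, seg.fs, params, voices_per_octave=voices_per_octave
            )
        scal = cwt(seg, banks[n])
        images.append(render_scalogram(scal, size=image_size, colormap=colormap))
    return np.stack(images)


@dataclass
class ExperimentResult:
    stage: Stage
    split: SplitIndices
    model: TrainedModel
    confusion: ConfusionMatrix
    metrics: Metrics
    dataset: LabeledDataset


def run_experiment(
    records: list[tuple[CTGRecord, ClassLabel]],
    stage: Stage,
    params: MorseParams = MorseParams(),
    plan: SlicePlan = SlicePlan(),
    train_config: TrainConfig = TrainConfig(),
    backbone: Backbone | None = None,
    split_seed: int = 0,
    split_by_record: bool = False,
    image_size: tuple[int, int] = (224, 224),
) -> ExperimentResult:
    """Run one labor-stage experiment end to end on labeled records."""
    dataset = build_dataset(records, stage, augment_minority=True, plan=plan)
    images = dataset_images(dataset, params, image_size=image_size)
    split = stratified_split(
        dataset, seed=split_seed, by_record=split_by_record
    )
    by_id = {it.item_id: i for i, it in enumerate(dataset.items)}
    labels = dataset.labels()

    def subset(ids: list[str]):
        idx = [by_id[i] for i in ids]
        return images[idx], [labels[i] for i in idx]

    X_train, y_train = subset(split.train)
    X_val, y_val = subset(split.validation)
    X_test, y_test = subset(split.test)
    model = train_classifier(
        X_train, y_train, train_config, backbone,
        val_images=X_val if len(X_val) else None,
        val_labels=y_val if len(y_val) else None,
    )
    cm = evaluate(model, X_test, y_test)
    result = ExperimentResult(
        stage=stage,
        split=split,
        model=model,
        confusion=cm,
        metrics=metrics(cm),
        dataset=dataset,
    )
    logger.info(
        "stage %s: confusion (tp=%d fn=%d fp=%d tn=%d) metrics %s",
        stage.name, cm.tp, cm.fn, cm.fp, cm.tn, result.metrics,
    )
    return result
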