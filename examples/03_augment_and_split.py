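"""Slicing augmentation and stratified splitting arithmetic.

Reproduces the dataset bookkeeping of a 439 normal / 113 distressed cohort:
x3 oversampling of the distressed class by backward window slicing over two
labor-stage experiments, then a per-class 10% holdout.
"""

from ctgmorse import SlicePlan, Stage, expected_counts, slice_offsets, stratified_split
from ctgmorse.augment import DatasetItem, LabeledDataset
from ctgmorse.record_io import ClassLabel

plan = SlicePlan()  # 5-min backward shift, twice
print(f"slice plan: shift {plan.shift_seconds:.0f}s x {plan.n_slices} "
      f"-> {plan.multiplier} windows per distressed record")
print(f"stage-1 window starts for a 30-min signal: "
      f"{slice_offsets(7200, Stage.STAGE1, 4.0, plan)} (samples)")

n_norm, n_dist = expected_counts(439, 113, plan, n_experiments=2)
print(f"\ndataset: {n_norm} normal + {n_dist} distressed = {n_norm + n_dist} images")

items = [DatasetItem(f"n{i}", f"rn{i}", Stage.STAGE1, 0, ClassLabel.NORMAL)
         for i in range(n_norm)]
items += [DatasetItem(f"d{i}", f"rd{i // 3}", Stage.STAGE1, 0, ClassLabel.DISTRESSED)
          for i in range(n_dist)]
split = stratified_split(LabeledDataset(items), test_frac=0.10, seed=0)
n_test_norm = sum(1 for i in split.test if i.startswith("n"))
print(f"10% per-class holdout: {len(split.test)} test items "
      f"({n_test_norm} normal, {len(split.test) - n_test_norm} distressed)")
print(f"training pool: {len(split.train) + len(split.validation)} items "
      f"(validation carved from it during training)")
# Expected output: 1556 images (878/678), 156 test items (88/68), 1400 pool.
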