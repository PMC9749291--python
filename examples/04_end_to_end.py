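"""End-to-end fetal-distress classification on a synthetic cohort.

Simulates 40 normal + 10 distressed recordings with a strong distress
signature, runs cleaning -> slicing augmentation -> Morse scalograms ->
record-grouped stratified split -> classifier training -> evaluation, and
prints the confusion matrix with accuracy / sensitivity / specificity.
"""

from ctgmorse import FHRSimConfig, Stage, TrainConfig, run_experiment, simulate_cohort

cohort = simulate_cohort(40, 10, FHRSimConfig(seed=23, class_separation=1.0))
records = [(rec, label) for rec, label, _ in cohort]

result = run_experiment(
    records,
    Stage.STAGE1,
    train_config=TrainConfig(max_epochs=15, seed=20210000),
    split_seed=0,
    split_by_record=True,   # augmented slices never span train and test
)

n_norm, n_dist = result.dataset.class_counts
print(f"dataset: {n_norm} normal + {n_dist} distressed segments")
print(f"split: {len(result.split.train)} train / "
      f"{len(result.split.validation)} validation / {len(result.split.test)} test")

cm = result.confusion
print(f"\nconfusion matrix (distressed positive): "
      f"tp={cm.tp} fn={cm.fn} fp={cm.fp} tn={cm.tn}")
m = result.metrics
print(f"accuracy {m.accuracy}%  sensitivity {m.sensitivity}%  "
      f"specificity {m.specificity}%")
# With a strong distress signature (lower baseline, reduced variability,
# recurrent decelerations) the scalogram classifier separates the classes
# near-perfectly; sensitivity is the fraction of distressed test segments
# correctly flagged.
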