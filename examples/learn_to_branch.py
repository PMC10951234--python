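"""Recover planted subject groups with the learn-to-branch layer.

Generates a cohort of 12 subjects in three planted groups that differ in
how behavior maps to stress, fits the branched model (Gumbel-softmax
selection with temperature annealing, head warmup, and random restarts),
and compares the learned branch assignment to the ground truth with the
adjusted Rand index.

Takes a few minutes on one CPU core: the restart procedure trains several
candidate models.  Recovery is reliable but not certain — restarts land
in a wrong grouping roughly one time in three, and the restart selector
usually, not always, picks a correct one.
"""

from sklearn.metrics import adjusted_rand_score

from stresslearn import (
    BackboneConfig,
    CohortSpec,
    TrainConfig,
    cohort_to_dataset,
    fit_branched,
    generate_cohort,
)

spec = CohortSpec(n_subjects=12, n_groups=3, days_per_subject=60,
                  delta=8.0, seed=1)
cohort = generate_cohort(spec)
ds = cohort_to_dataset(cohort)

model, info = fit_branched(
    ds, n_branches=3,
    config=BackboneConfig(latent_dim=32, shared_width=32, head_hidden=8),
    cfg=TrainConfig(epochs=50), seed=0,
)

groups = model.groups()
subjects = ds.subject_list
ari = adjusted_rand_score([cohort.group_of[s] for s in subjects],
                          [groups[s] for s in subjects])
print("subject  planted  learned")
for s in subjects:
    print(f"{s:8s} {cohort.group_of[s]:7d} {groups[s]:8d}")
print(f"\nadjusted Rand index vs planted groups: {ari:.2f} "
      "(1.0 = perfect recovery, ~0 = chance)")
print("restart selection scores (training CE at end of warmup):",
      {k: round(v, 3) for k, v in info["warmup_scores"].items()})
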