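"""Group subjects by psychological survey scores (the clustered baseline).

Density-based clustering (DBSCAN) on standardized survey rows; groups are
used as shared output heads.  Also shows cold-start group assignment of a
new subject by nearest centroid.
"""

import numpy as np

from stresslearn import CohortSpec, assign_new_subject, cluster_surveys, generate_cohort
from stresslearn.preprocess import SurveyScores

cohort = generate_cohort(CohortSpec(n_subjects=12, n_groups=3,
                                    days_per_subject=5, seed=2))
scores = SurveyScores.from_frame(cohort.surveys)
plan = cluster_surveys(scores)

print("DBSCAN params:", plan.params)
print(plan.to_frame().to_string(index=False))
print(f"groups: {plan.n_groups}, mean size {plan.mean_group_size():.1f} "
      "(target: 3-4 subjects per group)")

newcomer = scores.S.mean(axis=0) + np.array([1, 0, 0, 0, 0, 0.5])
print("new subject assigned to group:",
      assign_new_subject(plan, scores, newcomer))
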