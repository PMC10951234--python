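# Default run configuration for the stresslearn CLI.
# A run is fully reproducible from this file plus --seed.

cohort:                 # synthetic-cohort generator (simulate command)
  n_subjects: 12
  n_groups: 3           # planted stress-response groups
  days_per_subject: 60
  delta: 3.0            # group effect size on the stress response
  subject_offset_scale: 0.8
  label_noise: 0.6
  missing_day_prob: 0.05

backbone:
  latent_dim: 128       # encoder last-hidden-state width (the latent)
  shared_width: 64      # shared fully connected layer after latent + covariates
  head_hidden: 32       # hidden width of each 2-layer subject head

train:
  epochs: 50
  batch_size: 32
  lr: 1.0e-3
  branch_lr: 2.0e-2     # faster clock for branch-selection logits
  tau0: 5.0             # Gumbel-softmax temperature: linear decay tau0 -> tau_min
  tau_min: 0.1
  # loss weights: reconstruction alpha=1e-4, personal CE beta=1,
  # generic CE lambda defaults to 1/(number of training subjects)

n_branches: 4           # branched model: ceil(12 subjects / 3)
fine_tune_epochs: 5     # online-learning increments
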