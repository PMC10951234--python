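# Methods

## Problem

Daily stress self-reports (EMA, 1–5) are predicted from passively sensed
smartphone streams: activity and audio inference classes, conversation,
phone-charge and phone-lock events. The streams are irregular — thousands
of timestamped events per day at no fixed rate — and subjects differ both
in their baseline stress and in *how* behavior maps to stress, which is
what personalization and subject grouping address.

## Featurization

Each channel-day is binned into 1440 one-minute slots. `sum` channels
(conversation, charge, lock) accumulate event counts per minute; `mode`
channels (activity, audio, values 0–3) record the modal class among that
minute's events. Unobserved minutes are imputed per channel: zero fill for
activity/audio, forward fill for conversation/charge, forward fill with
mean-imputed leading gaps for phone lock. Each of the 24 hours is then
summarized by the histogram of its 60 minute-values, normalized to
proportions, giving a day tensor X ∈ R^{C×24×Ĥ}.

The histogram bin count Ĥ = 4 for all channels: the categorical channels
use their four classes as bins; the count channels use bins 0, 1, 2, ≥3
events/minute. A uniform Ĥ keeps the channel stack rectangular. Day-level
covariates (day-of-week one-hot, exam-period flag, time-to-deadline, sleep
rating, sleep duration) are carried alongside the tensor, not inside it.

Raw labels collapse as {1,2}→below-median, {3}→median, {4,5}→above-median.
Binary stress detection is served by training on the 3 classes and merging
the median and above-median probabilities — training with the finer labels
and merging outputs beats direct binary training. Subjects are retained
when they have strictly more than 35 and strictly fewer than 150 labeled
days (both bounds exclusive).

## Model

A one-layer LSTM encoder reads the 24 flattened histogram steps; its last
hidden state (width 128 by default) is the latent. A one-layer LSTM
decoder reconstructs the input sequence from the encoder's hidden states;
the mean absolute reconstruction error (RE) acts as a denoising
regularizer. The latent, concatenated with the covariates, passes through
a shared ReLU layer (width 64) and then a two-layer MLP head per subject
(hidden 32, ReLU; linear output to 3 logits, softmax outside). A generic
head of the same shape is trained on everyone and serves subjects with no
data. The loss is

    L = α·RE + β·CE_personal + λ·CE_generic

with α = 1e-4, β = 1, and λ = 1/(number of training subjects) — the
generic head sees every batch, so its weight is scaled down accordingly.
CE is computed from logits with log-sum-exp; the public prediction
contract is softmax probabilities.

Optimization is Adam (lr 1e-3, batch 32), chosen as standard practice for
models of this size; epochs are configuration. Training is deterministic
given the seed.

## Learn-to-branch

K branch nodes (single ReLU layers, width equal to the shared layer) sit
between the shared layer and the heads. Subject j's head consumes
B^T·softmax((log θ_j + ε)/τ) during training (ε i.i.d. Gumbel(0,1), fresh
per example) and the argmax branch at evaluation. θ starts uniform
(all-zero logits); τ decays linearly from 5.0 to 0.1 across training, so
the mixture weights used by the network approach one-hot vectors —
convergence is reported as the per-subject max of softmax(logits/τ) at the
final temperature, i.e. the weights the forward pass actually uses.
Subjects sharing an argmax branch form a learned group. K defaults to
⌈N/3⌉ (3–4 subjects per group works best in practice). The selection
logits get a faster learning rate (2e-2) than the rest of the network.

Three training-schedule choices matter, all adopted after studying the
optimization behavior on synthetic cohorts:

* **Common head initialization.** All personal heads start as copies of
  the generic head, so early between-subject loss differences are carried
  by the branch routing rather than by divergent head initializations.
* **Head warmup.** For the first 80% of epochs the personal heads'
  weights are frozen (their output bias stays free and absorbs
  per-subject base rates). Without this, the heads absorb the
  group-specific response themselves and the routing gradient dies before
  branches specialize.
* **Random restarts.** The branch-assignment landscape has locally stable
  "compromise" configurations where two true groups share a branch; which
  basin a run reaches depends on initialization, essentially a random
  allocation of groups to branches. As with k-means `n_init`, `fit_branched`
  trains several restarts (default 8), advances all of them to a probe
  point, finishes the best few, and keeps the run with the lowest
  training classification error under hard routing — correct groupings
  fit distinctly better than compromises, which makes the score a
  reliable selector.

Cold start: with zero data, predictions come from the generic head
(bypassing branches entirely). When a subject's first data arrives, a new
uniform θ column and a head initialized from the generic head are created
and fine-tuned.

## Baselines

*Pooled*: the same backbone with exactly one head for all subjects.
*Clustered*: heads shared within groups obtained by DBSCAN on
standardized survey scores (PHQ-9, PSS, Loneliness, Flourishing, PANAS,
Big Five aggregate); noise points become singleton groups, and the
parameter grid targets a mean cluster size of 3–4 where attainable.
Groups are named after their lexicographically first member, so a plan of
singletons reproduces the personalized model exactly (verified
bit-for-bit). New subjects are assigned to the nearest cluster centroid
in standardized survey space.

## Evaluation

Three schemas: stratified five-fold (per subject × label cell, round-robin
after a seeded shuffle), chronological five-fold (per-subject contiguous
blocks, each block tests once), and leave-one-subject-out with weekly
online learning (weeks are 7-day blocks anchored at the subject's first
observation; increment k = 0 is the pure cold start; later increments
fine-tune the running model for a fixed number of epochs — retraining
from scratch is available by flag).

Metrics are micro-averaged over the label-indicator matrix: micro-F1
(equal to accuracy for single-label multiclass predictions — both facts
are asserted in the tests), micro ROC AUC, PR AUC via average precision
(step interpolation, no trapezoids), and precision at recall ≥ 0.9,
operationalized as the precision at the *largest* threshold whose recall
still reaches 0.9 (the most conservative qualifying operating point).
Binary metrics always come from merged 3-class probabilities. All four
metrics are checked against brute-force enumeration oracles on a
randomized battery of small instances.

## Synthetic cohorts

The generator emulates the shape of a student passive-sensing study
without reproducing any real dataset. Per subject: a planted group g and
a persistent Gaussian baseline offset. Per day: channel intensities drawn
around piecewise-constant diurnal profiles (six 4-hour segments), events
emitted minute-wise (categorical draws for activity/audio, Poisson counts
for binary channels); the latent stress score is
δ·(w_g·z) + offset + noise, where z is the day's standardized behavior
summary and w_g is a group-specific unit weight vector. Raw labels cut
the latent score at cohort quantiles (0.10, 0.35, 0.70, 0.90), echoing
the below/median/above imbalance of real stress EMA. Surveys are group
centroids plus noise. δ = 0 removes all group structure from the stress
response (the null model); the default δ = 3 is a moderate regime, and
δ = 8 is the high-separation ("easy") regime used for group-recovery
experiments. A Bayes-rate classifier built from the true generative
parameters provides an upper bound no trained model should beat.

What the generator does *not* emulate: sensor dropout correlated with
behavior, label autocorrelation across days, non-stationary habits,
location or raw audio structure. Passing tests therefore demonstrate that
the pipeline recovers structure the generator plants, not performance on
real cohorts.

## Problem sizes

Experiments and tests run on cohorts of 4–12 subjects with 14–60 days and
a reduced backbone (latent 16–32, shared 32, heads 8–16), sizes at which
the numpy implementation trains a model in seconds to a few minutes on one
CPU core. Group-recovery and convergence experiments use the 12-subject,
3-group, 60-day cohort at δ = 8 with the full 50-epoch schedule;
personalization-benefit comparisons use an 8-subject cohort with strong
subject offsets (scale 2.0), the regime where per-subject heads matter by
construction; cold-start curves use a 6-subject, 5-week cohort. The
published defaults (latent 128, shared 64, heads 32) remain the model's
defaults.

## Numerical and degenerate-input choices

Histogram rows of fully imputed series always sum to 1 (asserted to
1e-9). An all-unobserved series under forward-fill-then-mean fills with 0
and logs a warning. Argmax ties in hard branch selection break to the
lowest index. Softmax and CE use max-shift / log-sum-exp stabilization.
AUCs on single-class inputs return NaN with a warning rather than a
value. The autodiff engine is float64 throughout; gradients of every
composite operation are verified against central finite differences.

## Known limitations

Branched-model group recovery is reliable only with restarts; single runs
land in compromise basins roughly two times in three even at high group
separation. The restart selector needs the training CE gap between
correct and compromise groupings to be visible, and that gap can fall
below training noise — between a perfect and a one-merge-off grouping the
selection score sometimes differs by less than 0.002 nats, so even the
restart procedure occasionally returns an imperfect grouping.

At δ = 0 any single small cohort can show accidental alignment between
per-subject baseline offsets and the (independent) planted groups; the
branch layer then groups by baseline and spuriously "recovers" groups.
Null-regime statements are therefore evaluated as expectations over
several fresh cohort draws, never on one cohort.
The LSTM backbone is the only encoder implemented; the config's
`backbone_kind` exists so a different sequence encoder can be added
without touching the heads, branching, or evaluation layers.
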