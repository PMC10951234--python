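"""Learn-to-branch: differentiable grouping of subjects between the shared
layer and the personal heads.

K branch nodes sit after the shared layer.  Which branch output a subject's
personal head consumes is governed by selection weights theta (one
categorical distribution per subject, stored as logits).  During training
the hard argmax selection is relaxed with the Gumbel-softmax trick,

    d_j = B^T softmax((log theta_j + eps) / tau),    eps ~ Gumbel(0,1),

and the temperature tau is annealed linearly across epochs so the mixture
weights approach one-hot vectors; at evaluation time the branch with the
largest selection weight is taken outright.  Subjects that settle on the
same branch form a learned group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Head, StressModel, BackboneConfig
from .nn import Linear, Tensor, softmax, take_columns

__all__ = [
    "BranchWeights",
    "TemperatureSchedule",
    "gumbel_noise",
    "soft_branch_combine",
    "hard_branch_select",
    "anneal",
    "extract_groups",
    "default_branch_count",
    "BranchedStressModel",
    "fit_branched",
]


def default_branch_count(n_subjects: int) -> int:
    """Default K = ceil(N/3): around 3-4 subjects per branch tends to work
    best for survey-based grouping of students."""
    return int(np.ceil(n_subjects / 3))


@dataclass
class BranchWeights:
    """Selection logits, one column per subject (log theta, K x N)."""

    logits: np.ndarray
    subject_order: list[str]

    def probabilities(self, tau: float = 1.0) -> np.ndarray:
        """Deterministic mixture weights softmax(logits / tau), per column."""
        z = self.logits / tau
        z = z - z.max(axis=0, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=0, keepdims=True)


@dataclass
class TemperatureSchedule:
    """Linear decay from tau0 to tau_min over total_epochs."""

    tau0: float = 5.0
    tau_min: float = 0.1
    total_epochs: int = 50

    def __post_init__(self):
        if not (self.tau0 >= self.tau_min > 0):
            raise ValueError("need tau0 >= tau_min > 0")

    def at(self, epoch: int) -> float:
        return anneal(self, epoch)


def anneal(schedule: TemperatureSchedule, epoch: int) -> float:
    """tau = max(tau_min, tau0 - epoch * (tau0 - tau_min) / total_epochs)."""
    if not (0 <= epoch):
        raise ValueError("epoch must be non-negative")
    step = (schedule.tau0 - schedule.tau_min) / schedule.total_epochs
    return max(schedule.tau_min, schedule.tau0 - epoch * step)


def gumbel_noise(rng: np.random.Generator, size) -> np.ndarray:
    """i.i.d. Gumbel(0,1) draws: -log(-log U)."""
    u = rng.uniform(low=np.finfo(float).tiny, high=1.0, size=size)
    return -np.log(-np.log(u))


def soft_branch_combine(B: np.ndarray, logits_col: np.ndarray,
                        eps: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Convex mixture of branch outputs with Gumbel-softmax weights.

    ``B`` is (K, d) stacked branch outputs for one example; returns
    ``(d_j, weights)`` where ``d_j = B^T softmax((logits + eps)/tau)``.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    z = (np.asarray(logits_col, dtype=float) + np.asarray(eps, dtype=float)) / tau
    z = z - z.max()
    w = np.exp(z)
    w = w / w.sum()
    return np.asarray(B).T @ w, w


def hard_branch_select(logits_col: np.ndarray) -> int:
    """Argmax branch; ties break to the lowest index."""
    return int(np.argmax(logits_col))


def extract_groups(weights: BranchWeights) -> dict[str, int]:
    """Hard branch assignment per subject — the learned grouping."""
    return {s: hard_branch_select(weights.logits[:, j])
            for j, s in enumerate(weights.subject_order)}


class BranchedStressModel(StressModel):
    """Multitask model with a learn-to-branch layer feeding the heads.

    The generic head bypasses the branches entirely, so cold-start
    predictions are unaffected by the (subject-specific) selection weights.
    """

    def __init__(self, n_channels: int, n_bins: int, n_covariates: int,
                 subjects: list[str], n_branches: int | None = None,
                 config: BackboneConfig | None = None, seed: int = 0):
        super().__init__(n_channels, n_bins, n_covariates, subjects,
                         config=config, seed=seed)
        self.subject_order = sorted(set(subjects))
        K = n_branches or default_branch_count(len(self.subject_order))
        if K < 1:
            raise ValueError("need at least one branch")
        self.n_branches = K
        width = self.config.shared_width
        self.branches = [Linear(width, width, self._rng) for _ in range(K)]
        # uniform initialization: all-zero logits = equal selection weights
        self.branch_logits = Tensor(np.zeros((K, len(self.subject_order))),
                                    requires_grad=True)
        self.tau = 1.0
        self.train_rng: np.random.Generator | None = None
        # personal heads start from a common point (the generic head) so
        # that early between-subject differences are carried by the branch
        # layer rather than by divergent head initializations
        for head in self.heads.values():
            head.copy_from(self.generic_head)

    # ------------------------------------------------------------------ #
    def subject_index(self, subject: str) -> int:
        try:
            return self.subject_order.index(subject)
        except ValueError:
            raise KeyError(f"subject {subject!r} not registered with the branch layer")

    def branch_weights(self) -> BranchWeights:
        return BranchWeights(self.branch_logits.data.copy(), list(self.subject_order))

    def groups(self) -> dict[str, int]:
        return extract_groups(self.branch_weights())

    def head_input(self, feats: Tensor, subject_idx: np.ndarray,
                   train_mode: bool = False) -> Tensor:
        outs = [layer(feats).relu() for layer in self.branches]
        if train_mode:
            if self.train_rng is None:
                raise RuntimeError("train_mode requires a seeded train_rng")
            eps = gumbel_noise(self.train_rng, (len(subject_idx), self.n_branches))
            logits = take_columns(self.branch_logits, subject_idx)
            w = softmax((logits + Tensor(eps)) * (1.0 / self.tau), axis=1)
            mixed = None
            for i, b in enumerate(outs):
                term = b * w.slice_cols(i, i + 1)
                mixed = term if mixed is None else mixed + term
            return mixed
        # evaluation: deterministic hard selection, no noise
        choice = np.array([hard_branch_select(self.branch_logits.data[:, j])
                           for j in subject_idx])
        onehot = np.zeros((len(subject_idx), self.n_branches))
        onehot[np.arange(len(subject_idx)), choice] = 1.0
        w = Tensor(onehot)
        mixed = None
        for i, b in enumerate(outs):
            term = b * w.slice_cols(i, i + 1)
            mixed = term if mixed is None else mixed + term
        return mixed

    # -- cold start ----------------------------------------------------- #
    def add_subject(self, subject: str) -> None:
        """Register an incoming subject: uniform branch-selection column
        plus a personal head warm-started from the generic head."""
        if subject in self.subject_order:
            super().add_subject(subject)
            return
        self.subject_order.append(subject)
        new_col = np.zeros((self.n_branches, 1))
        self.branch_logits = Tensor(
            np.concatenate([self.branch_logits.data, new_col], axis=1),
            requires_grad=True)
        super().add_subject(subject)

    def assignment_report(self) -> "pd.DataFrame":
        """Branch id plus final softmax selection weights per subject."""
        import pandas as pd

        bw = self.branch_weights()
        probs = bw.probabilities(tau=1.0)
        rows = []
        for j, s in enumerate(bw.subject_order):
            row = {"subject_id": s, "branch": hard_branch_select(bw.logits[:, j])}
            row.update({f"w{i}": probs[i, j] for i in range(self.n_branches)})
            rows.append(row)
        return pd.DataFrame(rows)


def fit_branched(dataset, n_branches: int | None = None,
                 config: BackboneConfig | None = None,
                 cfg=None, seed: int = 0, restarts: int = 8,
                 probe_epochs: int | None = None, finalists: int = 4):
    """Fit a branched model with random restarts.

    The branch-assignment landscape has locally stable "compromise"
    configurations in which two true groups share one branch; which basin
    a run falls into depends on the random initialization, essentially a
    random allocation of groups to branches.  As with k-means' ``n_init``,
    several restarts are trained and the one that fits best is kept: runs
    that recover coherent groups fit markedly better than compromises.

    Selection is two-stage to save compute.  All restarts train to
    ``probe_epochs`` (default half the budget) and the best ``finalists``
    by training classification error under hard routing continue to the
    end of the head warmup, where the winner is chosen by the same score.
    Scoring at the end of the warmup — while the personal heads are still
    frozen — is deliberate: once heads unfreeze they partially compensate
    for a poor grouping, which blurs the score differences between basins.
    Only the winner trains to the full epoch budget.

    Unless overridden, the head warmup covers 80% of the epochs so branch
    routing settles before the personal heads specialize.

    Returns ``(model, info)`` where ``info`` has the per-stage scores and
    the training history of the winner.
    """
    import dataclasses

    from .model import TrainConfig, Trainer

    cfg = cfg or TrainConfig(epochs=50)
    if cfg.head_warmup_epochs == 0:
        cfg = dataclasses.replace(cfg, head_warmup_epochs=int(0.8 * cfg.epochs))
    warmup = cfg.head_warmup_epochs
    probe = min(probe_epochs if probe_epochs is not None else cfg.epochs // 2,
                warmup)
    subjects = sorted(set(dataset.subjects))
    n, C, T, H = dataset.X.shape
    d = dataset.covariates.shape[1]

    trainers = []
    for r in range(restarts):
        seed_r = (seed * 1000003 + r) % (2 ** 31)
        model = BranchedStressModel(C, H, d, subjects, n_branches=n_branches,
                                    config=config, seed=seed_r)
        trainers.append(Trainer(model, dataset, cfg, seed=seed_r))
    probe_scores = []
    for t in trainers:
        t.run(probe)
        probe_scores.append(t.eval_personal_ce())
    survivors = np.argsort(probe_scores)[:max(1, min(finalists, restarts))]
    warmup_scores = {}
    for r in survivors:
        trainers[r].run(warmup - probe)
        warmup_scores[int(r)] = trainers[r].eval_personal_ce()
    best = min(warmup_scores, key=warmup_scores.get)
    trainers[best].run()
    info = {
        "probe_scores": [float(s) for s in probe_scores],
        "warmup_scores": {k: float(v) for k, v in warmup_scores.items()},
        "selected_restart": int(best),
        "final_score": float(trainers[best].eval_personal_ce()),
        "history": trainers[best].history,
    }
    return trainers[best].model, info
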