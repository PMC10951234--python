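"""Comparison models: pooled single-head baseline and survey-clustered
group heads.

The clustered variant replaces per-subject heads with per-group heads,
where groups come from density-based clustering (DBSCAN) of standardized
psychological survey scores; the sweet spot in practice is an average of
3-4 subjects per cluster.  A clustered model whose groups are all
singletons is exactly the fully personalized model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.preprocessing import StandardScaler

from .model import POOLED, BackboneConfig, StressModel
from .preprocess import SurveyScores

logger = logging.getLogger(__name__)


@dataclass
class ClusterPlan:
    """Subject -> group assignment with the method's metadata.

    DBSCAN noise points become their own singleton groups, so every
    training subject is always assigned.
    """

    assignment: dict[str, str]
    method: str = "dbscan"
    params: dict = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignment.values()))

    def mean_group_size(self) -> float:
        return len(self.assignment) / self.n_groups

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"subject_id": s, "group": g} for s, g in sorted(self.assignment.items())])


def _group_names(subject_ids: list[str], raw_labels: np.ndarray) -> dict[str, str]:
    """Name each group after its lexicographically first member, so that a
    plan of singletons reproduces the per-subject head keys exactly."""
    assignment: dict[str, str] = {}
    cluster_rep: dict[int, str] = {}
    for s, lab in sorted(zip(subject_ids, raw_labels)):
        if lab == -1:  # DBSCAN noise -> singleton
            assignment[s] = s
        else:
            cluster_rep.setdefault(lab, s)
            assignment[s] = cluster_rep[lab]
    return assignment


def cluster_surveys(scores: SurveyScores, eps: float | None = None,
                    min_samples: int | None = None,
                    target_mean_size: tuple[float, float] = (3.0, 4.0)) -> ClusterPlan:
    """DBSCAN on standardized survey-score rows.

    When ``eps``/``min_samples`` are not given, a small grid is searched
    and the configuration whose mean cluster size lands in
    ``target_mean_size`` (closest to its midpoint otherwise) is kept.
    """
    S = np.asarray(scores.S, dtype=float)
    if len(scores.subject_ids) == 1:
        return ClusterPlan({scores.subject_ids[0]: scores.subject_ids[0]},
                           params={"note": "single subject"})
    if np.allclose(S, S[0]):
        logger.warning("degenerate survey matrix (identical rows): single cluster")
        rep = sorted(scores.subject_ids)[0]
        return ClusterPlan({s: rep for s in scores.subject_ids},
                           params={"note": "degenerate"})
    Z = StandardScaler().fit_transform(S)

    def run(e: float, m: int) -> ClusterPlan:
        labels = DBSCAN(eps=e, min_samples=m).fit_predict(Z)
        return ClusterPlan(_group_names(scores.subject_ids, labels),
                           params={"eps": float(e), "min_samples": int(m)})

    if eps is not None and min_samples is not None:
        return run(eps, min_samples)

    from scipy.spatial.distance import pdist

    d = pdist(Z)
    eps_grid = np.quantile(d, [0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
    ms_grid = [2, 3] if min_samples is None else [min_samples]
    lo, hi = target_mean_size
    mid = 0.5 * (lo + hi)
    best, best_cost = None, np.inf
    for e in eps_grid:
        if e <= 0:
            continue
        for m in ms_grid:
            plan = run(e, m)
            size = plan.mean_group_size()
            cost = 0.0 if lo <= size <= hi else abs(size - mid)
            if cost < best_cost:
                best, best_cost = plan, cost
    return best


def assign_new_subject(plan: ClusterPlan, scores: SurveyScores,
                       new_scores: np.ndarray) -> str:
    """Cold-start group for an incoming subject: nearest cluster centroid
    in standardized survey space."""
    scaler = StandardScaler().fit(scores.S)
    Z = scaler.transform(scores.S)
    z_new = scaler.transform(np.atleast_2d(new_scores))[0]
    groups = sorted(set(plan.assignment.values()))
    centroids = {
        g: Z[[i for i, s in enumerate(scores.subject_ids)
              if plan.assignment[s] == g]].mean(axis=0)
        for g in groups
    }
    return min(groups, key=lambda g: float(np.linalg.norm(centroids[g] - z_new)))


# ---------------------------------------------------------------------- #
# model factories (shared by the evaluation harness and the CLI)
# ---------------------------------------------------------------------- #

def make_model(kind: str, n_channels: int, n_bins: int, n_covariates: int,
               subjects: list[str], seed: int = 0,
               config: BackboneConfig | None = None,
               cluster_plan: ClusterPlan | None = None,
               n_branches: int | None = None) -> StressModel:
    """Construct any of the supported models over the same backbone.

    ``calmnet`` — per-subject heads; ``pooled`` — one head for everyone;
    ``clustered`` — survey-cluster group heads; ``branched`` — per-subject
    heads behind a learn-to-branch layer.
    """
    from .branching import BranchedStressModel

    if kind == "calmnet":
        return StressModel(n_channels, n_bins, n_covariates, subjects,
                           config=config, seed=seed)
    if kind == "pooled":
        return StressModel(n_channels, n_bins, n_covariates, subjects,
                           config=config, seed=seed,
                           head_map={s: POOLED for s in subjects})
    if kind == "clustered":
        if cluster_plan is None:
            raise ValueError("clustered model needs a ClusterPlan")
        head_map = {s: cluster_plan.assignment[s] for s in subjects}
        return StressModel(n_channels, n_bins, n_covariates, subjects,
                           config=config, seed=seed, head_map=head_map)
    if kind == "branched":
        return BranchedStressModel(n_channels, n_bins, n_covariates, subjects,
                                   n_branches=n_branches, config=config, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}")


def factory_for(kind: str, dataset, config: BackboneConfig | None = None,
                cluster_plan: ClusterPlan | None = None,
                n_branches: int | None = None):
    """Bind dataset shapes into a ``(subjects, seed) -> model`` factory."""
    n, C, T, H = dataset.X.shape
    d = dataset.covariates.shape[1]

    def factory(subjects, seed):
        return make_model(kind, C, H, d, list(subjects), seed=seed, config=config,
                          cluster_plan=cluster_plan, n_branches=n_branches)

    return factory
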