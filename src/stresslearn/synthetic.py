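"""Synthetic cohort generator shaped like a student passive-sensing study.

Produces irregular timestamped event streams (activity/audio inference
classes, conversation, phone charge, phone lock), daily stress self-reports
on a 1-5 scale, per-subject psychological survey scores, and calendar
covariates — with *planted* subject groups so grouping methods can be
scored against ground truth.

Generative story, per subject:

* the subject belongs to group ``g`` (uniformly at random);
* each day, per-channel behavior intensities are drawn around piecewise-
  constant profiles over six 4-hour day segments, then events are emitted
  minute by minute (categorical draws for activity/audio, Poisson counts
  for the binary channels);
* a latent stress score combines the day's standardized behavior summary
  through a group-specific weight vector (separation controlled by the
  effect size ``delta``), a persistent subject offset, and Gaussian noise;
* raw labels 1-5 are cut at fixed cohort quantiles (0.10/0.35/0.70/0.90),
  mirroring the imbalance of real daily stress reports;
* survey scores are the group centroid plus noise, so surveys carry group
  information the way trait questionnaires do.

``delta = 0`` removes all group structure from the stress response — the
null model for group-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import (
    HISTOGRAM_CHANNELS,
    RawEventSeries,
    StressDataset,
    aggregate_minutes,
    assemble_day,
    hour_histograms,
    impute_minutes,
)

N_SEGMENTS = 6  # 4-hour blocks: night, early morning, morning, afternoon, evening, late
SEGMENT_MINUTES = 240

SURVEY_NAMES = ["phq9", "pss", "loneliness", "flourish", "panas", "big5_neuro"]

#: raw-label quantile cuts; chosen so the merged 3-class marginals echo the
#: below/median/above imbalance seen in daily stress EMA data
LABEL_QUANTILES = (0.10, 0.35, 0.70, 0.90)


@dataclass
class CohortSpec:
    """Knobs of the generator; defaults give the standard test cohort
    (12 subjects in 3 groups, 60 days each) that trains in minutes on CPU."""

    n_subjects: int = 12
    n_groups: int = 3
    days_per_subject: int = 60
    delta: float = 3.0               # group effect size on the stress response
    subject_offset_scale: float = 0.8
    label_noise: float = 0.6
    missing_day_prob: float = 0.05
    survey_separation: float = 2.0
    survey_noise: float = 1.0
    categorical_event_rate: float = 0.5   # events/minute for activity & audio
    binary_event_rate: float = 0.25       # events/minute for the binary channels
    day_intensity_sd: float = 0.6
    start_date: str = "2024-01-01"
    seed: int = 0

    def __post_init__(self):
        if not (self.n_subjects >= self.n_groups >= 1):
            raise ValueError("need n_subjects >= n_groups >= 1")
        if not (0 <= self.missing_day_prob <= 1):
            raise ValueError("missing_day_prob must be a probability")
        if self.delta < 0 or self.label_noise < 0:
            raise ValueError("delta and label_noise must be non-negative")


@dataclass
class SyntheticCohort:
    """Generated raw streams plus the ground truth behind them."""

    spec: CohortSpec
    events: dict                      # (subject, date, channel) -> [(ts, value)]
    ema: pd.DataFrame                 # subject_id, date, stress_raw
    surveys: pd.DataFrame             # subject_id + survey columns
    calendar: pd.DataFrame            # date, exam_period, time_to_deadline
    sleep: pd.DataFrame               # subject_id, date, sleep_rating, sleep_duration
    group_of: dict[str, int]
    behavior_summary: dict            # (subject, date) -> standardized channel summary
    latent_stress: dict               # (subject, date) -> latent score
    group_weights: np.ndarray         # (n_groups, n_channels)
    subject_offsets: dict[str, float]
    label_cuts: np.ndarray
    n_masked_days: int = 0

    @property
    def subjects(self) -> list[str]:
        return sorted(self.group_of)


def _group_weight_vectors(n_groups: int, n_channels: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Unit-norm weight vectors, one per group, mutually well separated:
    each group reads a different (signed) mix of channels."""
    W = np.zeros((n_groups, n_channels))
    for g in range(n_groups):
        W[g, g % n_channels] = 1.0
        W[g, (g + 1) % n_channels] = -0.5 if g % 2 else 0.5
        W[g] /= np.linalg.norm(W[g])
    return W


def _segment_profiles(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    """Shared diurnal activity template per channel and 4-hour segment,
    in [0.05, 0.95]: low at night, high during the day."""
    base = np.array([0.10, 0.35, 0.75, 0.70, 0.80, 0.40])
    prof = np.clip(base[None, :] + rng.normal(0, 0.05, size=(n_channels, N_SEGMENTS)),
                   0.05, 0.95)
    return prof


def generate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Draw a full cohort; bit-identical for a given spec (seed included)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    channels = HISTOGRAM_CHANNELS
    C = len(channels)

    subjects = [f"s{i:02d}" for i in range(spec.n_subjects)]
    # every group non-empty, remainder uniform
    groups = list(range(spec.n_groups)) * (spec.n_subjects // spec.n_groups)
    groups += list(rng.integers(0, spec.n_groups, spec.n_subjects - len(groups)))
    rng.shuffle(groups)
    group_of = dict(zip(subjects, map(int, groups)))
    offsets = {s: float(rng.normal(0, spec.subject_offset_scale)) for s in subjects}
    W = _group_weight_vectors(spec.n_groups, C, rng)
    profiles = _segment_profiles(C, rng)

    dates = pd.date_range(spec.start_date, periods=spec.days_per_subject, freq="D")
    date_strs = [d.strftime("%Y-%m-%d") for d in dates]

    # calendar: an exam period covering the 6th and 7th weeks; deadlines every 2 weeks
    exam = np.zeros(len(dates))
    exam[min(35, len(dates)):min(49, len(dates))] = 1.0
    deadline_every = 14
    ttd = np.array([(deadline_every - (i % deadline_every)) % deadline_every
                    for i in range(len(dates))], dtype=float)
    calendar = pd.DataFrame({"date": date_strs, "exam_period": exam,
                             "time_to_deadline": ttd})

    events: dict = {}
    raw_summary: dict = {}
    sleep_rows = []
    for s in subjects:
        for d in date_strs:
            intensity = np.exp(rng.normal(0, spec.day_intensity_sd, size=C))
            summary = np.zeros(C)
            for c, ch in enumerate(channels):
                ev = []
                for seg in range(N_SEGMENTS):
                    level = np.clip(profiles[c, seg] * intensity[c], 0.0, 1.0)
                    if ch in ("activity", "audio"):
                        rate = spec.categorical_event_rate * level
                        n_ev = rng.poisson(rate * SEGMENT_MINUTES)
                        ts = np.sort(rng.uniform(seg * SEGMENT_MINUTES * 60,
                                                 (seg + 1) * SEGMENT_MINUTES * 60, n_ev))
                        vals = rng.binomial(3, level, size=n_ev).astype(float)
                    else:
                        rate = spec.binary_event_rate * level
                        n_ev = rng.poisson(rate * SEGMENT_MINUTES)
                        ts = np.sort(rng.uniform(seg * SEGMENT_MINUTES * 60,
                                                 (seg + 1) * SEGMENT_MINUTES * 60, n_ev))
                        vals = np.ones(n_ev)
                    ev.extend(zip(ts.tolist(), vals.tolist()))
                ev.sort(key=lambda e: e[0])
                events[(s, d, ch)] = ev
                if ch in ("activity", "audio"):
                    summary[c] = np.mean([v for _, v in ev]) if ev else 0.0
                else:
                    summary[c] = np.log1p(len(ev))
            raw_summary[(s, d)] = summary
            sleep_rows.append({"subject_id": s, "date": d,
                               "sleep_rating": float(rng.integers(1, 6)),
                               "sleep_duration": float(np.clip(rng.normal(7, 1), 3, 12))})

    # standardize summaries cohort-wide so delta has a stable scale
    M = np.stack(list(raw_summary.values()))
    mu, sd = M.mean(axis=0), M.std(axis=0) + 1e-12
    behavior = {k: (v - mu) / sd for k, v in raw_summary.items()}

    latent = {}
    for (s, d), z in behavior.items():
        g = group_of[s]
        latent[(s, d)] = float(spec.delta * (W[g] @ z) + offsets[s]
                               + rng.normal(0, spec.label_noise))
    scores = np.array(list(latent.values()))
    cuts = np.quantile(scores, LABEL_QUANTILES)

    ema_rows = []
    n_masked = 0
    for s in subjects:
        for d in date_strs:
            if rng.uniform() < spec.missing_day_prob:
                n_masked += 1
                continue
            raw = 1 + int(np.searchsorted(cuts, latent[(s, d)], side="right"))
            ema_rows.append({"subject_id": s, "date": d, "stress_raw": raw})

    centroids = rng.normal(0, spec.survey_separation,
                           size=(spec.n_groups, len(SURVEY_NAMES)))
    survey_rows = []
    for s in subjects:
        g = group_of[s]
        vals = centroids[g] + rng.normal(0, spec.survey_noise, len(SURVEY_NAMES))
        survey_rows.append({"subject_id": s, **dict(zip(SURVEY_NAMES, vals))})

    return SyntheticCohort(
        spec=spec, events=events, ema=pd.DataFrame(ema_rows),
        surveys=pd.DataFrame(survey_rows), calendar=calendar,
        sleep=pd.DataFrame(sleep_rows), group_of=group_of,
        behavior_summary=behavior, latent_stress=latent, group_weights=W,
        subject_offsets=offsets, label_cuts=cuts, n_masked_days=n_masked,
    )


def cohort_to_dataset(cohort: SyntheticCohort) -> StressDataset:
    """Run the generated raw streams through the full featurization
    pipeline (minute aggregation, imputation, hourly histograms, covariate
    assembly, label mapping)."""
    from .preprocess import _day_covariates

    cal = cohort.calendar.set_index("date")
    sleep = cohort.sleep.set_index(["subject_id", "date"])
    examples = []
    for _, row in cohort.ema.iterrows():
        s, d, raw = row["subject_id"], row["date"], int(row["stress_raw"])
        hists = []
        for ch in HISTOGRAM_CHANNELS:
            series = RawEventSeries(ch, cohort.events[(s, d, ch)])
            hists.append(hour_histograms(impute_minutes(aggregate_minutes(series))))
        srow = sleep.loc[(s, d)]
        cov = _day_covariates(pd.Timestamp(d), cal.loc[d],
                              float(srow["sleep_rating"]), float(srow["sleep_duration"]))
        examples.append(assemble_day(hists, cov, raw, s, d))
    return StressDataset(
        X=np.stack([e.X for e in examples]),
        covariates=np.stack([e.covariates for e in examples]),
        labels=np.array([e.label for e in examples]),
        subjects=np.array([e.subject_id for e in examples]),
        dates=np.array([e.date for e in examples]),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str) -> None:
    """Write the CSV layout the preprocessing pipeline reads (round-trip
    compatible with :func:`stresslearn.preprocess.build_dataset`)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.ema.to_csv(out / "ema.csv", index=False)
    cohort.calendar.to_csv(out / "calendar.csv", index=False)
    cohort.surveys.to_csv(out / "surveys.csv", index=False)
    for s in cohort.subjects:
        sdir = out / s
        sdir.mkdir(exist_ok=True)
        for ch in HISTOGRAM_CHANNELS:
            rows = []
            for d in cohort.calendar["date"]:
                for t, v in cohort.events.get((s, d, ch), []):
                    rows.append((d, t, v))
            pd.DataFrame(rows, columns=["date", "timestamp", "value"]).to_csv(
                sdir / f"{ch}.csv", index=False)
        sub_sleep = cohort.sleep[cohort.sleep["subject_id"] == s]
        for name in ("sleep_rating", "sleep_duration"):
            sub_sleep[["date", name]].rename(columns={name: "value"}).to_csv(
                sdir / f"{name}.csv", index=False)


def bayes_predict(cohort: SyntheticCohort) -> pd.DataFrame:
    """Oracle 3-class prediction from the true generative parameters.

    For each labeled day the latent-score distribution (before noise) is
    known; class probabilities follow from Gaussian tail masses between the
    label cuts, merged 1-5 -> 3 classes.  An upper bound no trained model
    should beat on average.
    """
    from scipy.stats import norm

    spec = cohort.spec
    rows = []
    for _, r in cohort.ema.iterrows():
        s, d = r["subject_id"], r["date"]
        mean = (spec.delta * (cohort.group_weights[cohort.group_of[s]]
                              @ cohort.behavior_summary[(s, d)])
                + cohort.subject_offsets[s])
        cdf = norm.cdf(cohort.label_cuts, loc=mean, scale=max(spec.label_noise, 1e-9))
        raw_p = np.diff(np.concatenate([[0.0], cdf, [1.0]]))  # P(raw=1..5)
        p3 = np.array([raw_p[0] + raw_p[1], raw_p[2], raw_p[3] + raw_p[4]])
        rows.append({"subject_id": s, "date": d, "p1": p3[0], "p2": p3[1],
                     "p3": p3[2], "pred": 1 + int(np.argmax(p3))})
    return pd.DataFrame(rows)
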