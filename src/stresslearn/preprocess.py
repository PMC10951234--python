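"""Featurization of irregular mobile-sensor event streams.

Passive smartphone sensing yields irregular timestamped events per channel
(activity and audio inference classes, conversation/charge/lock indicators).
The pipeline regularizes them into a fixed per-day representation:

1. :func:`aggregate_minutes` — bin events into 1440 one-minute slots with a
   per-feature rule (``sum`` counts event values; ``mode`` records the modal
   class observed that minute);
2. :func:`impute_minutes` — fill unobserved minutes (zero, forward-fill, or
   forward-fill followed by mean for leading gaps);
3. :func:`hour_histograms` — summarize each of the 24 hours by the value
   histogram of its 60 minutes, normalized to proportions;
4. :func:`assemble_day` — stack channels into a ``C x 24 x H`` tensor and
   attach day-level covariates and the mapped stress label.

Daily self-reported stress (1-5) is collapsed to three classes
(below-median / median / above-median) by :func:`map_stress_label`, and
subjects with too few or disproportionately many labeled days are dropped
by :func:`filter_subjects`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTES_PER_DAY = 1440
HOURS_PER_DAY = 24

#: per-feature minute-aggregation rule and imputation strategy
FEATURE_RULES: dict[str, tuple[str, str]] = {
    "activity": ("mode", "zero"),
    "audio": ("mode", "zero"),
    "conversation": ("sum", "ffill"),
    "phone_charge": ("sum", "ffill"),
    "phone_lock": ("sum", "ffill_then_mean"),
}

#: channels stacked into the day tensor, in order
HISTOGRAM_CHANNELS = ("activity", "audio", "conversation", "phone_charge", "phone_lock")

#: default histogram bin edges per channel (4 bins each for a uniform tensor).
#: activity/audio are 4-way categorical; the binary-sum channels use
#: equal-width bins over the per-minute count range seen in practice.
DEFAULT_BIN_EDGES: dict[str, np.ndarray] = {
    "activity": np.array([-0.5, 0.5, 1.5, 2.5, 3.5]),
    "audio": np.array([-0.5, 0.5, 1.5, 2.5, 3.5]),
    "conversation": np.array([-0.5, 0.5, 1.5, 2.5, np.inf]),
    "phone_charge": np.array([-0.5, 0.5, 1.5, 2.5, np.inf]),
    "phone_lock": np.array([-0.5, 0.5, 1.5, 2.5, np.inf]),
}

COVARIATE_NAMES = (
    ["dow_%d" % d for d in range(7)]
    + ["exam_period", "time_to_deadline", "sleep_rating", "sleep_duration"]
)


@dataclass
class RawEventSeries:
    """Irregular events of one feature within one local day.

    ``events`` is an ordered list of ``(timestamp, value)`` with timestamps
    in seconds within the day, ``[0, 86400)``, non-decreasing.
    """

    feature_name: str
    events: list[tuple[float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.feature_name not in FEATURE_RULES:
            raise ValueError(f"unknown feature {self.feature_name!r}")
        last = -np.inf
        for t, v in self.events:
            if not (0 <= t < 86400):
                raise ValueError(f"timestamp {t} outside [0, 86400)")
            if t < last:
                raise ValueError("timestamps must be non-decreasing")
            last = t
            if self.feature_name in ("activity", "audio") and v not in (0, 1, 2, 3):
                raise ValueError(f"{self.feature_name} value {v} not in {{0,1,2,3}}")
            if self.feature_name in ("conversation", "phone_charge", "phone_lock") and v not in (0, 1):
                raise ValueError(f"{self.feature_name} value {v} not binary")


@dataclass
class MinuteSeries:
    """Minute-binned day: 1440 values with an observed mask."""

    feature_name: str
    values: np.ndarray
    observed_mask: np.ndarray
    rule: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.observed_mask = np.asarray(self.observed_mask, dtype=bool)
        if self.values.shape != (MINUTES_PER_DAY,) or self.observed_mask.shape != (MINUTES_PER_DAY,):
            raise ValueError("minute series must have exactly 1440 entries")


@dataclass
class HourHistogramSeries:
    """24 hourly value-histograms (rows sum to 1) for one channel-day."""

    feature_name: str
    H: np.ndarray

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        if self.H.ndim != 2 or self.H.shape[0] != HOURS_PER_DAY:
            raise ValueError("histogram matrix must be 24 x n_bins")


@dataclass
class DayExample:
    """One subject-day: stacked histogram tensor, covariates, 3-class label."""

    subject_id: str
    date: str
    X: np.ndarray  # (C, 24, H)
    covariates: np.ndarray
    label: int

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.X.ndim != 3 or self.X.shape[1] != HOURS_PER_DAY:
            raise ValueError("day tensor must be C x 24 x H")
        if self.label not in (1, 2, 3):
            raise ValueError("label must be in {1,2,3}")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError("covariates must be finite")


@dataclass
class SurveyScores:
    """Per-subject survey score matrix (one row per subject)."""

    S: np.ndarray
    survey_names: list[str]
    subject_ids: list[str]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_col: str = "subject_id") -> "SurveyScores":
        """Assemble from a dataframe; missing scores are mean-imputed."""
        df = df.set_index(subject_col)
        S = df.to_numpy(dtype=float)
        col_means = np.nanmean(S, axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        nan_mask = ~np.isfinite(S)
        S[nan_mask] = np.broadcast_to(col_means, S.shape)[nan_mask]
        return cls(S=S, survey_names=list(df.columns), subject_ids=list(df.index.astype(str)))


def aggregate_minutes(events: RawEventSeries) -> MinuteSeries:
    """Bin a day of irregular events into 1440 one-minute slots.

    ``sum`` features accumulate event values per minute; ``mode`` features
    record the modal value among that minute's events (smallest value wins
    ties).  Minutes with no events are flagged unobserved.
    """
    events.validate()
    rule, _ = FEATURE_RULES[events.feature_name]
    values = np.zeros(MINUTES_PER_DAY)
    observed = np.zeros(MINUTES_PER_DAY, dtype=bool)
    if events.events:
        ts = np.array([t for t, _ in events.events])
        vs = np.array([v for _, v in events.events])
        minutes = (ts // 60).astype(int)
        if rule == "sum":
            np.add.at(values, minutes, vs)
            observed[minutes] = True
        else:  # mode
            for m in np.unique(minutes):
                sel = vs[minutes == m]
                cats, counts = np.unique(sel, return_counts=True)
                values[m] = cats[np.argmax(counts)]
                observed[m] = True
    return MinuteSeries(events.feature_name, values, observed, rule)


def impute_minutes(series: MinuteSeries, strategy: str | None = None) -> MinuteSeries:
    """Fill unobserved minutes; returns a fully observed series.

    Strategies: ``zero`` (fill 0), ``ffill`` (carry last observed value;
    leading gap 0), ``ffill_then_mean`` (forward fill, then the mean of
    observed values for the leading gap).  When ``strategy`` is omitted the
    feature's canonical strategy is used.
    """
    if strategy is None:
        strategy = FEATURE_RULES[series.feature_name][1]
    if strategy not in ("zero", "ffill", "ffill_then_mean"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = series.values.copy()
    obs = series.observed_mask
    if obs.all():
        return MinuteSeries(series.feature_name, values, np.ones_like(obs), series.rule)
    if strategy == "zero":
        values[~obs] = 0.0
    else:
        if not obs.any():
            logger.warning("all minutes unobserved for %s; filling with 0", series.feature_name)
            values[:] = 0.0
        else:
            # forward fill: index of last observed minute at or before each slot
            idx = np.where(obs, np.arange(MINUTES_PER_DAY), -1)
            idx = np.maximum.accumulate(idx)
            filled = np.where(idx >= 0, values[np.clip(idx, 0, None)], np.nan)
            lead = 0.0 if strategy == "ffill" else float(values[obs].mean())
            values = np.where(np.isnan(filled), lead, filled)
    return MinuteSeries(series.feature_name, values, np.ones_like(obs), series.rule)


def hour_histograms(series: MinuteSeries, bin_edges: np.ndarray | None = None) -> HourHistogramSeries:
    """Histogram each hour's 60 minute-values, normalized to proportions."""
    if not series.observed_mask.all():
        raise ValueError("series must be imputed before histogramming")
    if bin_edges is None:
        bin_edges = DEFAULT_BIN_EDGES[series.feature_name]
    bin_edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(bin_edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing")
    n_bins = len(bin_edges) - 1
    H = np.zeros((HOURS_PER_DAY, n_bins))
    per_hour = series.values.reshape(HOURS_PER_DAY, 60)
    for h in range(HOURS_PER_DAY):
        counts, _ = np.histogram(per_hour[h], bins=bin_edges)
        H[h] = counts / 60.0
    return HourHistogramSeries(series.feature_name, H)


def map_stress_label(raw: int) -> int:
    """Collapse raw stress 1-5 to 3 classes: {1,2}->1, 3->2, {4,5}->3."""
    raw = int(raw)
    if raw not in (1, 2, 3, 4, 5):
        raise ValueError(f"raw stress label {raw} outside 1..5")
    return {1: 1, 2: 1, 3: 2, 4: 3, 5: 3}[raw]


def filter_subjects(day_counts: dict[str, int],
                    min_days: int = 35, max_days: int = 150) -> set[str]:
    """Keep subjects with strictly more than ``min_days`` and strictly fewer
    than ``max_days`` labeled days, balancing under- and over-represented
    subjects."""
    return {s for s, n in day_counts.items() if min_days < n < max_days}


def assemble_day(channel_hists: list[HourHistogramSeries], covariates: np.ndarray,
                 raw_label: int, subject_id: str, date: str) -> DayExample:
    """Stack per-channel histograms into a day tensor with mapped label.

    Channels must arrive in :data:`HISTOGRAM_CHANNELS` order with equal bin
    counts.  Covariate order is :data:`COVARIATE_NAMES`.
    """
    names = tuple(h.feature_name for h in channel_hists)
    if names != HISTOGRAM_CHANNELS:
        raise ValueError(f"expected channels {HISTOGRAM_CHANNELS}, got {names}")
    widths = {h.H.shape[1] for h in channel_hists}
    if len(widths) != 1:
        raise ValueError("all channels must share the same histogram width")
    X = np.stack([h.H for h in channel_hists], axis=0)
    return DayExample(subject_id=subject_id, date=date, X=X,
                      covariates=covariates, label=map_stress_label(raw_label))


@dataclass
class StressDataset:
    """Preprocessed cohort: one row per labeled subject-day."""

    X: np.ndarray              # (n, C, 24, H)
    covariates: np.ndarray     # (n, d)
    labels: np.ndarray         # (n,) in {1,2,3}
    subjects: np.ndarray       # (n,) str
    dates: np.ndarray          # (n,) str ISO dates
    channel_names: tuple = HISTOGRAM_CHANNELS
    covariate_names: tuple = tuple(COVARIATE_NAMES)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def subject_list(self) -> list[str]:
        return sorted(set(self.subjects.tolist()))

    def subset(self, idx) -> "StressDataset":
        idx = np.asarray(idx)
        return StressDataset(self.X[idx], self.covariates[idx], self.labels[idx],
                             self.subjects[idx], self.dates[idx],
                             self.channel_names, self.covariate_names)

    def save(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X)
            f.create_dataset("covariates", data=self.covariates)
            f.create_dataset("labels", data=self.labels)
            str_dt = h5py.string_dtype()
            f.create_dataset("subjects", data=self.subjects.astype(object), dtype=str_dt)
            f.create_dataset("dates", data=self.dates.astype(object), dtype=str_dt)
            f.attrs["channel_names"] = list(self.channel_names)
            f.attrs["covariate_names"] = list(self.covariate_names)

    @classmethod
    def load(cls, path: str) -> "StressDataset":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                X=f["X"][...],
                covariates=f["covariates"][...],
                labels=f["labels"][...],
                subjects=f["subjects"].asstr()[...],
                dates=f["dates"].asstr()[...],
                channel_names=tuple(f.attrs["channel_names"]),
                covariate_names=tuple(f.attrs["covariate_names"]),
            )


def _day_covariates(date: pd.Timestamp, calendar_row: pd.Series | None,
                    sleep_rating: float, sleep_duration: float) -> np.ndarray:
    dow = np.zeros(7)
    dow[date.dayofweek] = 1.0
    exam = float(calendar_row["exam_period"]) if calendar_row is not None else 0.0
    ttd = float(calendar_row["time_to_deadline"]) if calendar_row is not None else 0.0
    return np.concatenate([dow, [exam, ttd, sleep_rating, sleep_duration]])


def build_dataset(raw_dir: str, bin_edges: dict[str, np.ndarray] | None = None,
                  apply_subject_filter: bool = False) -> StressDataset:
    """Run the full pipeline over a raw cohort directory.

    Layout: ``<raw_dir>/<subject>/<feature>.csv`` with columns
    ``date,timestamp,value`` for event channels and ``date,value`` for the
    day-level sleep features; ``<raw_dir>/ema.csv`` with
    ``subject_id,date,stress_raw``; optional ``calendar.csv`` with
    ``date,exam_period,time_to_deadline``.
    """
    import pathlib

    raw = pathlib.Path(raw_dir)
    bin_edges = bin_edges or DEFAULT_BIN_EDGES
    ema = pd.read_csv(raw / "ema.csv", dtype={"subject_id": str})
    cal_path = raw / "calendar.csv"
    calendar = pd.read_csv(cal_path).set_index("date") if cal_path.exists() else None

    if apply_subject_filter:
        counts = ema.groupby("subject_id").size().to_dict()
        keep = filter_subjects(counts)
        ema = ema[ema["subject_id"].isin(keep)]

    examples: list[DayExample] = []
    for subject, sub_ema in ema.groupby("subject_id"):
        sdir = raw / str(subject)
        streams = {feat: pd.read_csv(sdir / f"{feat}.csv") for feat in HISTOGRAM_CHANNELS}
        sleep = {name: pd.read_csv(sdir / f"{name}.csv").set_index("date")["value"]
                 for name in ("sleep_rating", "sleep_duration")
                 if (sdir / f"{name}.csv").exists()}
        for _, row in sub_ema.iterrows():
            date = str(row["date"])
            hists = []
            for feat in HISTOGRAM_CHANNELS:
                df = streams[feat]
                day_events = df[df["date"] == date]
                series = RawEventSeries(
                    feat, list(zip(day_events["timestamp"].astype(float),
                                   day_events["value"].astype(float))))
                ms = impute_minutes(aggregate_minutes(series))
                hists.append(hour_histograms(ms, bin_edges[feat]))
            ts = pd.Timestamp(date)
            cal_row = calendar.loc[date] if calendar is not None and date in calendar.index else None
            def _sleep_val(name: str) -> float:
                s = sleep.get(name)
                v = float(s.get(date, 0.0)) if s is not None else 0.0
                return v if np.isfinite(v) else 0.0

            cov = _day_covariates(ts, cal_row, _sleep_val("sleep_rating"),
                                  _sleep_val("sleep_duration"))
            examples.append(assemble_day(hists, cov, int(row["stress_raw"]),
                                         str(subject), date))
    if not examples:
        raise ValueError("no labeled days found under " + str(raw))
    return StressDataset(
        X=np.stack([e.X for e in examples]),
        covariates=np.stack([e.covariates for e in examples]),
        labels=np.array([e.label for e in examples]),
        subjects=np.array([e.subject_id for e in examples]),
        dates=np.array([e.date for e in examples]),
    )
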