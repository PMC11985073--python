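"""Censored time-to-event analysis of feeding-step latencies and durations.

Each step latency (paralyze "duration" from contact; inter-step intervals for
TCR, bend and ingest) is right-censored at the observation window when the
step was not executed.  Kaplan-Meier product-limit curves are reported as
cumulative fractions 1 - S(t); box summaries use the T25/T50/T75 crossing
times of the curve (first event time at which the cumulative fraction reaches
the target, no interpolation — curves that plateau below the target leave the
percentile "not reached").  Groups are compared with the log-rank (Mantel-Cox)
test; correlations between adjacent-step timings use Spearman's rank
coefficient on doubly-uncensored pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_multivariate_logrank
from scipy import stats

from .ethogram_io import ConditionLabel, FeedingStep, TimingRecord


@dataclass
class LatencySample:
    """Latency observations for one step under one condition.

    ``observed[i]`` is False for records right-censored at ``window_s``.
    """

    step: FeedingStep
    condition: ConditionLabel | None
    times_s: np.ndarray
    observed: np.ndarray
    window_s: float = 120.0

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.times_s.shape != self.observed.shape:
            raise ValueError("times_s and observed must have equal length")
        # censoring normally happens at the window, but earlier censoring is
        # accepted (e.g. samples pooled across observation protocols)
        if np.any(self.times_s > self.window_s):
            raise ValueError("latencies exceed the observation window")

    @property
    def n(self) -> int:
        return int(self.times_s.size)

    @property
    def uncensored(self) -> np.ndarray:
        return self.times_s[self.observed]

    @classmethod
    def from_timings(
        cls,
        timings: Iterable[TimingRecord],
        step: FeedingStep,
        condition: ConditionLabel | None = None,
        window_s: float = 120.0,
        quantity: str = "latency",
    ) -> "LatencySample":
        """Collect one step's latency (or duration) records into a sample.

        ``quantity="duration"`` keeps only executed steps with annotated
        offsets (all uncensored), matching how executed-step durations are
        compared between conditions.
        """
        times, observed = [], []
        for rec in timings:
            if rec.step is not step:
                continue
            if quantity == "latency":
                times.append(rec.latency_s)
                observed.append(not rec.censored)
            elif quantity == "duration":
                if rec.duration_s is not None:
                    times.append(rec.duration_s)
                    observed.append(True)
            else:
                raise ValueError(f"unknown quantity {quantity!r}")
        return cls(step, condition, np.array(times), np.array(observed), window_s)


@dataclass
class KMCurve:
    """Kaplan-Meier curve expressed as a cumulative fraction 1 - S(t)."""

    event_times_s: np.ndarray
    cumulative_fraction: np.ndarray
    at_risk: np.ndarray
    percentile_times: dict[int, float | None] = field(default_factory=dict)

    def fraction_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times_s, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumulative_fraction[idx])

    def to_frame(self, **labels) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.event_times_s,
                "cumulative_fraction": self.cumulative_fraction,
                "at_risk": self.at_risk,
            }
        )
        for i, (k, v) in enumerate(labels.items()):
            df.insert(i, k, v)
        return df


def km_curve(sample: LatencySample, percentiles: Sequence[int] = (25, 50, 75)) -> KMCurve:
    """Product-limit estimate of the cumulative fraction executing a step.

    Ties follow the standard convention (events at a time processed before
    censorings at that time).  A fully censored sample yields a curve flat at
    zero with all percentiles not reached (warning, not error).
    """
    if sample.n == 0:
        raise ValueError("empty latency sample")
    if not sample.observed.any():
        warnings.warn("all observations censored: curve is flat at 0", stacklevel=2)
    kmf = KaplanMeierFitter()
    kmf.fit(sample.times_s, event_observed=sample.observed)
    event_table = kmf.event_table
    mask = event_table["observed"] > 0
    times = event_table.index.to_numpy(dtype=float)[mask]
    at_risk = event_table["at_risk"].to_numpy(dtype=int)[mask]
    surv = kmf.survival_function_["KM_estimate"]
    fraction = 1.0 - np.array([float(surv.loc[t]) for t in times])
    pct: dict[int, float | None] = {}
    for q in percentiles:
        reached = np.nonzero(fraction >= q / 100.0 - 1e-12)[0]
        pct[int(q)] = float(times[reached[0]]) if reached.size else None
    return KMCurve(times, fraction, at_risk, pct)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_two_sided: float
    df: int = 1


def logrank_test(sample_a: LatencySample, sample_b: LatencySample) -> LogrankResult:
    """Two-group log-rank (Mantel-Cox) test, 1 df, two-sided p."""
    if sample_a.n == 0 or sample_b.n == 0:
        raise ValueError("both samples must be non-empty")
    res = _ll_logrank(
        sample_a.times_s,
        sample_b.times_s,
        event_observed_A=sample_a.observed,
        event_observed_B=sample_b.observed,
    )
    return LogrankResult(float(res.test_statistic), float(res.p_value), 1)


def multigroup_logrank_test(samples: Sequence[LatencySample]) -> LogrankResult:
    """k-group log-rank test with k - 1 df (for the satiety time-course)."""
    if len(samples) < 2 or any(s.n == 0 for s in samples):
        raise ValueError("need >= 2 non-empty samples")
    times = np.concatenate([s.times_s for s in samples])
    events = np.concatenate([s.observed for s in samples])
    groups = np.concatenate([np.full(s.n, i) for i, s in enumerate(samples)])
    res = _ll_multivariate_logrank(times, groups, events)
    return LogrankResult(float(res.test_statistic), float(res.p_value), len(samples) - 1)


@dataclass(frozen=True)
class FoldChange:
    """T50 ratio between conditions; undefined when a T50 is not reached."""

    ratio: float | None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def t50_fold_change(sample_num: LatencySample, sample_den: LatencySample) -> FoldChange:
    """Ratio of KM median crossing times T50(num)/T50(den) (e.g. fed/starved)."""
    t50s = []
    for label, sample in (("numerator", sample_num), ("denominator", sample_den)):
        t50 = km_curve(sample, percentiles=(50,)).percentile_times[50]
        if t50 is None:
            return FoldChange(None, f"T50 not reached in {label} sample")
        t50s.append(t50)
    if t50s[1] == 0:
        return FoldChange(None, "denominator T50 is zero")
    return FoldChange(t50s[0] / t50s[1])


def adjacent_timing_correlation(
    timings: Iterable[TimingRecord],
    pair: tuple[tuple[FeedingStep, str], tuple[FeedingStep, str]],
) -> dict:
    """Spearman correlation between two timing quantities of adjacent steps.

    ``pair`` names two (step, quantity) items, quantity in {"latency",
    "duration"}; values are matched by observation and restricted to
    observations where both are uncensored.  Requires >= 3 pairs.
    """
    def value(rec: TimingRecord, quantity: str) -> float | None:
        if rec.censored:
            return None
        if quantity == "latency":
            return rec.latency_s
        if quantity == "duration":
            return rec.duration_s
        raise ValueError(f"unknown quantity {quantity!r}")

    (step_x, qty_x), (step_y, qty_y) = pair
    by_obs: dict[str, dict[int, float]] = {}
    for rec in timings:
        for i, (step, qty) in enumerate(((step_x, qty_x), (step_y, qty_y))):
            if rec.step is step:
                v = value(rec, qty)
                if v is not None:
                    by_obs.setdefault(rec.observation_id, {})[i] = v
    xs = [d[0] for d in by_obs.values() if 0 in d and 1 in d]
    ys = [d[1] for d in by_obs.values() if 0 in d and 1 in d]
    if len(xs) < 3:
        raise ValueError(f"need >= 3 doubly-uncensored pairs, got {len(xs)}")
    rho, p = stats.spearmanr(xs, ys)
    return {"rho": float(rho), "p": float(p), "n_pairs": len(xs)}
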