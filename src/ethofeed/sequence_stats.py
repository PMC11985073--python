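"""Transition probabilities, step/ingestion agreement, and consumption counts.

First-order statistics over the stereotyped feeding sequence: for each step,
the distribution of the *next* behavior executed (any strictly later
canonical step, or no further behavior within the window); the agreement
probability between each tentacle-mediated step and ingestion (fraction of
observations where both occurred or both failed); and per-animal prey
consumption out of the offered prey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ethogram_io import (
    CANONICAL_STEPS,
    NO_FURTHER_BEHAVIOR,
    FeedingStep,
    Observation,
)

PROBABILITY_TOL = 1e-12


@dataclass
class TransitionTable:
    """Outcome counts following one feeding step.

    Outcomes are every canonical step strictly later in rank than
    ``from_step`` (skip-ahead transitions such as paralyze → bend keep their
    own column) plus ``"none"`` for no further behavior within the window.
    """

    from_step: FeedingStep
    outcome_labels: list[str]
    counts: list[int]
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def probabilities(self) -> list[float]:
        n = self.n
        return [c / n for c in self.counts]

    def count_for(self, outcome: str) -> int:
        return self.counts[self.outcome_labels.index(outcome)]

    def probability_for(self, outcome: str) -> float:
        return self.count_for(outcome) / self.n

    @property
    def canonical_next(self) -> str:
        return CANONICAL_STEPS[self.from_step.rank + 1].value

    def two_by_two(self, other: "TransitionTable") -> np.ndarray:
        """Collapse two condition tables to 2x2: canonical-next vs all else."""
        if other.from_step is not self.from_step:
            raise ValueError("tables must share from_step")
        rows = []
        for t in (self, other):
            nxt = t.count_for(t.canonical_next)
            rows.append([nxt, t.n - nxt])
        return np.asarray(rows, dtype=int)

    def contingency(self, other: "TransitionTable") -> np.ndarray:
        """Full r x c outcome-count table for two conditions (for chi-square)."""
        if other.outcome_labels != self.outcome_labels:
            raise ValueError("tables must share outcome alphabet")
        return np.asarray([self.counts, other.counts], dtype=int)

    def merge(self, other: "TransitionTable") -> "TransitionTable":
        if other.outcome_labels != self.outcome_labels or other.from_step is not self.from_step:
            raise ValueError("incompatible tables")
        return TransitionTable(
            self.from_step,
            list(self.outcome_labels),
            [a + b for a, b in zip(self.counts, other.counts)],
            self.n_excluded + other.n_excluded,
        )

    def to_frame(self, condition: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "from_step": self.from_step.value,
                "outcome": self.outcome_labels,
                "count": self.counts,
                "probability": self.probabilities,
            }
        )
        if condition is not None:
            df.insert(0, "condition", condition)
        return df


def next_outcome(obs: Observation, from_step: FeedingStep) -> str:
    """The first canonical step executed after ``from_step``, or ``"none"``."""
    for step in CANONICAL_STEPS[from_step.rank + 1 :]:
        if obs.has_step(step):
            return step.value
    return NO_FURTHER_BEHAVIOR


def transition_matrix(
    observations: Sequence[Observation], from_step: FeedingStep
) -> TransitionTable:
    """Counts/probabilities of outcomes following ``from_step``.

    Observations that did not execute ``from_step`` are excluded (tallied in
    ``n_excluded``); an empty qualifying set raises rather than producing an
    empty-denominator table.
    """
    if from_step is FeedingStep.INGEST:
        raise ValueError("ingest is terminal: no outgoing transitions")
    labels = [s.value for s in CANONICAL_STEPS[from_step.rank + 1 :]] + [NO_FURTHER_BEHAVIOR]
    counts = dict.fromkeys(labels, 0)
    excluded = 0
    for obs in observations:
        if not obs.has_step(from_step):
            excluded += 1
            continue
        counts[next_outcome(obs, from_step)] += 1
    if sum(counts.values()) == 0:
        raise ValueError(f"no observation executed {from_step.value}")
    return TransitionTable(from_step, labels, [counts[l] for l in labels], excluded)


@dataclass
class AgreementResult:
    """Concordance between one tentacle-mediated step and ingestion.

    Occurrence is scored within the observation window, so a censored step
    counts as a failure.  ``table`` is the 2x2 occurrence table
    [[both, step-only], [ingest-only, neither]] for downstream testing.
    """

    step: FeedingStep
    n: int
    n_concordant: int
    table: np.ndarray = field(repr=False)

    @property
    def probability(self) -> float:
        return self.n_concordant / self.n


def agreement_probability(
    observations: Sequence[Observation], step: FeedingStep
) -> AgreementResult:
    """Agreement probability between ``step`` and ingestion."""
    if step not in (FeedingStep.PARALYZE, FeedingStep.TCR, FeedingStep.BEND):
        raise ValueError("agreement is defined for paralyze, tcr and bend")
    if len(observations) == 0:
        raise ValueError("no observations")
    table = np.zeros((2, 2), dtype=int)
    for obs in observations:
        s = obs.has_step(step)
        i = obs.has_step(FeedingStep.INGEST)
        table[0 if s else 1, 0 if i else 1] += 1
    concordant = int(table[0, 0] + table[1, 1])
    return AgreementResult(step, len(observations), concordant, table)


@dataclass(frozen=True)
class ConsumptionRecord:
    subject_id: str
    offered: int
    consumed: int

    def __post_init__(self) -> None:
        if not 0 <= self.consumed <= self.offered:
            raise ValueError("consumed must lie in [0, offered]")


def consumption_counts(observations: Sequence[Observation]) -> list[ConsumptionRecord]:
    """Prey consumed per subject (one offer = one observation)."""
    by_subject: dict[str, list[Observation]] = {}
    for obs in observations:
        by_subject.setdefault(obs.subject_id, []).append(obs)
    return [
        ConsumptionRecord(
            subject_id=sid,
            offered=len(group),
            consumed=sum(o.has_step(FeedingStep.INGEST) for o in group),
        )
        for sid, group in by_subject.items()
    ]


def consumption_summary(records: Iterable[ConsumptionRecord]) -> dict:
    """Mean ± SEM of consumed counts across subjects."""
    consumed = np.array([r.consumed for r in records], dtype=float)
    if consumed.size == 0:
        raise ValueError("no consumption records")
    sem = float(consumed.std(ddof=1) / np.sqrt(consumed.size)) if consumed.size > 1 else 0.0
    return {"n_subjects": int(consumed.size), "mean": float(consumed.mean()), "sem": sem}
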