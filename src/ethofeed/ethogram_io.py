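"""Data model, parsing, validation and timing extraction for behavioral event tables.

The feeding sequence of *Cladonema* jellyfish is a stereotyped five-step
program: prey **contact** (t = 0 by convention), prey **paralyze** (annotated
as the time point of paralysis completion), the tentacle contraction reflex
(**TCR**), tentacle **bend**, and prey **ingest**.  Annotated video
observations arrive as a long-format CSV, one row per behavioral event; this
module validates them against the sequence grammar (later steps require all
earlier steps), and converts each observation into latency / duration records
with right-censoring at the observation window (120 s per step by default).
"""

from __future__ import annotations

import enum
import io
import json
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import pandas as pd

#: Per-step observation window, seconds; each step is allowed this long from
#: its timing reference (contact for paralyze, the previous step's offset for
#: later steps) before it is scored as censored.
DEFAULT_WINDOW_S = 120.0

#: Post-meal time points (minutes) used in the satiety time-course protocol.
TIME_COURSE_MINUTES = (5, 10, 30, 60)

FEEDING_STATES = ("starved", "fed")
PREPARATIONS = ("intact", "manubrium_less", "tentacle_above_bulb", "tentacle_below_bulb")
TENTACLE_USES = ("na", "used", "unused")

#: Columns of the long-format event-table CSV dialect (header row, UTF-8).
EVENT_TABLE_COLUMNS = (
    "observation_id",
    "subject_id",
    "feeding_state",
    "preparation",
    "tentacle_use",
    "minutes_since_meal",
    "step",
    "onset_s",
    "offset_s",
)


class FeedingStep(enum.Enum):
    """The canonical behavioral alphabet, ordered by rank in the sequence."""

    CONTACT = "contact"
    PARALYZE = "paralyze"
    TCR = "tcr"
    BEND = "bend"
    INGEST = "ingest"

    @property
    def rank(self) -> int:
        return CANONICAL_STEPS.index(self)

    def __str__(self) -> str:  # CSV cell value
        return self.value


CANONICAL_STEPS: tuple[FeedingStep, ...] = (
    FeedingStep.CONTACT,
    FeedingStep.PARALYZE,
    FeedingStep.TCR,
    FeedingStep.BEND,
    FeedingStep.INGEST,
)

#: Label used for the "no further behavior" outcome in transition tables.
NO_FURTHER_BEHAVIOR = "none"


class GrammarError(ValueError):
    """An observation violates the stereotyped-sequence grammar."""


class TimingError(ValueError):
    """Event annotations produce an impossible timing (e.g. negative ISI)."""


@dataclass(frozen=True)
class BehavioralEvent:
    """One annotated behavior: onset (s since prey contact) and optional offset.

    Paralyze is annotated in the source videos as a single time point (the
    completion of paralysis), so its event carries only an onset.
    """

    step: FeedingStep
    onset_s: float
    offset_s: float | None = None

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.offset_s is not None and self.offset_s < self.onset_s:
            raise ValueError(
                f"offset_s ({self.offset_s}) precedes onset_s ({self.onset_s}) for {self.step}"
            )

    @property
    def reference_offset_s(self) -> float:
        """Timing reference this event provides to the next step."""
        return self.offset_s if self.offset_s is not None else self.onset_s


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition of an observation.

    ``minutes_since_meal`` applies only to the post-meal time-course protocol
    on fed animals (5/10/30/60 min between the meal and tentacle dissection).
    """

    feeding_state: str = "starved"
    preparation: str = "intact"
    tentacle_use: str = "na"
    minutes_since_meal: int | None = None

    def __post_init__(self) -> None:
        if self.feeding_state not in FEEDING_STATES:
            raise ValueError(f"unknown feeding_state {self.feeding_state!r}")
        if self.preparation not in PREPARATIONS:
            raise ValueError(f"unknown preparation {self.preparation!r}")
        if self.tentacle_use not in TENTACLE_USES:
            raise ValueError(f"unknown tentacle_use {self.tentacle_use!r}")
        if self.minutes_since_meal is not None and self.feeding_state != "fed":
            raise ValueError("minutes_since_meal requires feeding_state='fed'")

    def matches(self, **criteria) -> bool:
        for key, value in criteria.items():
            if not hasattr(self, key):
                raise KeyError(f"unknown condition field {key!r}")
            if getattr(self, key) != value:
                return False
        return True


@dataclass
class Observation:
    """One prey-offer episode on one animal or tentacle.

    Events are kept sorted by onset; ``validate`` enforces the sequence
    grammar: contact present at t = 0, at most one event per step, and the
    executed steps forming a rank prefix of the canonical order.
    """

    observation_id: str
    subject_id: str
    condition: ConditionLabel
    events: list[BehavioralEvent] = field(default_factory=list)
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.onset_s, e.step.rank))

    def validate(self) -> None:
        steps = [e.step for e in self.events]
        if len(set(steps)) != len(steps):
            dupes = sorted({s.value for s in steps if steps.count(s) > 1})
            raise GrammarError(f"duplicate step(s) {dupes} in observation {self.observation_id}")
        ranks = sorted(s.rank for s in steps)
        if FeedingStep.CONTACT not in steps:
            raise GrammarError(f"observation {self.observation_id} lacks a contact event")
        if ranks != list(range(len(ranks))):
            missing = [
                CANONICAL_STEPS[r].value for r in range(max(ranks) + 1) if r not in ranks
            ]
            raise GrammarError(
                f"observation {self.observation_id} executes later steps without {missing}"
            )
        contact = self.event_for(FeedingStep.CONTACT)
        if contact.onset_s != 0:
            raise GrammarError(
                f"observation {self.observation_id}: contact must be at t=0, got {contact.onset_s}"
            )

    def has_step(self, step: FeedingStep) -> bool:
        return any(e.step is step for e in self.events)

    def event_for(self, step: FeedingStep) -> BehavioralEvent:
        for e in self.events:
            if e.step is step:
                return e
        raise KeyError(f"no {step.value} event in observation {self.observation_id}")

    def executed_steps(self) -> list[FeedingStep]:
        return [s for s in CANONICAL_STEPS if self.has_step(s)]


@dataclass(frozen=True)
class TimingRecord:
    """Latency and duration of one step within one observation.

    ``latency_s`` is measured from the step's timing reference: prey contact
    for paralyze (so paralyze latency is what field annotations call the
    "paralyze duration"), the previous step's offset for TCR/bend/ingest (the
    inter-step interval, ISI).  Censored records carry latency equal to the
    window and no duration.
    """

    observation_id: str
    step: FeedingStep
    latency_s: float
    duration_s: float | None
    censored: bool

    def __post_init__(self) -> None:
        if self.censored and self.duration_s is not None:
            raise ValueError("censored records carry no duration")


@dataclass
class ParseReport:
    """Bookkeeping from :func:`parse_event_table`."""

    n_rows: int = 0
    n_observations: int = 0
    rejected_rows: list[dict] = field(default_factory=list)
    rejected_observations: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_rows": self.n_rows,
                "n_observations": self.n_observations,
                "rejected_rows": self.rejected_rows,
                "rejected_observations": self.rejected_observations,
            },
            indent=2,
            sort_keys=True,
        )


def _parse_condition(row: pd.Series) -> ConditionLabel:
    minutes = row.get("minutes_since_meal")
    if minutes is None or (isinstance(minutes, float) and pd.isna(minutes)) or minutes == "":
        minutes = None
    else:
        minutes = int(minutes)
    return ConditionLabel(
        feeding_state=str(row.get("feeding_state", "starved")),
        preparation=str(row.get("preparation", "intact")),
        tentacle_use=str(row.get("tentacle_use", "na")),
        minutes_since_meal=minutes,
    )


def parse_event_table(
    source, window_s: float = DEFAULT_WINDOW_S
) -> tuple[list[Observation], ParseReport]:
    """Parse a long-format event table into validated Observations.

    ``source`` may be a file path, an open text buffer, or a DataFrame with
    the documented columns.  Malformed rows (unknown step, offset < onset,
    unparseable numbers) are rejected row-wise; observations violating the
    sequence grammar (duplicate steps, later steps without earlier ones) are
    rejected whole.  Both kinds of rejection are recorded in the returned
    :class:`ParseReport` for audit, never silently repaired.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, dtype={"observation_id": str, "subject_id": str})
    if df.empty:
        raise ValueError("event table is empty")
    missing = {"observation_id", "step", "onset_s"} - set(df.columns)
    if missing:
        raise ValueError(f"event table lacks required columns: {sorted(missing)}")

    report = ParseReport(n_rows=len(df))
    known_steps = {s.value: s for s in CANONICAL_STEPS}
    rows_by_obs: dict[str, list] = {}
    meta_by_obs: dict[str, pd.Series] = {}

    for idx, row in df.iterrows():
        step_label = str(row["step"])
        if step_label not in known_steps:
            report.rejected_rows.append(
                {"row": int(idx), "reason": f"unknown step label {step_label!r}"}
            )
            continue
        try:
            onset = float(row["onset_s"])
            offset_raw = row.get("offset_s")
            offset = (
                None
                if offset_raw is None or (isinstance(offset_raw, float) and pd.isna(offset_raw)) or offset_raw == ""
                else float(offset_raw)
            )
            event = BehavioralEvent(known_steps[step_label], onset, offset)
        except (TypeError, ValueError) as exc:
            report.rejected_rows.append({"row": int(idx), "reason": str(exc)})
            continue
        obs_id = str(row["observation_id"])
        rows_by_obs.setdefault(obs_id, []).append(event)
        meta_by_obs.setdefault(obs_id, row)

    observations: list[Observation] = []
    for obs_id, events in rows_by_obs.items():
        meta = meta_by_obs[obs_id]
        try:
            condition = _parse_condition(meta)
            obs = Observation(
                observation_id=obs_id,
                subject_id=str(meta.get("subject_id", obs_id)),
                condition=condition,
                events=events,
                window_s=window_s,
            )
            obs.validate()
        except (GrammarError, ValueError) as exc:
            report.rejected_observations.append({"observation_id": obs_id, "reason": str(exc)})
            continue
        observations.append(obs)
    report.n_observations = len(observations)
    return observations, report


def write_event_table(observations: Iterable[Observation], path=None) -> pd.DataFrame:
    """Serialize Observations back to the long CSV dialect (round-trip safe)."""
    rows = []
    for obs in observations:
        c = obs.condition
        for e in obs.events:
            rows.append(
                {
                    "observation_id": obs.observation_id,
                    "subject_id": obs.subject_id,
                    "feeding_state": c.feeding_state,
                    "preparation": c.preparation,
                    "tentacle_use": c.tentacle_use,
                    "minutes_since_meal": c.minutes_since_meal,
                    "step": e.step.value,
                    "onset_s": e.onset_s,
                    "offset_s": e.offset_s,
                }
            )
    df = pd.DataFrame(rows, columns=list(EVENT_TABLE_COLUMNS))
    if path is not None:
        df.to_csv(path, index=False)
    return df


def extract_timings(obs: Observation) -> list[TimingRecord]:
    """Latency/duration records for every step of one grammar-valid observation.

    The first step not executed (or executed beyond the window from its
    reference) yields a censored record with latency = window; steps after it
    have no timing reference and yield nothing.  A negative inter-step
    interval (overlapping annotations) raises :class:`TimingError`.
    """
    obs.validate()
    records: list[TimingRecord] = []
    reference = obs.event_for(FeedingStep.CONTACT).reference_offset_s
    for step in CANONICAL_STEPS[1:]:
        if not obs.has_step(step):
            records.append(TimingRecord(obs.observation_id, step, obs.window_s, None, True))
            break
        event = obs.event_for(step)
        latency = event.onset_s - reference
        if latency < 0:
            raise TimingError(
                f"observation {obs.observation_id}: {step.value} onset ({event.onset_s}s) "
                f"precedes the previous step's offset ({reference}s)"
            )
        if latency > obs.window_s:
            # executed, but outside the per-step window: scored as censored
            records.append(TimingRecord(obs.observation_id, step, obs.window_s, None, True))
            break
        duration = None
        if step is not FeedingStep.PARALYZE and event.offset_s is not None:
            duration = event.offset_s - event.onset_s
        records.append(TimingRecord(obs.observation_id, step, latency, duration, False))
        reference = event.reference_offset_s
    return records


def filter_observations(
    observations: Sequence[Observation],
    predicate: Callable[[ConditionLabel], bool] | None = None,
    **criteria,
) -> list[Observation]:
    """Order-preserving subset by condition.

    Either pass a callable over :class:`ConditionLabel`, or keyword criteria
    (``feeding_state="starved"``); unknown criterion fields raise KeyError.
    With neither, the list is returned unchanged.
    """
    if predicate is None and not criteria:
        return list(observations)
    if predicate is not None:
        return [o for o in observations if predicate(o.condition)]
    return [o for o in observations if o.condition.matches(**criteria)]
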