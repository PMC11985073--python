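"""Semi-Markov generator of synthetic feeding observations.

Each observation starts with prey contact at t = 0 and advances through the
canonical steps (paralyze, TCR, bend, ingest).  Given its predecessor was
executed, a step is *ever executed* with per-step probability π; when it is,
its latency from the timing reference is drawn from a positive-support
distribution (log-normal by default, parameterized by its median and
log-scale σ), and — for steps with extent — a duration is drawn likewise.
A step whose success draw fails, or whose drawn latency exceeds the
observation window, terminates the sequence (the step and everything
downstream are right-censored).  Censoring is therefore emergent (slow
responders) as well as explicit (never-responders), matching the plateaus of
real cumulative-fraction curves.

Satiety is encoded as the ground truth the analysis pipeline must recover:
fed presets lower the transition probabilities π and lengthen latency
medians (paralyze 2x, TCR 5x) but leave executed-step durations untouched.
Time-course presets (5/10/30/60 min post-meal, severed tentacles) apply the
TCR inhibition from 5 min onward while the paralyze inhibition appears only
at 60 min.

Reproducibility: a dataset is generated from a single integer seed; each
subject receives a deterministically spawned child stream, so the same
(config, seed) yields bit-identical tables regardless of how many other
subjects are simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .ethogram_io import (
    CANONICAL_STEPS,
    DEFAULT_WINDOW_S,
    BehavioralEvent,
    ConditionLabel,
    FeedingStep,
    Observation,
)

#: Steps subject to the success/latency draw (contact is given).
PROGRESSION_STEPS = CANONICAL_STEPS[1:]
#: Steps with an annotated extent (paralyze is a completion time point).
DURATION_STEPS = (FeedingStep.TCR, FeedingStep.BEND, FeedingStep.INGEST)

LATENCY_FAMILIES = ("lognormal", "exponential", "gamma")


def _draw_positive(rng: np.random.Generator, family: str, median: float, sigma: float) -> float:
    """One draw from a positive distribution parameterized by its median.

    For the log-normal, ``sigma`` is the log-scale; for the exponential it is
    ignored (the median alone fixes the rate); for the gamma it sets the
    shape as 1/sigma**2 with the scale solved so the median matches.
    """
    if family == "lognormal":
        return float(np.exp(np.log(median) + sigma * rng.standard_normal()))
    if family == "exponential":
        return float(rng.exponential(median / np.log(2.0)))
    if family == "gamma":
        from scipy.stats import gamma as _gamma

        shape = 1.0 / sigma**2
        scale = median / _gamma.ppf(0.5, shape)
        return float(rng.gamma(shape, scale))
    raise ValueError(f"unknown latency family {family!r}")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the semi-Markov feeding generator.

    ``success``, ``latency_median_s``, ``latency_sigma`` are keyed by the
    progression steps; ``duration_median_s`` / ``duration_sigma`` by the
    steps with extent.  Medians are in seconds.
    """

    success: dict[FeedingStep, float]
    latency_median_s: dict[FeedingStep, float]
    latency_sigma: dict[FeedingStep, float]
    duration_median_s: dict[FeedingStep, float]
    duration_sigma: dict[FeedingStep, float]
    condition: ConditionLabel = ConditionLabel()
    window_s: float = DEFAULT_WINDOW_S
    offers_per_subject: int = 5
    n_subjects: int = 19
    latency_family: str = "lognormal"
    preset_name: str = "custom"

    def __post_init__(self) -> None:
        for step in PROGRESSION_STEPS:
            p = self.success.get(step)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"success probability for {step.value} must be in [0,1]")
            if self.success[step] > 0 and (
                step not in self.latency_median_s or self.latency_median_s[step] <= 0
            ):
                raise ValueError(f"latency median for {step.value} must be > 0")
        for step, m in self.duration_median_s.items():
            if m <= 0:
                raise ValueError(f"duration median for {step.value} must be > 0")
        if self.latency_family not in LATENCY_FAMILIES:
            raise ValueError(f"latency_family must be one of {LATENCY_FAMILIES}")
        if self.window_s <= 0 or self.offers_per_subject < 1 or self.n_subjects < 1:
            raise ValueError("window_s > 0, offers_per_subject >= 1, n_subjects >= 1 required")

    def truth(self) -> dict:
        """Generator ground truth, JSON-serializable, for recovery tests."""
        return {
            "preset_name": self.preset_name,
            "latency_family": self.latency_family,
            "window_s": self.window_s,
            "offers_per_subject": self.offers_per_subject,
            "n_subjects": self.n_subjects,
            "success": {s.value: self.success[s] for s in PROGRESSION_STEPS},
            "latency_median_s": {
                s.value: self.latency_median_s.get(s) for s in PROGRESSION_STEPS
            },
            "latency_sigma": {s.value: self.latency_sigma.get(s) for s in PROGRESSION_STEPS},
            "duration_median_s": {s.value: m for s, m in self.duration_median_s.items()},
            "duration_sigma": {s.value: m for s, m in self.duration_sigma.items()},
            "condition": dataclasses.asdict(self.condition),
        }


def simulate_observation(
    config: SimConfig,
    rng: np.random.Generator,
    observation_id: str = "obs",
    subject_id: str = "subject",
) -> Observation:
    """Simulate one prey-offer episode."""
    events = [BehavioralEvent(FeedingStep.CONTACT, 0.0, 0.0)]
    reference = 0.0
    for step in PROGRESSION_STEPS:
        if rng.random() >= config.success[step]:
            break
        latency = _draw_positive(
            rng, config.latency_family, config.latency_median_s[step], config.latency_sigma[step]
        )
        if latency > config.window_s:
            break
        onset = reference + latency
        if step in config.duration_median_s:
            duration = _draw_positive(
                rng, config.latency_family, config.duration_median_s[step], config.duration_sigma[step]
            )
            events.append(BehavioralEvent(step, onset, onset + duration))
            reference = onset + duration
        else:
            events.append(BehavioralEvent(step, onset))
            reference = onset
    return Observation(observation_id, subject_id, config.condition, events, config.window_s)


def simulate_dataset(
    config_or_preset: SimConfig | str,
    n_subjects: int | None = None,
    seed: int = 0,
) -> tuple[list[Observation], dict]:
    """Simulate a full dataset: ``offers_per_subject`` observations per subject.

    Returns the observations together with the generator truth record.
    Subject sub-streams are spawned deterministically from the seed.
    """
    config = get_preset(config_or_preset) if isinstance(config_or_preset, str) else config_or_preset
    if n_subjects is not None:
        config = replace(config, n_subjects=n_subjects)
    streams = np.random.SeedSequence(seed).spawn(config.n_subjects)
    observations: list[Observation] = []
    for si, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        subject = f"{config.preset_name}-s{si:03d}"
        for oi in range(config.offers_per_subject):
            observations.append(
                simulate_observation(config, rng, f"{subject}-o{oi}", subject)
            )
    truth = config.truth()
    truth["seed"] = seed
    truth["n_observations"] = len(observations)
    return observations, truth


# ---------------------------------------------------------------------------
# Preset library
# ---------------------------------------------------------------------------

_P, _T, _B, _I = (
    FeedingStep.PARALYZE,
    FeedingStep.TCR,
    FeedingStep.BEND,
    FeedingStep.INGEST,
)

# Executed-step durations are condition-invariant: satiety prolongs latencies
# (step initiation) but not the motor programs themselves.
_DURATIONS = {_T: 2.5, _B: 4.0, _I: 30.0}
_DURATION_SIGMA = {_T: 0.4, _B: 0.4, _I: 0.5}

_STARVED_SUCCESS = {_P: 0.92, _T: 0.96, _B: 0.97, _I: 0.97}
_STARVED_MEDIAN = {_P: 4.0, _T: 2.0, _B: 3.0, _I: 5.0}
_LATENCY_SIGMA = {_P: 0.5, _T: 0.5, _B: 0.6, _I: 0.6}

_FED_SUCCESS = {_P: 0.80, _T: 0.65, _B: 0.75, _I: 0.60}
# paralyze 2x, TCR 5x, bend/ingest 2.5x slower after a meal
_FED_MEDIAN = {_P: 8.0, _T: 10.0, _B: 7.5, _I: 12.5}

#: Observation counts per satiety time-course arm (starved, 5, 10, 30, 60 min).
TIME_COURSE_N = {None: 87, 5: 62, 10: 74, 30: 67, 60: 64}


def _config(success, medians, condition, *, n_subjects, offers=5, name="custom", no_ingest=False, bend_success=None):
    success = dict(success)
    if bend_success is not None:
        success[_B] = bend_success
    if no_ingest:
        success[_I] = 0.0
    return SimConfig(
        success=success,
        latency_median_s=dict(medians),
        latency_sigma=dict(_LATENCY_SIGMA),
        duration_median_s=dict(_DURATIONS),
        duration_sigma=dict(_DURATION_SIGMA),
        condition=condition,
        n_subjects=n_subjects,
        offers_per_subject=offers,
        preset_name=name,
    )


def _time_course_config(minutes: int | None, n: int) -> SimConfig:
    # Severed tentacles: no manubrium, so bend/ingest are absent; TCR
    # inhibition appears from 5 min post-meal, paralyze only at 60 min.
    par_success = {None: 0.92, 5: 0.88, 10: 0.88, 30: 0.85, 60: 0.80}[minutes]
    tcr_success = {None: 0.95, 5: 0.80, 10: 0.78, 30: 0.75, 60: 0.72}[minutes]
    par_median = 8.0 if minutes == 60 else 4.0
    tcr_median = 2.0 if minutes is None else 10.0
    if minutes is None:
        condition = ConditionLabel("starved", "tentacle_below_bulb")
        name = "tc_starved"
    else:
        condition = ConditionLabel("fed", "tentacle_below_bulb", minutes_since_meal=minutes)
        name = f"fed_tc_{minutes}"
    return _config(
        {_P: par_success, _T: tcr_success, _B: 0.0, _I: 0.0},
        {_P: par_median, _T: tcr_median, _B: 3.0, _I: 5.0},
        condition,
        n_subjects=n,
        offers=1,
        name=name,
    )


def _build_presets() -> dict[str, SimConfig]:
    presets: dict[str, SimConfig] = {}
    presets["starved"] = _config(
        _STARVED_SUCCESS, _STARVED_MEDIAN, ConditionLabel("starved"), n_subjects=19, name="starved"
    )
    presets["fed"] = _config(
        _FED_SUCCESS, _FED_MEDIAN, ConditionLabel("fed"), n_subjects=18, name="fed"
    )
    # tentacle-targeted feeding: whole animals are starved-state; previously
    # "used" tentacles paralyze marginally faster (sensitization).
    presets["unused_tentacle"] = _config(
        _STARVED_SUCCESS,
        _STARVED_MEDIAN,
        ConditionLabel("starved", tentacle_use="unused"),
        n_subjects=16,
        name="unused_tentacle",
    )
    used_median = {**_STARVED_MEDIAN, _P: 3.2}
    presets["used_tentacle"] = _config(
        {**_STARVED_SUCCESS, _P: 0.95},
        used_median,
        ConditionLabel("starved", tentacle_use="used"),
        n_subjects=14,
        name="used_tentacle",
    )
    # manubrium resection: tentacle steps intact, ingestion impossible.
    for state, success, medians, n in (
        ("starved", _STARVED_SUCCESS, _STARVED_MEDIAN, 9),
        ("fed", _FED_SUCCESS, _FED_MEDIAN, 6),
    ):
        presets[f"manubrium_less_{state}"] = _config(
            success,
            medians,
            ConditionLabel(state, "manubrium_less"),
            n_subjects=n,
            name=f"manubrium_less_{state}",
            no_ingest=True,
        )
    # severed tentacles (above/below the bulb): paralyze and TCR observable,
    # no bend/ingest; the satiety effect persists in both preparations.
    for prep, n_starved, n_fed in (
        ("tentacle_above_bulb", 40, 28),
        ("tentacle_below_bulb", 113, 95),
    ):
        for state, success, medians, n in (
            ("starved", _STARVED_SUCCESS, _STARVED_MEDIAN, n_starved),
            ("fed", _FED_SUCCESS, _FED_MEDIAN, n_fed),
        ):
            presets[f"{prep}_{state}"] = _config(
                {_P: success[_P], _T: success[_T], _B: 0.0, _I: 0.0},
                medians,
                ConditionLabel(state, prep),
                n_subjects=n,
                offers=1,
                name=f"{prep}_{state}",
            )
    # satiety time-course on severed tentacles
    presets["tc_starved"] = _time_course_config(None, TIME_COURSE_N[None])
    for minutes in (5, 10, 30, 60):
        presets[f"fed_tc_{minutes}"] = _time_course_config(minutes, TIME_COURSE_N[minutes])
    return presets


PRESETS: dict[str, SimConfig] = _build_presets()


def get_preset(name: str) -> SimConfig:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
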