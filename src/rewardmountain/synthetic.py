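"""Synthetic pseudo-sweep designs and simulated operant sessions.

No behavioural data are distributed with this package, so validation rests
on simulation: a ground-truth mountain surface stands in for a subject, and
the sampling design reproduces the study structure — three pseudo-sweeps
(frequency, price, radial) of nine log-equispaced points per train
duration, two train durations (0.25 s and 1 s), the five central points of
each sweep sampled twice per survey and the four extremes once, trial order
drawn without replacement from a virtual urn, and eight surveys in total
(so 16 replicates per central point and 8 per extreme point).

Two simulators are provided.  :func:`simulate_observations` draws time
allocations directly from a bounded (beta) noise law centred on the
ground-truth surface.  :func:`simulate_trial_events` goes one level deeper
and emits time-stamped lever-event streams from a two-state work/leisure
dwell process, including reward deliveries, blackout delays, and flanking
bracket trials, so the trial-metrics code can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mountain import (
    DualMountainParams,
    SingleMountainParams,
    StimulusPoint,
    time_allocation,
)
from .transforms import DEFAULT_TRANSFORMS, TransformParams
from .trial_metrics import LeverEvent, TrialRecord

__all__ = [
    "PseudoSweep",
    "SurveySchedule",
    "GroundTruth",
    "BehaviorPolicy",
    "SWEEP_TYPES",
    "N_POINTS",
    "CENTRAL_INDICES",
    "EXTREME_INDICES",
    "build_pseudo_sweeps",
    "build_survey_schedule",
    "simulate_observations",
    "simulate_trial_events",
]

SWEEP_TYPES = ("frequency", "price", "radial")
N_POINTS = 9
CENTRAL_INDICES = (2, 3, 4, 5, 6)   # sampled twice per survey
EXTREME_INDICES = (0, 1, 7, 8)      # sampled once per survey


@dataclass(frozen=True)
class PseudoSweep:
    """Nine log-equispaced (pulse frequency, price) points along a line."""

    sweep_type: str
    points: tuple[tuple[float, float], ...]
    train_duration: float

    def __post_init__(self) -> None:
        if self.sweep_type not in SWEEP_TYPES:
            raise ValueError(f"unknown sweep type {self.sweep_type!r}")
        if len(self.points) != N_POINTS:
            raise ValueError(f"a pseudo-sweep has exactly {N_POINTS} points")


@dataclass(frozen=True)
class SurveySchedule:
    """Trial-by-trial sampling schedule over one or more surveys.

    ``entries`` is a long-format table, one row per scheduled test trial,
    in presentation order, with columns ``survey``, ``sweep_type``,
    ``train_duration_s``, ``point_index``, ``pulse_frequency_pps``,
    ``price_s``.
    """

    entries: pd.DataFrame
    n_surveys: int
    rng_seed: int

    def point_counts(self) -> pd.DataFrame:
        """Scheduled observation count per design point."""
        return (
            self.entries.groupby(
                ["sweep_type", "train_duration_s", "point_index"], as_index=False
            )
            .size()
            .rename(columns={"size": "n_scheduled"})
        )


@dataclass(frozen=True)
class GroundTruth:
    """A known surface plus noise settings, standing in for one subject."""

    model: SingleMountainParams | DualMountainParams
    tp: TransformParams = DEFAULT_TRANSFORMS
    noise_concentration: float = 40.0
    n_surveys: int = 8
    heteroscedastic: bool = False
    het_strength: float = 2.0
    subject: str = "synthetic"

    def __post_init__(self) -> None:
        if self.noise_concentration <= 0:
            raise ValueError("noise_concentration must be positive")


def build_pseudo_sweeps(
    f_hm: float,
    p_e: float,
    duration: float,
    f_span_decades: float = 1.0,
    p_span_decades: float = 1.0,
    low_price: float = 3.5,
    high_frequency: float = 310.0,
) -> list[PseudoSweep]:
    """The three pseudo-sweeps surveying the mountain at one train duration.

    The frequency sweep runs parallel to the pulse-frequency axis at a low
    constant price; the price sweep runs parallel to the price axis at a
    high constant frequency; the radial sweep runs diagonally from (high
    frequency, low price) to (low frequency, high price) through the
    location point (``f_hm``, ``p_e``) in log-log space.  Spans are total
    widths in decades, centred on the location parameters so that the end
    points of each sweep sit on the behavioural asymptotes.
    """
    if f_hm <= 0 or p_e <= 0 or low_price <= 0 or high_frequency <= 0:
        raise ValueError("center and anchor values must be positive")
    if f_span_decades <= 0 or p_span_decades <= 0:
        raise ValueError("spans must be positive")

    freqs = np.geomspace(
        f_hm * 10 ** (-f_span_decades / 2), f_hm * 10 ** (f_span_decades / 2), N_POINTS
    )
    prices = np.geomspace(
        p_e * 10 ** (-p_span_decades / 2), p_e * 10 ** (p_span_decades / 2), N_POINTS
    )
    freq_sweep = PseudoSweep(
        "frequency", tuple((float(f), float(low_price)) for f in freqs), duration
    )
    price_sweep = PseudoSweep(
        "price", tuple((float(high_frequency), float(p)) for p in prices), duration
    )
    # radial: frequency descends while price ascends; index 4 is (f_hm, p_e)
    radial = PseudoSweep(
        "radial",
        tuple((float(f), float(p)) for f, p in zip(freqs[::-1], prices)),
        duration,
    )
    return [freq_sweep, price_sweep, radial]


def build_survey_schedule(
    sweeps: list[PseudoSweep], n_surveys: int = 8, seed: int = 0
) -> SurveySchedule:
    """Randomised without-replacement schedule over the six pseudo-sweeps.

    Within each survey the urn holds every sweep point once (extremes) or
    twice (the five central points) for all six sweeps — 84 trials — and is
    emptied in a seeded uniform random order.  Different surveys use
    independent child random streams of the root seed.
    """
    if len(sweeps) != 6:
        raise ValueError(f"expected 6 pseudo-sweeps (3 per train duration), got {len(sweeps)}")
    durations = sorted({s.train_duration for s in sweeps})
    if len(durations) != 2:
        raise ValueError("the six sweeps must cover exactly two train durations")

    urn = []
    for sweep in sweeps:
        for idx, (f, p) in enumerate(sweep.points):
            weight = 2 if idx in CENTRAL_INDICES else 1
            urn.extend(
                [(sweep.sweep_type, sweep.train_duration, idx, f, p)] * weight
            )

    children = np.random.SeedSequence(seed).spawn(n_surveys)
    rows = []
    for survey, child in enumerate(children):
        rng = np.random.default_rng(child)
        for j in rng.permutation(len(urn)):
            sweep_type, dur, idx, f, p = urn[j]
            rows.append(
                {
                    "survey": survey,
                    "sweep_type": sweep_type,
                    "train_duration_s": dur,
                    "point_index": idx,
                    "pulse_frequency_pps": f,
                    "price_s": p,
                }
            )
    return SurveySchedule(entries=pd.DataFrame(rows), n_surveys=n_surveys, rng_seed=seed)


def _surface_ta(truth: GroundTruth, f: float, p: float, d: float) -> float:
    return time_allocation(StimulusPoint(f, p, d), truth.model, truth.tp)


def _draw_bounded(rng: np.random.Generator, mu: float, truth: GroundTruth) -> float:
    """One beta draw with mean ``mu`` and the truth's concentration."""
    mu = float(np.clip(mu, 1e-4, 1.0 - 1e-4))
    kappa = truth.noise_concentration
    if truth.heteroscedastic:
        # extra dispersion on the rising portion, where real performance is
        # most variable; asymptotes keep the nominal concentration
        kappa = kappa / (1.0 + truth.het_strength * 4.0 * mu * (1.0 - mu))
    return float(rng.beta(mu * kappa, (1.0 - mu) * kappa))


def simulate_observations(
    truth: GroundTruth, schedule: SurveySchedule, seed: int = 0
) -> pd.DataFrame:
    """Draw a tidy observation table from the ground truth along a schedule.

    One row per scheduled trial, in schedule order, with the observation
    CSV schema (subject, train_duration_s, pulse_frequency_pps, price_s,
    sweep_type, survey, time_allocation).  Reproducible: the same seed
    yields an identical table.
    """
    children = np.random.SeedSequence(seed).spawn(schedule.n_surveys)
    rngs = {s: np.random.default_rng(c) for s, c in enumerate(children)}
    rows = []
    for rec in schedule.entries.itertuples(index=False):
        mu = _surface_ta(
            truth, rec.pulse_frequency_pps, rec.price_s, rec.train_duration_s
        )
        ta = _draw_bounded(rngs[rec.survey], mu, truth)
        rows.append(
            {
                "subject": truth.subject,
                "train_duration_s": rec.train_duration_s,
                "pulse_frequency_pps": rec.pulse_frequency_pps,
                "price_s": rec.price_s,
                "sweep_type": rec.sweep_type,
                "survey": rec.survey,
                "time_allocation": ta,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BehaviorPolicy:
    """Work/leisure dwell policy of the event-level simulator.

    Work bouts are exponential with mean ``mean_work_bout`` (s); leisure
    bouts are 1 s plus an exponential tail, so that no leisure bout can be
    misread as a tap, and their mean is set per trial so the stationary
    work fraction equals the target time allocation.  When that would
    require leisure bouts longer than ``max_leisure_bout`` (poor mixing on
    short trials), the work bouts are shortened instead, preserving the
    work fraction.  ``n_rewards`` sizes the trial: lever-available time is
    ``n_rewards`` x price.
    """

    mean_work_bout: float = 8.0
    max_leisure_bout: float = 20.0
    n_rewards: int = 25
    blackout: float = 2.0
    tap_threshold: float = 1.0
    always_work_above: float = 0.98
    leading_bracket_ta: float = 0.95
    trailing_bracket_ta: float = 0.05
    bracket_frequency_high: float = 400.0
    bracket_frequency_low: float = 10.0
    bracket_price: float = 1.0
    bracket_duration: float = 0.5
    include_brackets: bool = True


def _simulate_one_trial(
    rng: np.random.Generator,
    target_ta: float,
    stimulus: StimulusPoint,
    policy: BehaviorPolicy,
    trial_id: str,
    role: str,
    survey: int,
    subject: str,
) -> TrialRecord:
    """Emit one trial's lever events from the two-state dwell process."""
    available_total = policy.n_rewards * stimulus.price
    price = stimulus.price
    always = target_ta >= policy.always_work_above
    if not always:
        ta = float(np.clip(target_ta, 1e-3, policy.always_work_above))
        # leisure bouts are 1 s + exponential tail; pick bout means so the
        # stationary work fraction is ta while keeping both bouts short
        # enough to mix within a trial
        mean_work = policy.mean_work_bout
        mean_leisure = mean_work * (1.0 - ta) / ta
        if mean_leisure > policy.max_leisure_bout:
            mean_leisure = policy.max_leisure_bout
            mean_work = mean_leisure * ta / (1.0 - ta)
        if mean_leisure < 1.0:
            mean_leisure = 1.0
            mean_work = ta / (1.0 - ta)
        mean_leisure_tail = mean_leisure - 1.0
        working = bool(rng.random() < ta)
    else:
        working = True

    events: list[LeverEvent] = []
    t = 0.0                 # wall-clock time inside the trial
    available = 0.0         # lever-available time consumed
    held_since: float | None = None
    hold_accum = 0.0        # cumulative hold since the last reward
    n_rewards = 0

    def remaining() -> float:
        return available_total - available

    while remaining() > 1e-12:
        if working or always:
            if held_since is None:
                events.append(LeverEvent(t, "press"))
                held_since = t
            bout = float(rng.exponential(mean_work)) if not always else math.inf
            # the bout may be cut by a reward or by trial end
            span = min(bout, remaining())
            to_reward = price - hold_accum
            if to_reward <= span:
                # reward fires mid-bout: release, blackout, resume
                t += to_reward
                available += to_reward
                events.append(LeverEvent(t, "reward_delivered"))
                events.append(LeverEvent(t, "release"))
                held_since = None
                hold_accum = 0.0
                n_rewards += 1
                t += policy.blackout  # lever retracted; availability clock paused
                if remaining() > 1e-12:
                    events.append(LeverEvent(t, "press"))
                    held_since = t
                continue
            t += span
            available += span
            hold_accum += span
            if span == bout and not always:
                events.append(LeverEvent(t, "release"))
                held_since = None
                working = False
        else:
            bout = 1.0 + float(rng.exponential(mean_leisure_tail)) if mean_leisure_tail > 0 else 1.0
            span = min(bout, remaining())
            t += span
            available += span
            working = True
    if held_since is not None:
        events.append(LeverEvent(t, "release"))

    return TrialRecord(
        trial_id=trial_id,
        role=role,
        stimulus=stimulus,
        events=events,
        duration=t,
        subject=subject,
        survey=survey,
        blackout=policy.blackout,
        tap_threshold=policy.tap_threshold,
    )


def simulate_trial_events(
    truth: GroundTruth,
    schedule: SurveySchedule,
    policy: BehaviorPolicy | None = None,
    seed: int = 0,
) -> list[TrialRecord]:
    """Emit lever-event trial records for every scheduled test trial.

    Each test trial is flanked by a leading bracket (very strong reference
    reward, worked almost continuously) and a trailing bracket (very weak
    reference, mostly ignored), mirroring the triad structure of the
    behavioural protocol.  Passing the records through the trial-metrics
    code and averaging recovers the ground-truth surface within Monte
    Carlo error.
    """
    policy = policy or BehaviorPolicy()
    children = np.random.SeedSequence(seed).spawn(schedule.n_surveys)
    rngs = {s: np.random.default_rng(c) for s, c in enumerate(children)}
    trials: list[TrialRecord] = []
    for i, rec in enumerate(schedule.entries.itertuples(index=False)):
        rng = rngs[rec.survey]
        survey = int(rec.survey)
        if policy.include_brackets:
            lead_stim = StimulusPoint(
                policy.bracket_frequency_high, policy.bracket_price, policy.bracket_duration
            )
            trials.append(
                _simulate_one_trial(
                    rng, policy.leading_bracket_ta, lead_stim, policy,
                    f"t{i:05d}-lead", "leading_bracket", survey, truth.subject,
                )
            )
        stim = StimulusPoint(rec.pulse_frequency_pps, rec.price_s, rec.train_duration_s)
        target = _surface_ta(
            truth, rec.pulse_frequency_pps, rec.price_s, rec.train_duration_s
        )
        trial = _simulate_one_trial(
            rng, target, stim, policy, f"t{i:05d}-test", "test", survey, truth.subject
        )
        trial.extras["sweep_type"] = rec.sweep_type
        trials.append(trial)
        if policy.include_brackets:
            trail_stim = StimulusPoint(
                policy.bracket_frequency_low, policy.bracket_price, policy.bracket_duration
            )
            trials.append(
                _simulate_one_trial(
                    rng, policy.trailing_bracket_ta, trail_stim, policy,
                    f"t{i:05d}-trail", "trailing_bracket", survey, truth.subject,
                )
            )
    return trials
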