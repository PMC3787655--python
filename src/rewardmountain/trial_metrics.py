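"""Time allocation from time-stamped lever events.

Under the cumulative handling-time schedule a reward is delivered once the
lever has been held for a cumulative total equal to the trial's price; the
lever then retracts for a fixed blackout delay.  The dependent measure is
*time allocation* (TA): the proportion of corrected trial time spent
working.  The corrections are

* the interval before the first reward is excluded (the subject has no
  information yet about the payoff on offer),
* blackout intervals are excluded from both work and trial time,
* brief lever releases ("taps", strictly shorter than ``tap_threshold``)
  count as work — the subject is at the lever, actively harvesting.

Bracket trials (very strong / very weak reference rewards flanking each
test trial) are quality controls, summarised per survey by
:func:`bracket_stability_report`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mountain import StimulusPoint

__all__ = [
    "LeverEvent",
    "TrialRecord",
    "MalformedEventStream",
    "compute_time_allocation",
    "trials_to_observations",
    "bracket_stability_report",
]

logger = logging.getLogger(__name__)

EVENT_KINDS = frozenset({"press", "release", "reward_delivered", "trial_start", "trial_end"})
ROLES = frozenset({"test", "leading_bracket", "trailing_bracket"})


class MalformedEventStream(ValueError):
    """Raised for event streams that violate the lever-logging contract."""


@dataclass(frozen=True)
class LeverEvent:
    """One time-stamped lever-log entry, ``t`` in seconds from trial start."""

    t: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class TrialRecord:
    """One trial: its stimulus, role, and the raw lever-event stream."""

    trial_id: str
    role: str
    stimulus: StimulusPoint
    events: list[LeverEvent]
    duration: float
    subject: str = "synthetic"
    survey: int | None = None
    blackout: float = 2.0
    tap_threshold: float = 1.0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown trial role {self.role!r}")
        if self.blackout < 0:
            raise ValueError("blackout must be non-negative")


def _overlap(intervals: list[tuple[float, float]], lo: float, hi: float) -> float:
    """Total length of ``intervals`` clipped to [lo, hi]."""
    total = 0.0
    for a, b in intervals:
        total += max(0.0, min(b, hi) - max(a, lo))
    return total


def _subtract_overlap(a: float, b: float, cuts: list[tuple[float, float]]) -> float:
    """Length of [a, b] minus its overlap with ``cuts``."""
    return max(0.0, b - a) - _overlap(cuts, a, b)


def _parse_stream(trial: TrialRecord):
    """Split the stream into hold intervals, gap intervals, and reward times."""
    events = sorted(trial.events, key=lambda e: e.t)
    t0, t_end = 0.0, float(trial.duration)
    for e in events:
        if e.kind == "trial_start":
            t0 = e.t
        elif e.kind == "trial_end":
            t_end = e.t
    if t_end <= t0:
        raise MalformedEventStream("trial end must follow trial start")

    presses, releases, rewards = [], [], []
    held = False
    for e in events:
        if e.t < t0 - 1e-12 or e.t > t_end + 1e-12:
            raise MalformedEventStream(f"event at t={e.t} outside the trial span")
        if e.kind == "press":
            if held:
                raise MalformedEventStream(f"press at t={e.t} while lever already held")
            held = True
            presses.append(e.t)
        elif e.kind == "release":
            if not held:
                raise MalformedEventStream(f"release at t={e.t} with lever not held")
            held = False
            releases.append(e.t)
        elif e.kind == "reward_delivered":
            rewards.append(e.t)
    if held:  # lever still down when the trial times out
        releases.append(t_end)

    holds = list(zip(presses, releases))
    for a, b in holds:
        if b < a:
            raise MalformedEventStream("release precedes its press")

    # gaps: maximal released spans between t0, the holds, and t_end
    gaps = []
    prev = t0
    for a, b in holds:
        if a > prev:
            gaps.append((prev, a))
        prev = b
    if t_end > prev:
        gaps.append((prev, t_end))

    blackouts = [(t, min(t + trial.blackout, t_end)) for t in rewards]
    return t0, t_end, holds, gaps, rewards, blackouts


def compute_time_allocation(trial: TrialRecord) -> float:
    """Time allocation of one trial, or NaN when no reward was delivered.

    Work time is the lever-hold time plus released gaps whose non-blackout
    length is strictly below ``tap_threshold``; the denominator is the span
    from the first reward to trial end minus blackout time.  A gap that
    spans a reward delivery is classified by its total non-blackout length
    (such gaps are logged).  The result is clipped to [0, 1].
    """
    t0, t_end, holds, gaps, rewards, blackouts = _parse_stream(trial)
    if not rewards:
        return float("nan")
    first_reward = min(rewards)

    for a in (p for p, _ in holds):
        for lo, hi in blackouts:
            if lo < a < hi:
                raise MalformedEventStream(
                    f"press at t={a} during blackout [{lo}, {hi}]: lever is retracted"
                )

    denom = _subtract_overlap(first_reward, t_end, blackouts)
    if denom <= 0:
        return float("nan")

    work = 0.0
    for a, b in holds:
        work += _subtract_overlap(max(a, first_reward), min(b, t_end), blackouts)
    for a, b in gaps:
        gap_len = _subtract_overlap(a, b, blackouts)
        if gap_len < trial.tap_threshold:
            if any(a < t < b for t in rewards) and gap_len > 0:
                logger.debug(
                    "trial %s: tap gap [%.3f, %.3f] spans a reward delivery",
                    trial.trial_id, a, b,
                )
            work += _subtract_overlap(max(a, first_reward), min(b, t_end), blackouts)

    return float(np.clip(work / denom, 0.0, 1.0))


def trials_to_observations(trials: list[TrialRecord]) -> pd.DataFrame:
    """Tidy observation table from test trials; undefined-TA trials dropped.

    Columns: subject, train_duration_s, pulse_frequency_pps, price_s,
    sweep_type, survey, time_allocation.  Bracket trials are excluded (they
    are QC references, not mountain observations).
    """
    rows = []
    dropped = 0
    for tr in trials:
        if tr.role != "test":
            continue
        ta = compute_time_allocation(tr)
        if np.isnan(ta):
            dropped += 1
            continue
        rows.append(
            {
                "subject": tr.subject,
                "train_duration_s": tr.stimulus.train_duration,
                "pulse_frequency_pps": tr.stimulus.pulse_frequency,
                "price_s": tr.stimulus.price,
                "sweep_type": tr.extras.get("sweep_type", "unknown"),
                "survey": tr.survey if tr.survey is not None else -1,
                "time_allocation": ta,
            }
        )
    if dropped:
        logger.info("dropped %d trial(s) with no reward (undefined TA)", dropped)
    return pd.DataFrame(rows)


def bracket_stability_report(
    trials: list[TrialRecord], high_thresh: float = 0.8, low_thresh: float = 0.2
) -> pd.DataFrame:
    """Per-survey bracket-trial stability summary.

    For each survey index, reports the mean TA on leading brackets (strong
    reference reward — should be consistently high) and trailing brackets
    (weak reference — consistently low), with ``stable`` True when the
    leading mean is at least ``high_thresh`` and the trailing mean at most
    ``low_thresh``.
    """
    records: dict[int, dict[str, list[float]]] = {}
    for tr in trials:
        if tr.role not in ("leading_bracket", "trailing_bracket"):
            continue
        ta = compute_time_allocation(tr)
        if np.isnan(ta):
            continue
        survey = tr.survey if tr.survey is not None else -1
        bucket = records.setdefault(survey, {"leading": [], "trailing": []})
        bucket["leading" if tr.role == "leading_bracket" else "trailing"].append(ta)

    if not records:
        warnings.warn("no bracket trials found; stability report is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["survey", "leading_mean", "trailing_mean", "n_leading",
                     "n_trailing", "stable"]
        )

    rows = []
    for survey in sorted(records):
        lead, trail = records[survey]["leading"], records[survey]["trailing"]
        lead_mean = float(np.mean(lead)) if lead else float("nan")
        trail_mean = float(np.mean(trail)) if trail else float("nan")
        stable = bool(
            lead and trail and lead_mean >= high_thresh and trail_mean <= low_thresh
        )
        rows.append(
            {
                "survey": survey,
                "leading_mean": lead_mean,
                "trailing_mean": trail_mean,
                "n_leading": len(lead),
                "n_trailing": len(trail),
                "stable": stable,
            }
        )
    return pd.DataFrame(rows)
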