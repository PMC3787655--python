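"""Time-allocation computation versus an independent interval-sweep oracle."""

import numpy as np
import pytest

import rewardmountain as rm
from rewardmountain.trial_metrics import MalformedEventStream

STIM = rm.StimulusPoint(100.0, 5.0, 1.0)


def make_trial(events, duration, blackout=2.0, tap_threshold=1.0, role="test", survey=0):
    return rm.TrialRecord(
        trial_id="t",
        role=role,
        stimulus=STIM,
        events=[rm.LeverEvent(t, k) for t, k in events],
        duration=duration,
        survey=survey,
        blackout=blackout,
        tap_threshold=tap_threshold,
    )


def oracle_time_allocation(trial):
    """Classify every elementary interval of the trial independently.

    Splits the trial span at every event boundary, blackout edge and gap
    edge, then decides for each elementary piece — from the raw stream, not
    via the production code path — whether it is excluded (pre-first-reward
    or blackout), work (lever held, or inside a short released gap), or
    leisure.
    """
    T = trial.duration
    presses = sorted(e.t for e in trial.events if e.kind == "press")
    releases = sorted(e.t for e in trial.events if e.kind == "release")
    rewards = sorted(e.t for e in trial.events if e.kind == "reward_delivered")
    if not rewards:
        return float("nan")
    if len(releases) < len(presses):
        releases = releases + [T]
    blackouts = [(t, min(t + trial.blackout, T)) for t in rewards]
    first = rewards[0]

    def in_blackout(t):
        return any(lo <= t < hi for lo, hi in blackouts)

    def held(t):
        return sum(1 for p in presses if p <= t) > sum(1 for r in releases if r <= t)

    # maximal released gaps and their non-blackout lengths
    edges = [0.0] + presses + releases + [T]
    gaps = []
    prev = 0.0
    for p, r in zip(presses, releases):
        if p > prev:
            gaps.append((prev, p))
        prev = r
    if T > prev:
        gaps.append((prev, T))

    def gap_nb_length(lo, hi):
        cut = hi - lo
        for a, b in blackouts:
            cut -= max(0.0, min(b, hi) - max(a, lo))
        return cut

    short_gap = {
        (lo, hi): gap_nb_length(lo, hi) < trial.tap_threshold for lo, hi in gaps
    }

    bounds = sorted(
        set(
            [0.0, T, first]
            + presses
            + releases
            + [b for pair in blackouts for b in pair]
        )
    )
    work = denom = 0.0
    for lo, hi in zip(bounds, bounds[1:]):
        if hi <= first:
            continue
        mid = (max(lo, first) + hi) / 2.0
        length = hi - max(lo, first)
        if in_blackout(mid):
            continue
        denom += length
        if held(mid):
            work += length
        else:
            for (glo, ghi), is_short in short_gap.items():
                if glo <= mid < ghi and is_short:
                    work += length
                    break
    if denom <= 0:
        return float("nan")
    return min(1.0, max(0.0, work / denom))


class TestComputeTimeAllocation:
    def test_continuous_hold_is_one(self):
        # press at 0, reward at 1, held (re-pressed after blackout) to the end
        ev = [
            (0.0, "press"), (5.0, "reward_delivered"), (5.0, "release"),
            (7.0, "press"), (30.0, "release"),
        ]
        trial = make_trial(ev, duration=30.0)
        assert rm.compute_time_allocation(trial) == pytest.approx(1.0)

    def test_half_work_half_leisure(self):
        # after the first reward: 10 s hold then a 10 s gap, no blackout overlap
        ev = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (13.0, "release"),
        ]
        trial = make_trial(ev, duration=23.0)
        # denominator: 23 - 1 - 2 (blackout) = 20; work: hold [3,13] = 10
        assert rm.compute_time_allocation(trial) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "gap, counts_as_work", [(0.5, True), (0.999, True), (1.0, False), (1.5, False)]
    )
    def test_tap_rule_strict_threshold(self, gap, counts_as_work):
        ev = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (10.0, "release"),
            (10.0 + gap, "press"), (20.0, "release"),
        ]
        trial = make_trial(ev, duration=20.0)
        denom = 20.0 - 1.0 - 2.0
        work = 7.0 + (20.0 - 10.0 - gap) + (gap if counts_as_work else 0.0)
        assert rm.compute_time_allocation(trial) == pytest.approx(work / denom)

    def test_no_reward_is_undefined(self):
        trial = make_trial([(0.0, "press"), (4.0, "release")], duration=10.0)
        assert np.isnan(rm.compute_time_allocation(trial))

    def test_non_alternating_stream_rejected(self):
        trial = make_trial([(0.0, "press"), (1.0, "press")], duration=10.0)
        with pytest.raises(MalformedEventStream):
            rm.compute_time_allocation(trial)

    def test_press_during_blackout_rejected(self):
        ev = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (2.0, "press"), (10.0, "release"),  # blackout runs to t=3
        ]
        trial = make_trial(ev, duration=10.0)
        with pytest.raises(MalformedEventStream):
            rm.compute_time_allocation(trial)

    def test_zero_length_hold_split_is_invariant(self):
        base = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (13.0, "release"),
        ]
        split = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (8.0, "release"), (8.0, "press"), (13.0, "release"),
        ]
        t1 = make_trial(base, duration=23.0)
        t2 = make_trial(split, duration=23.0)
        assert rm.compute_time_allocation(t1) == pytest.approx(
            rm.compute_time_allocation(t2), abs=1e-12
        )

    def test_extra_blackout_shrinks_denominator_only(self):
        # a second reward inside a hold adds a blackout; the work outside
        # blackouts is unchanged and the denominator shrinks by exactly 2 s
        ev1 = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (13.0, "release"),
        ]
        ev2 = [
            (0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
            (3.0, "press"), (8.0, "reward_delivered"), (8.0, "release"),
            (10.0, "press"), (15.0, "release"),
        ]
        t1 = make_trial(ev1, duration=23.0)
        t2 = make_trial(ev2, duration=23.0)
        # t1: work 10 / denom 20; t2: work (5 + 5) / denom (20 - 2)
        assert rm.compute_time_allocation(t1) == pytest.approx(0.5)
        assert rm.compute_time_allocation(t2) == pytest.approx(10.0 / 18.0)


def random_trial(rng):
    """Protocol-respecting random stream: rewards end holds, blackout follows."""
    T = float(rng.uniform(20.0, 60.0))
    events = []
    t = 0.0
    held = False
    while t < T - 0.5:
        if not held:
            t += float(rng.uniform(0.05, 3.0))
            if t >= T:
                break
            events.append((t, "press"))
            held = True
        else:
            hold = float(rng.uniform(0.1, 6.0))
            if rng.random() < 0.35:  # reward fires mid-hold
                u = float(rng.uniform(0.05, hold))
                t_r = min(t + u, T)
                events.append((t_r, "reward_delivered"))
                events.append((t_r, "release"))
                held = False
                t = t_r + 2.0  # blackout: lever retracted, no events
            else:
                t = min(t + hold, T)
                if t < T:
                    events.append((t, "release"))
                    held = False
    return make_trial(events, duration=T)


def test_oracle_agreement_on_random_streams(rng):
    """The production TA matches the interval-sweep oracle on 1000 streams."""
    checked = 0
    for _ in range(1000):
        trial = random_trial(rng)
        ours = rm.compute_time_allocation(trial)
        ref = oracle_time_allocation(trial)
        if np.isnan(ref):
            assert np.isnan(ours)
        else:
            assert ours == pytest.approx(ref, abs=1e-9)
            checked += 1
    assert checked > 500  # most random streams deliver at least one reward


class TestBracketStability:
    @staticmethod
    def bracket_trial(ta, role, survey):
        """A 20 s post-reward window with a single hold of length 20*ta."""
        work = 20.0 * ta
        ev = [(0.0, "press"), (0.5, "reward_delivered"), (0.5, "release")]
        if work > 0:
            ev += [(2.5, "press"), (2.5 + work, "release")]
        return make_trial(ev, duration=22.5, role=role, survey=survey)

    def test_pass_and_fail_flags(self):
        trials = [
            self.bracket_trial(0.95, "leading_bracket", 0),
            self.bracket_trial(0.05, "trailing_bracket", 0),
            self.bracket_trial(0.5, "leading_bracket", 1),
            self.bracket_trial(0.05, "trailing_bracket", 1),
            self.bracket_trial(0.9, "leading_bracket", 2),
            self.bracket_trial(0.4, "trailing_bracket", 2),
        ]
        report = rm.bracket_stability_report(trials, high_thresh=0.8, low_thresh=0.2)
        flags = dict(zip(report["survey"], report["stable"]))
        assert flags == {0: True, 1: False, 2: False}
        assert report.loc[report.survey == 0, "leading_mean"].iloc[0] == pytest.approx(
            0.95, abs=0.01
        )

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            report = rm.bracket_stability_report([])
        assert report.empty


def test_trials_to_observations_drops_undefined():
    good = make_trial(
        [(0.0, "press"), (1.0, "reward_delivered"), (1.0, "release"),
         (3.0, "press"), (13.0, "release")],
        duration=23.0,
    )
    bad = make_trial([(0.0, "press"), (4.0, "release")], duration=10.0)
    obs = rm.trials_to_observations([good, bad])
    assert len(obs) == 1
    assert obs["time_allocation"].iloc[0] == pytest.approx(0.5)
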