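"""Shared fixtures: ground-truth surfaces and simulated experiments."""

from __future__ import annotations

import numpy as np
import pytest

import rewardmountain as rm

SHORT, LONG = 0.25, 1.0


def make_single_truth(
    f_hm_short: float = 200.0,
    f_hm_long: float = 100.0,
    p_e_short: float = 8.0,
    p_e_long: float = 8.0,
    ta_max_short: float = 0.92,
    ta_max_long: float = 0.88,
    a: float = 4.0,
    g: float = 4.0,
    ta_min: float = 0.08,
) -> rm.SingleMountainParams:
    return rm.SingleMountainParams(
        a=a,
        g=g,
        ta_min=ta_min,
        blocks={
            SHORT: rm.DurationBlock(f_hm_short, p_e_short, ta_max_short),
            LONG: rm.DurationBlock(f_hm_long, p_e_long, ta_max_long),
        },
    )


def design_for(params: rm.SingleMountainParams, n_surveys: int = 8, seed: int = 0):
    """Six pseudo-sweeps through the truth's location points, scheduled."""
    sweeps = []
    for dur, blk in sorted(params.blocks.items()):
        sweeps += rm.build_pseudo_sweeps(blk.f_hm, blk.p_e, dur)
    return rm.build_survey_schedule(sweeps, n_surveys, seed)


def simulate_experiment(
    params: rm.SingleMountainParams,
    seed: int,
    noise_concentration: float = 40.0,
    n_surveys: int = 8,
):
    truth = rm.GroundTruth(model=params, noise_concentration=noise_concentration)
    schedule = design_for(params, n_surveys, seed)
    return rm.simulate_observations(truth, schedule, seed + 10_000)


@pytest.fixture(scope="session")
def single_truth() -> rm.SingleMountainParams:
    return make_single_truth()


@pytest.fixture(scope="session")
def standard_observations(single_truth):
    """One simulated 8-survey experiment at reference noise."""
    return simulate_experiment(single_truth, seed=11)


@pytest.fixture(scope="session")
def standard_fit(standard_observations):
    return rm.fit_mountain(standard_observations, rm.FitSpec(), seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
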