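"""Mountain surfaces: oracle transcription, reductions, monotonicity, dual mechanism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rewardmountain as rm
from rewardmountain.transforms import (
    FrequencyFollowingParams,
    StrengthDurationParams,
    SubjectivePriceParams,
)
from .test_transforms import naive_frequency_following, naive_subjective_price

SHORT, LONG = 0.25, 1.0

# transforms that are numerically the identity over the tested ranges
IDENTITY_TP = rm.TransformParams(
    subjective_price=SubjectivePriceParams(sp_min=1e-12, sp_bend=1e-12),
    frequency_following=FrequencyFollowingParams(f_bend=20.63, f_near_max=1e9),
)


def single_params(**kw):
    defaults = dict(a=3.5, g=4.2, ta_min=0.06, f_hm=110.0, p_e=9.0, ta_max=0.91)
    defaults.update(kw)
    blk = rm.DurationBlock(defaults["f_hm"], defaults["p_e"], defaults["ta_max"])
    return rm.SingleMountainParams(
        a=defaults["a"], g=defaults["g"], ta_min=defaults["ta_min"], blocks={LONG: blk}
    )


def naive_extended_ta(f, p, params, duration=LONG):
    """Term-by-term transcription of the extended surface (no stabilisation)."""
    blk = params.blocks[duration]
    ff = naive_frequency_following(f)
    ff_hm = naive_frequency_following(blk.f_hm)
    sp = naive_subjective_price(p)
    sp_e = naive_subjective_price(blk.p_e)
    u = ff**params.g / (ff**params.g + ff_hm**params.g)
    num = u**params.a
    return (blk.ta_max - params.ta_min) * num / (
        num + (sp / sp_e) ** params.a
    ) + params.ta_min


class TestRewardIntensitySingle:
    def test_half_max_definition(self):
        assert rm.reward_intensity_single(70.0, 70.0, 3.0) == pytest.approx(0.5)

    def test_zero(self):
        assert rm.reward_intensity_single(0.0, 70.0, 3.0) == 0.0

    def test_hand_value(self):
        assert rm.reward_intensity_single(140.0, 70.0, 2.0) == pytest.approx(0.8)

    def test_huge_exponent_does_not_overflow(self):
        val = rm.reward_intensity_single(1e4, 10.0, 40.0)
        assert val == pytest.approx(1.0)


class TestExtendedSurface:
    def test_matches_naive_transcription_on_grid(self):
        params = single_params()
        F, P = np.meshgrid(np.geomspace(10, 1000, 20), np.geomspace(0.5, 50, 20))
        ours = rm.time_allocation_extended(F, P, LONG, params)
        theirs = np.vectorize(lambda f, p: naive_extended_ta(f, p, params))(F, P)
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_halfway_at_saturated_reward_and_matched_price(self):
        # with an effectively unbounded frequency-following plateau the
        # intensity saturates and TA at p = p_e is exactly halfway
        params = single_params()
        ta = rm.time_allocation_extended(1e7, params.blocks[LONG].p_e, LONG, params, IDENTITY_TP)
        halfway = (params.blocks[LONG].ta_max + params.ta_min) / 2
        assert ta == pytest.approx(halfway, abs=1e-9)

    def test_zero_frequency_gives_floor(self):
        params = single_params()
        assert rm.time_allocation_extended(0.0, 5.0, LONG, params) == pytest.approx(
            params.ta_min, abs=1e-12
        )

    def test_original_is_extended_with_identity_transforms(self):
        # plateau placed at 1e5 pps: identity over the tested range without
        # the float cancellation a 1e9 plateau would cause
        tp = rm.TransformParams(
            subjective_price=SubjectivePriceParams(sp_min=1e-12, sp_bend=1e-12),
            frequency_following=FrequencyFollowingParams(f_bend=20.63, f_near_max=1e5),
        )
        params = single_params()
        F, P = np.meshgrid(np.geomspace(5, 500, 15), np.geomspace(0.5, 40, 15))
        ext = rm.time_allocation_extended(F, P, LONG, params, tp)
        orig = rm.time_allocation_original(F, P, LONG, params)
        np.testing.assert_allclose(ext, orig, rtol=1e-9)

    def test_original_limits(self):
        params = single_params()
        assert rm.time_allocation_original(0.0, 5.0, LONG, params) == pytest.approx(
            params.ta_min
        )
        # f at f_hm, price -> 0: payoff diverges, TA -> ta_max
        ta = rm.time_allocation_original(params.blocks[LONG].f_hm, 1e-9, LONG, params)
        assert ta == pytest.approx(params.blocks[LONG].ta_max, abs=1e-6)

    @given(
        a=st.floats(1.0, 8.0),
        g=st.floats(1.0, 8.0),
        f_hm=st.floats(50.0, 300.0),
        p_e=st.floats(3.0, 30.0),
        f=st.floats(1.0, 1000.0),
        p=st.floats(0.5, 100.0),
        df=st.floats(0.1, 500.0),
        dp=st.floats(0.1, 50.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_bounds_and_monotonicity(self, a, g, f_hm, p_e, f, p, df, dp):
        params = single_params(a=a, g=g, f_hm=f_hm, p_e=p_e)
        ta = rm.time_allocation_extended(f, p, LONG, params)
        assert params.ta_min - 1e-12 <= ta <= params.blocks[LONG].ta_max + 1e-12
        assert rm.time_allocation_extended(f + df, p, LONG, params) >= ta - 1e-12
        assert rm.time_allocation_extended(f, p + dp, LONG, params) <= ta + 1e-12

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            single_params(a=-1.0)
        with pytest.raises(ValueError):
            single_params(ta_max=0.05)  # below ta_min


class TestStrengthDurationConsistency:
    @given(st.floats(0.05, 5.0), st.floats(20.0, 200.0))
    @settings(max_examples=50, derandomize=True)
    def test_duration_ratio_identity(self, chronaxie, rheobase):
        # FFhm(0.25)/FFhm(1) = (1 + 4C) / (1 + C) for the hyperbolic law
        sd = StrengthDurationParams(rheobase=rheobase, chronaxie=chronaxie)
        ratio = rm.half_max_firing_at_duration(0.25, sd) / rm.half_max_firing_at_duration(
            1.0, sd
        )
        assert ratio == pytest.approx((1 + 4 * chronaxie) / (1 + chronaxie), rel=1e-12)


def dual_params(w=0.55, c2=5.0, r2=50.0, ta_max=0.9):
    return rm.DualMountainParams(
        integrator1=StrengthDurationParams(rheobase=60.0, chronaxie=0.3),
        integrator2=StrengthDurationParams(rheobase=r2, chronaxie=c2),
        w=w,
        price_scale=10.0,
        a=4.0,
        g=4.0,
        ta_min=0.08,
        ta_max={SHORT: ta_max, LONG: ta_max},
    )


class TestDualSurface:
    def test_w1_reduces_to_single_intensity(self):
        params = dual_params(w=1.0)
        ffhm1 = rm.half_max_firing_at_duration(LONG, params.integrator1)
        for ff in (10.0, 80.0, 300.0):
            assert rm.reward_intensity_dual(ff, LONG, params) == pytest.approx(
                rm.reward_intensity_single(ff, ffhm1, params.g), rel=1e-12
            )

    def test_saturation_with_low_demands(self):
        params = rm.DualMountainParams(
            integrator1=StrengthDurationParams(rheobase=10.0, chronaxie=0.1),
            integrator2=StrengthDurationParams(rheobase=15.0, chronaxie=0.2),
            w=0.5, price_scale=10.0, a=4.0, g=4.0, ta_min=0.08,
            ta_max={LONG: 0.9},
        )
        assert rm.max_achievable_intensity(params, 100.0) == pytest.approx(1.0, abs=1e-3)

    def test_integrator_dropout_caps_intensity_near_w(self):
        # integrator 2's half-max demand at 0.25 s (50 * 21 = 1050 spikes/s)
        # is far above the ~343 spikes/s plateau: it cannot be recruited
        params = dual_params()
        demand2 = rm.half_max_firing_at_duration(SHORT, params.integrator2)
        assert demand2 > rm.firing_plateau()
        i_max = rm.max_achievable_intensity(params, SHORT)
        assert i_max == pytest.approx(params.w, abs=0.05)

    def test_w1_reduction_identity_on_grid(self):
        sd = StrengthDurationParams(rheobase=60.0, chronaxie=0.5)
        ffhm = rm.half_max_firing_at_duration(LONG, sd)
        f_hm = rm.pulse_frequency_for_firing(ffhm).pulse_frequency
        single = rm.SingleMountainParams(
            a=3.5, g=4.2, ta_min=0.06, blocks={LONG: rm.DurationBlock(f_hm, 9.0, 0.91)}
        )
        dual = rm.DualMountainParams(
            integrator1=sd,
            integrator2=StrengthDurationParams(rheobase=1.0, chronaxie=1.0),
            w=1.0,
            price_scale=rm.subjective_price(9.0),
            a=3.5, g=4.2, ta_min=0.06, ta_max={LONG: 0.91},
        )
        F, P = np.meshgrid(np.geomspace(10, 1000, 50), np.geomspace(0.5, 100, 50))
        np.testing.assert_allclose(
            rm.time_allocation_dual(F, P, LONG, dual),
            rm.time_allocation_extended(F, P, LONG, single),
            rtol=1e-9,
        )

    def test_zero_frequency_gives_floor(self):
        params = dual_params()
        assert rm.time_allocation_dual(0.0, 5.0, LONG, params) == pytest.approx(
            params.ta_min, abs=1e-12
        )

    def test_price_halfway_crossing_shifts_left_at_short_duration(self):
        # the dropout lowers the achievable maximum at 0.25 s, so the price
        # at which TA for the best achievable reward crosses halfway is lower
        params = dual_params()
        short = rm.effective_location_params(params, SHORT)
        long = rm.effective_location_params(params, LONG)
        assert long["p_e_effective"] > short["p_e_effective"]

    def test_max_achievable_intensity_nondecreasing_in_duration(self):
        params = dual_params()
        durations = [0.1, 0.25, 0.5, 1.0, 2.0, 5.0]
        vals = [rm.max_achievable_intensity(params, d) for d in durations]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError):
            dual_params(w=1.5)


class TestEffectiveLocationParams:
    def test_single_self_consistency_without_plateau_limit(self):
        tp = rm.TransformParams(
            frequency_following=FrequencyFollowingParams(f_bend=20.63, f_near_max=1e6)
        )
        params = single_params()
        el = rm.effective_location_params(params, LONG, tp)
        assert el["f_hm_effective"] == pytest.approx(params.blocks[LONG].f_hm, rel=1e-6)
        assert el["p_e_effective"] == pytest.approx(params.blocks[LONG].p_e, rel=1e-6)

    def test_w1_dual_matches_single(self):
        sd = StrengthDurationParams(rheobase=60.0, chronaxie=0.5)
        f_hm = rm.pulse_frequency_for_firing(
            rm.half_max_firing_at_duration(LONG, sd)
        ).pulse_frequency
        single = rm.SingleMountainParams(
            a=3.5, g=4.2, ta_min=0.06, blocks={LONG: rm.DurationBlock(f_hm, 9.0, 0.91)}
        )
        dual = rm.DualMountainParams(
            integrator1=sd,
            integrator2=StrengthDurationParams(rheobase=1.0, chronaxie=1.0),
            w=1.0,
            price_scale=rm.subjective_price(9.0),
            a=3.5, g=4.2, ta_min=0.06, ta_max={LONG: 0.91},
        )
        el_s = rm.effective_location_params(single, LONG)
        el_d = rm.effective_location_params(dual, LONG)
        assert el_d["f_hm_effective"] == pytest.approx(el_s["f_hm_effective"], rel=1e-8)
        assert el_d["p_e_effective"] == pytest.approx(el_s["p_e_effective"], rel=1e-8)

    def test_flat_surface_raises(self):
        # price_scale so small that even the maximal reward cannot reach the
        # subjective-price floor: no halfway crossing exists
        params = dual_params()
        params = rm.DualMountainParams(
            integrator1=params.integrator1, integrator2=params.integrator2,
            w=params.w, price_scale=1.0, a=4.0, g=4.0, ta_min=0.08,
            ta_max={SHORT: 0.9, LONG: 0.9},
        )
        with pytest.raises(ValueError):
            rm.effective_location_params(params, SHORT)


def test_surface_grid_long_format(single_truth):
    grid = rm.evaluate_surface_grid(
        single_truth, [SHORT, LONG], (50, 500), (2, 30), n_f=10, n_p=8
    )
    assert len(grid) == 2 * 10 * 8
    assert set(grid.columns) == {
        "train_duration_s", "pulse_frequency_pps", "price_s", "time_allocation"
    }
    assert grid["time_allocation"].between(0, 1).all()
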