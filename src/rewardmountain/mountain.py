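"""Reward-mountain surfaces.

The reward mountain maps the two experimenter-controlled variables of an
intracranial self-stimulation trial — stimulation strength (pulse
frequency, pulses/s) and price (cumulative lever-hold time required per
reward, s) — to the proportion of trial time the subject allocates to
working.  Three surfaces are implemented:

* the *original* surface, in which neurons are assumed to fire once per
  pulse and the subjective price equals the objective one
  (:func:`time_allocation_original`);
* the *extended* single-integrator surface, which composes the same payoff
  structure with the frequency-following and subjective-price transforms
  (:func:`time_allocation_extended`);
* the *dual-integrator* surface, in which the stimulated population feeds
  two temporal integrators with different strength–duration laws whose
  weighted outputs are pooled (:func:`time_allocation_dual`).

All surfaces share the matching-law form: with reward intensity U in
[0, 1] and subjective price SP, the payoff U/(SP/SPe) is pushed through a
power-function with exponent ``a`` to yield a time allocation between
``ta_min`` and ``ta_max``.  Power expressions are evaluated in log space so
large exponents cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .transforms import (
    DEFAULT_TRANSFORMS,
    StrengthDurationParams,
    TransformParams,
    firing_plateau,
    frequency_following,
    half_max_firing_at_duration,
    objective_price_from_subjective,
    subjective_price,
)

__all__ = [
    "DurationBlock",
    "SingleMountainParams",
    "DualMountainParams",
    "StimulusPoint",
    "reward_intensity_single",
    "reward_intensity_dual",
    "max_achievable_intensity",
    "time_allocation_original",
    "time_allocation_extended",
    "time_allocation_dual",
    "time_allocation",
    "effective_location_params",
    "evaluate_surface_grid",
]


@dataclass(frozen=True)
class StimulusPoint:
    """One stimulation condition: pulse frequency (pps), price (s), duration (s)."""

    pulse_frequency: float
    price: float
    train_duration: float

    def __post_init__(self) -> None:
        if self.pulse_frequency < 0 or self.price < 0 or self.train_duration <= 0:
            raise ValueError("stimulus point out of domain")


@dataclass(frozen=True)
class DurationBlock:
    """Per-train-duration location/height parameters of the single model.

    ``f_hm`` is the pulse frequency (pps) of half-maximal reward intensity,
    ``p_e`` the objective price (s) at which work for a maximal reward sits
    halfway between floor and ceiling, ``ta_max`` the ceiling.
    """

    f_hm: float
    p_e: float
    ta_max: float

    def __post_init__(self) -> None:
        if self.f_hm <= 0 or self.p_e <= 0:
            raise ValueError("f_hm and p_e must be positive")
        if not 0.0 < self.ta_max <= 1.0:
            raise ValueError("ta_max must be in (0, 1]")


@dataclass(frozen=True)
class SingleMountainParams:
    """Single-integrator mountain: shared shape, per-duration location.

    ``a`` is the payoff-sensitivity exponent, ``g`` the reward-growth
    exponent, ``ta_min`` the common floor; ``blocks`` maps each train
    duration (s) to its :class:`DurationBlock`.  Location parameters are
    stored in objective units (pulse frequency and price) and converted
    through the transforms at evaluation time, so the same parameter object
    serves both the original and the extended surface.
    """

    a: float
    g: float
    ta_min: float
    blocks: Mapping[float, DurationBlock]

    def __post_init__(self) -> None:
        if self.a <= 0 or self.g <= 0:
            raise ValueError("a and g must be positive")
        if not 0.0 <= self.ta_min < 1.0:
            raise ValueError("ta_min must be in [0, 1)")
        for d, blk in self.blocks.items():
            if d <= 0:
                raise ValueError("train durations must be positive")
            if blk.ta_max <= self.ta_min:
                raise ValueError("ta_max must exceed ta_min for every duration")

    def block(self, duration: float) -> DurationBlock:
        try:
            return self.blocks[duration]
        except KeyError:
            raise KeyError(f"no parameters for train duration {duration}") from None


@dataclass(frozen=True)
class DualMountainParams:
    """Dual-integrator mountain.

    Two strength–duration-governed integrators with weights ``w`` and
    ``1 - w`` replace the single half-max location; ``price_scale`` (s) is
    the subjective price at which a unit-maximal pooled reward yields
    half-way time allocation (it plays the role SPe plays in the single
    model).  ``a``, ``g``, ``ta_min`` as in the single model; ``ta_max``
    maps each train duration to its ceiling.
    """

    integrator1: StrengthDurationParams
    integrator2: StrengthDurationParams
    w: float
    price_scale: float
    a: float
    g: float
    ta_min: float
    ta_max: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must be in [0, 1]")
        if self.price_scale <= 0:
            raise ValueError("price_scale must be positive")
        if self.a <= 0 or self.g <= 0:
            raise ValueError("a and g must be positive")
        if not 0.0 <= self.ta_min < 1.0:
            raise ValueError("ta_min must be in [0, 1)")
        for d, tmx in self.ta_max.items():
            if d <= 0 or not (self.ta_min < tmx <= 1.0):
                raise ValueError("ta_max must be in (ta_min, 1] for every duration")


def _log_ratio_power(log_num, log_den, exponent):
    """x^e / (x^e + y^e) computed as expit(e * (ln x - ln y)), overflow-free."""
    return expit(exponent * (log_num - log_den))


def _safe_log(x):
    with np.errstate(divide="ignore"):
        return np.log(x)


def reward_intensity_single(ff, ff_hm: float, g: float):
    """Reward intensity ff^g / (ff^g + ff_hm^g) of one integrator.

    ``ff`` is the induced firing frequency (spikes/s), ``ff_hm`` the firing
    frequency of half-maximal intensity, ``g`` the reward-growth exponent.
    """
    if ff_hm <= 0 or g <= 0:
        raise ValueError("ff_hm and g must be positive")
    arr = np.asarray(ff, dtype=float)
    if np.any(arr < 0):
        raise ValueError("firing frequency must be non-negative")
    out = _log_ratio_power(_safe_log(arr), np.log(ff_hm), g)
    return out.item() if np.isscalar(ff) or arr.ndim == 0 else out


def reward_intensity_dual(ff, d: float, params: DualMountainParams):
    """Pooled intensity of the two integrators at train duration ``d``.

    I = w * u1 + (1 - w) * u2 with u_i the single-integrator intensity
    against integrator i's half-max firing demand at this duration.  When
    an integrator's demand sits near or above the frequency-following
    plateau, its contribution cannot be recruited at any achievable firing
    frequency and the pooled maximum drops below 1.
    """
    if d <= 0:
        raise ValueError("train duration must be positive")
    demands = (
        half_max_firing_at_duration(d, params.integrator1),
        half_max_firing_at_duration(d, params.integrator2),
    )
    u1 = reward_intensity_single(ff, demands[0], params.g)
    u2 = reward_intensity_single(ff, demands[1], params.g)
    return params.w * u1 + (1.0 - params.w) * u2


def max_achievable_intensity(
    params: DualMountainParams, d: float, tp: TransformParams = DEFAULT_TRANSFORMS
) -> float:
    """Pooled intensity at the frequency-following plateau: the ceiling the
    directly stimulated neurons can actually deliver at duration ``d``."""
    return float(reward_intensity_dual(firing_plateau(tp.frequency_following), d, params))


def _matching_allocation(log_payoff, a, ta_min, ta_max):
    """Matching-law stage: TA = (ta_max - ta_min) * V^a/(V^a + 1) + ta_min."""
    return (ta_max - ta_min) * expit(a * log_payoff) + ta_min


def time_allocation_original(f, p, duration: float, params: SingleMountainParams):
    """Original surface: one spike per pulse, subjective price = objective."""
    blk = params.block(duration)
    f_arr = np.asarray(f, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(f_arr < 0) or np.any(p_arr <= 0):
        raise ValueError("pulse frequency must be >= 0 and price > 0")
    log_u = _safe_log(_log_ratio_power(_safe_log(f_arr), np.log(blk.f_hm), params.g))
    log_payoff = log_u - (_safe_log(p_arr) - np.log(blk.p_e))
    out = _matching_allocation(log_payoff, params.a, params.ta_min, blk.ta_max)
    scalar = (np.isscalar(f) or f_arr.ndim == 0) and (np.isscalar(p) or p_arr.ndim == 0)
    return out.item() if scalar else out


def time_allocation_extended(
    f,
    p,
    duration: float,
    params: SingleMountainParams,
    tp: TransformParams = DEFAULT_TRANSFORMS,
):
    """Extended single-integrator surface.

    The pulse frequency is passed through the frequency-following map (for
    both the stimulus and the stored half-max location ``f_hm``) and the
    price through the subjective-price map (likewise for ``p_e``), then the
    matching-law payoff stage is applied.
    """
    blk = params.block(duration)
    f_arr = np.asarray(f, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(f_arr < 0) or np.any(p_arr < 0):
        raise ValueError("pulse frequency and price must be non-negative")
    ff = frequency_following(f_arr, tp.frequency_following)
    ff_hm = frequency_following(blk.f_hm, tp.frequency_following)
    sp = subjective_price(p_arr, tp.subjective_price)
    sp_e = subjective_price(blk.p_e, tp.subjective_price)
    log_u = _safe_log(_log_ratio_power(_safe_log(np.asarray(ff)), np.log(ff_hm), params.g))
    log_payoff = log_u - (np.log(np.asarray(sp)) - np.log(sp_e))
    out = _matching_allocation(log_payoff, params.a, params.ta_min, blk.ta_max)
    scalar = (np.isscalar(f) or f_arr.ndim == 0) and (np.isscalar(p) or p_arr.ndim == 0)
    return out.item() if scalar else out


def time_allocation_dual(
    f,
    p,
    duration: float,
    params: DualMountainParams,
    tp: TransformParams = DEFAULT_TRANSFORMS,
):
    """Dual-integrator surface.

    TA = (ta_max - ta_min) * V^a/(V^a + 1) + ta_min with payoff
    V = I * price_scale / SP, where I is the pooled intensity of the two
    integrators at the induced firing frequency.  With w = 1 and
    price_scale equal to the single model's SPe this reduces algebraically
    to the extended surface.
    """
    try:
        ta_max = params.ta_max[duration]
    except KeyError:
        raise KeyError(f"no ta_max for train duration {duration}") from None
    f_arr = np.asarray(f, dtype=float)
    p_arr = np.asarray(p, dtype=float)
    if np.any(f_arr < 0) or np.any(p_arr < 0):
        raise ValueError("pulse frequency and price must be non-negative")
    ff = frequency_following(f_arr, tp.frequency_following)
    intensity = reward_intensity_dual(np.asarray(ff), duration, params)
    sp = subjective_price(p_arr, tp.subjective_price)
    log_payoff = (
        _safe_log(np.asarray(intensity)) + np.log(params.price_scale) - np.log(np.asarray(sp))
    )
    out = _matching_allocation(log_payoff, params.a, params.ta_min, ta_max)
    scalar = (np.isscalar(f) or f_arr.ndim == 0) and (np.isscalar(p) or p_arr.ndim == 0)
    return out.item() if scalar else out


def time_allocation(
    x: StimulusPoint,
    params: SingleMountainParams | DualMountainParams,
    tp: TransformParams = DEFAULT_TRANSFORMS,
) -> float:
    """Evaluate whichever surface ``params`` describes at a stimulus point."""
    if isinstance(params, SingleMountainParams):
        return time_allocation_extended(
            x.pulse_frequency, x.price, x.train_duration, params, tp
        )
    return time_allocation_dual(x.pulse_frequency, x.price, x.train_duration, params, tp)


def effective_location_params(
    params: SingleMountainParams | DualMountainParams,
    duration: float,
    tp: TransformParams = DEFAULT_TRANSFORMS,
) -> dict[str, float]:
    """Implied location parameters of a surface at one train duration.

    Returns ``f_hm_effective`` — the pulse frequency at which reward
    intensity reaches half its maximum achievable value at this duration —
    and ``p_e_effective`` — the objective price at which time allocation for
    a maximally intense (achievable) reward sits halfway between the floor
    and ceiling.  The achievable maximum is the intensity at the
    frequency-following plateau, so a dual surface whose long-chronaxie
    integrator drops out at short durations reports a left-shifted
    ``p_e_effective`` there.  Both quantities are found by monotone root
    finding; a surface with no halfway crossing raises ``ValueError``.
    """
    plateau = firing_plateau(tp.frequency_following)

    if isinstance(params, SingleMountainParams):
        blk = params.block(duration)
        ff_hm = frequency_following(blk.f_hm, tp.frequency_following)

        def intensity_of_f(f: float) -> float:
            return reward_intensity_single(
                frequency_following(f, tp.frequency_following), ff_hm, params.g
            )

        i_max = reward_intensity_single(plateau, ff_hm, params.g)
        sp_scale = subjective_price(blk.p_e, tp.subjective_price)
    else:
        def intensity_of_f(f: float) -> float:
            return float(
                reward_intensity_dual(
                    frequency_following(f, tp.frequency_following), duration, params
                )
            )

        i_max = max_achievable_intensity(params, duration, tp)
        sp_scale = params.price_scale

    if i_max <= 0:
        raise ValueError("surface is flat: maximum achievable intensity is zero")

    target = i_max / 2.0
    hi = tp.frequency_following.f_near_max
    while intensity_of_f(hi) <= target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - intensity approaches i_max, so unreachable
            raise ValueError("no half-maximal crossing along the frequency axis")
    f_hm_eff = brentq(lambda f: intensity_of_f(f) - target, 1e-9, hi, xtol=1e-10)

    sp_halfway = i_max * sp_scale
    if sp_halfway <= tp.subjective_price.sp_min:
        raise ValueError(
            "no halfway crossing along the price axis: required subjective price "
            "is below the subjective-price floor"
        )
    p_e_eff = objective_price_from_subjective(sp_halfway, tp.subjective_price)
    return {"f_hm_effective": float(f_hm_eff), "p_e_effective": float(p_e_eff)}


def evaluate_surface_grid(
    params: SingleMountainParams | DualMountainParams,
    durations,
    f_range: tuple[float, float],
    p_range: tuple[float, float],
    n_f: int = 50,
    n_p: int = 50,
    tp: TransformParams = DEFAULT_TRANSFORMS,
) -> pd.DataFrame:
    """Evaluate a surface on a log-spaced grid, long format for contouring.

    Returns a DataFrame with columns ``train_duration_s``,
    ``pulse_frequency_pps``, ``price_s``, ``time_allocation``.
    """
    freqs = np.geomspace(*f_range, n_f)
    prices = np.geomspace(*p_range, n_p)
    fgrid, pgrid = np.meshgrid(freqs, prices, indexing="ij")
    frames = []
    for d in durations:
        if isinstance(params, SingleMountainParams):
            ta = time_allocation_extended(fgrid, pgrid, d, params, tp)
        else:
            ta = time_allocation_dual(fgrid, pgrid, d, params, tp)
        frames.append(
            pd.DataFrame(
                {
                    "train_duration_s": d,
                    "pulse_frequency_pps": fgrid.ravel(),
                    "price_s": pgrid.ravel(),
                    "time_allocation": np.asarray(ta).ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
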