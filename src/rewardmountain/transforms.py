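"""Psychophysical transforms used by the extended reward-mountain model.

Three scalar maps link the experimenter-controlled stimulation variables to
the quantities the behavioural model actually operates on:

* :func:`subjective_price` — objective opportunity cost (cumulative
  lever-hold time, s) to subjective opportunity cost.  Very cheap rewards
  are not perceived as proportionally cheaper: the map flattens to a floor
  ``sp_min`` at low prices and converges on the identity at high prices.
* :func:`frequency_following` — stimulation pulse frequency (pulses/s) to
  the frequency of firing induced in the directly stimulated neurons
  (spikes/s).  The neurons follow the pulse train one-to-one up to a limit
  and then saturate abruptly at a plateau near ``f_near_max``.
* :func:`half_max_firing_at_duration` — train duration (s) to the induced
  firing frequency required for a half-maximal reward, the hyperbolic
  strength–duration law parameterised by rheobase and chronaxie.

Both saturating maps are softplus-shaped; they are evaluated through a
numerically stabilised softplus so that arguments far above the bend do not
overflow.  The inverse maps have no closed form and are solved by bracketed
monotone root finding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SubjectivePriceParams",
    "FrequencyFollowingParams",
    "StrengthDurationParams",
    "TransformParams",
    "DEFAULT_SUBJECTIVE_PRICE",
    "DEFAULT_FREQUENCY_FOLLOWING",
    "DEFAULT_TRANSFORMS",
    "subjective_price",
    "objective_price_from_subjective",
    "frequency_following",
    "firing_plateau",
    "pulse_frequency_for_firing",
    "InverseFrequencyResult",
    "half_max_firing_at_duration",
]

_INVERSE_TOL = 1e-10  # absolute tolerance on the transformed value


def _softplus(x):
    """ln(1 + e^x), stable for large |x| via ln(1+e^x) = max(x,0) + ln(1+e^-|x|)."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


@dataclass(frozen=True)
class SubjectivePriceParams:
    """Parameters of the objective-to-subjective price map.

    ``sp_min`` is the minimum subjective price (s): the floor that very low
    objective prices are compressed onto.  ``sp_bend`` (s) sets how abruptly
    the map transitions from the floor to the identity line.
    """

    sp_min: float = 1.75
    sp_bend: float = 0.57

    def __post_init__(self) -> None:
        if not (self.sp_min > 0 and self.sp_bend > 0):
            raise ValueError("sp_min and sp_bend must be positive")


@dataclass(frozen=True)
class FrequencyFollowingParams:
    """Parameters of the pulse-frequency to firing-frequency map.

    ``f_near_max`` (pulses/s) is the midpoint of the transition between the
    one-spike-per-pulse regime and the plateau; ``f_bend`` (pulses/s) sets
    the abruptness of that transition.
    """

    f_bend: float = 20.63
    f_near_max: float = 342.9

    def __post_init__(self) -> None:
        if not (self.f_bend > 0 and self.f_near_max > 0):
            raise ValueError("f_bend and f_near_max must be positive")


@dataclass(frozen=True)
class StrengthDurationParams:
    """Hyperbolic strength–duration law for one temporal integrator.

    ``rheobase`` (spikes/s) is the firing frequency required for a
    half-maximal reward at infinite train duration; ``chronaxie`` (s) is the
    train duration at which that requirement doubles.
    """

    rheobase: float
    chronaxie: float

    def __post_init__(self) -> None:
        if not (self.rheobase > 0 and self.chronaxie > 0):
            raise ValueError("rheobase and chronaxie must be positive")


@dataclass(frozen=True)
class TransformParams:
    """Bundle of the two sensory-side transforms used by the surfaces."""

    subjective_price: SubjectivePriceParams = SubjectivePriceParams()
    frequency_following: FrequencyFollowingParams = FrequencyFollowingParams()


DEFAULT_SUBJECTIVE_PRICE = SubjectivePriceParams()
DEFAULT_FREQUENCY_FOLLOWING = FrequencyFollowingParams()
DEFAULT_TRANSFORMS = TransformParams()


def subjective_price(p, params: SubjectivePriceParams = DEFAULT_SUBJECTIVE_PRICE):
    """Map an objective price ``p`` (s) to its subjective equivalent (s).

    SP = sp_min + sp_bend * ln(1 + exp((p - sp_min) / sp_bend)).

    Strictly increasing; approaches ``sp_min`` as p -> 0 and the identity
    line as p grows.  Accepts scalars or arrays; scalar in, scalar out.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("objective price must be non-negative")
    out = params.sp_min + params.sp_bend * _softplus((arr - params.sp_min) / params.sp_bend)
    return out.item() if np.isscalar(p) or arr.ndim == 0 else out


def objective_price_from_subjective(
    sp: float, params: SubjectivePriceParams = DEFAULT_SUBJECTIVE_PRICE
) -> float:
    """Invert :func:`subjective_price` by monotone root finding.

    Raises ``ValueError`` when ``sp`` is at or below ``sp_min``, where no
    finite objective price exists.
    """
    if sp <= params.sp_min:
        raise ValueError(
            f"subjective price {sp} is at or below the floor sp_min={params.sp_min}; "
            "no objective price maps there"
        )
    # SP(p) >= p, and SP(p) <= sp_min + sp_bend*softplus at p = sp, so [0, sp]
    # always brackets the root.
    lo, hi = 0.0, float(sp)
    return float(
        brentq(lambda p: subjective_price(p, params) - sp, lo, hi, xtol=_INVERSE_TOL)
    )


def firing_plateau(params: FrequencyFollowingParams = DEFAULT_FREQUENCY_FOLLOWING) -> float:
    """Asymptotic induced firing frequency (spikes/s) of the following map."""
    return float(params.f_bend * _softplus(params.f_near_max / params.f_bend))


def frequency_following(f, params: FrequencyFollowingParams = DEFAULT_FREQUENCY_FOLLOWING):
    """Map a pulse frequency ``f`` (pulses/s) to induced firing (spikes/s).

    FF = f_bend * [ln(1 + e^(f_near_max/f_bend)) - ln(1 + e^((f_near_max-f)/f_bend))].

    Exactly zero at f = 0; close to the identity (one spike per pulse) well
    below ``f_near_max``; saturates at :func:`firing_plateau` above it.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pulse frequency must be non-negative")
    fb, fnm = params.f_bend, params.f_near_max
    out = fb * (_softplus(fnm / fb) - _softplus((fnm - arr) / fb))
    return out.item() if np.isscalar(f) or arr.ndim == 0 else out


class InverseFrequencyResult(NamedTuple):
    """Result of inverting the frequency-following map.

    When the demanded firing frequency meets or exceeds the plateau no pulse
    frequency can produce it: ``unreachable`` is True and ``pulse_frequency``
    is NaN.  This is a real regime of the dual-integrator mechanism, not an
    error.
    """

    pulse_frequency: float
    unreachable: bool


def pulse_frequency_for_firing(
    ff: float, params: FrequencyFollowingParams = DEFAULT_FREQUENCY_FOLLOWING
) -> InverseFrequencyResult:
    """Pulse frequency required to induce firing at ``ff`` spikes/s.

    Returns an :class:`InverseFrequencyResult`; demands at or above the
    plateau are flagged ``unreachable`` rather than raised.
    """
    if ff < 0:
        raise ValueError("firing frequency must be non-negative")
    if ff == 0:
        return InverseFrequencyResult(0.0, False)
    plateau = firing_plateau(params)
    if ff >= plateau:
        return InverseFrequencyResult(float("nan"), True)
    # FF(f) <= f, so f = ff is a lower bracket; grow the upper bracket until
    # it clears the target.
    hi = max(ff, params.f_near_max)
    while frequency_following(hi, params) < ff:
        hi *= 2.0
    root = brentq(lambda f: frequency_following(f, params) - ff, 0.0, hi, xtol=_INVERSE_TOL)
    return InverseFrequencyResult(float(root), False)


def half_max_firing_at_duration(d, params: StrengthDurationParams):
    """Firing frequency (spikes/s) required for half-maximal reward at duration ``d``.

    FFhm(d) = rheobase * (1 + chronaxie / d): strictly decreasing in d,
    approaching the rheobase for very long trains and doubling it at
    d = chronaxie.
    """
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("train duration must be positive")
    out = params.rheobase * (1.0 + params.chronaxie / arr)
    return out.item() if np.isscalar(d) or arr.ndim == 0 else out
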