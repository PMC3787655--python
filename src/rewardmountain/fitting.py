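"""Fitting the reward mountain and bootstrap inference on its location.

The mountain is fitted jointly across the two train-duration conditions by
nonlinear least squares on individual time-allocation observations.  The
payoff-sensitivity exponent ``a``, reward-growth exponent ``g`` and floor
``ta_min`` are shared between durations; the location parameters ``f_hm``
and ``p_e`` and the ceiling ``ta_max`` are free per duration.  Location
parameters are optimised on the log scale and reported in natural units.

Uncertainty comes from a case bootstrap at the design-point level: at every
(duration, frequency, price) point, the point's replicate set is resampled
with replacement at its own size (8 or 16 in the reference design), the
surface is refitted, and percentile confidence intervals are read off the
order statistics of the resample estimates — for B = 1000 the 95% interval
excludes exactly the lowest and highest 25 estimates.  Train-duration
shifts in a location parameter are judged per resample (the per-duration
estimates of one resample come from one joint fit), summarised by the
median difference and its percentile interval, and called significant when
that interval excludes zero.

A constrained dual-integrator fit is also provided: the shape parameters
are frozen at single-fit values, chronaxies are capped (6 s by default),
and the two integrators are identified by ordering their chronaxies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, log_expit

from .mountain import DualMountainParams, DurationBlock, SingleMountainParams
from .transforms import (
    DEFAULT_TRANSFORMS,
    StrengthDurationParams,
    TransformParams,
    firing_plateau,
    frequency_following,
    subjective_price,
)

__all__ = [
    "FitSpec",
    "FitResult",
    "BootstrapSummary",
    "BootstrapResult",
    "ShiftEstimate",
    "fit_mountain",
    "bootstrap_fit",
    "resample_weights",
    "percentile_ci",
    "shift_inference",
    "duration_shift_report",
    "compare_models",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "train_duration_s",
    "pulse_frequency_pps",
    "price_s",
    "time_allocation",
)


@dataclass(frozen=True)
class FitSpec:
    """What to fit and how.

    ``kind`` selects the single- or dual-integrator surface.  For the dual
    surface the shape parameters may be supplied in ``fixed`` (keys ``a``,
    ``g``, ``ta_min`` and ``ta_max`` — the latter a mapping from train
    duration to ceiling), normally taken from a prior single fit; this is
    the constrained fit used when the data cannot identify all dual
    parameters.  With ``fixed`` empty the shape parameters are fitted too
    (the unconstrained variant used for information-criterion comparison).
    ``chronaxie_max`` caps both chronaxies.  ``n_starts`` controls the
    seeded multistart; parameter boxes are finite wherever a parameter is
    free.
    """

    kind: str = "single"
    n_starts: int = 8
    fixed: dict = field(default_factory=dict)
    chronaxie_max: float = 6.0
    a_bounds: tuple[float, float] = (0.5, 50.0)
    g_bounds: tuple[float, float] = (0.5, 50.0)
    ta_min_bounds: tuple[float, float] = (0.0, 0.45)
    ta_max_bounds: tuple[float, float] = (0.5, 1.0)
    f_hm_bounds: tuple[float, float] = (5.0, 5000.0)
    p_e_bounds: tuple[float, float] = (0.2, 500.0)
    rheobase_bounds: tuple[float, float] = (1.0, 2000.0)
    chronaxie_min: float = 1e-3
    xtol: float = 1e-10
    ftol: float = 1e-10
    max_nfev: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("single", "dual"):
            raise ValueError("kind must be 'single' or 'dual'")
        if self.kind == "dual" and self.fixed:
            missing = {"a", "g", "ta_min", "ta_max"} - set(self.fixed)
            if missing:
                raise ValueError(
                    "constrained dual fits fix all shape parameters; "
                    f"missing {sorted(missing)}"
                )


@dataclass
class FitResult:
    """Point estimates and diagnostics of one joint surface fit."""

    kind: str
    params: SingleMountainParams | DualMountainParams
    estimates: dict[str, float]
    objective: float
    converged: bool
    active_bounds: dict[str, bool]
    n_obs: int
    n_free: int
    x: np.ndarray  # internal parameter vector (warm-start handle)
    degenerate: bool = False


@dataclass
class BootstrapSummary:
    """B resample estimates of one parameter with mean and percentile CI."""

    parameter: str
    estimates: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_excluded_per_tail: int


@dataclass
class BootstrapResult:
    """Joint bootstrap output: one row per resample, one summary per parameter."""

    estimates: pd.DataFrame
    summaries: dict[str, BootstrapSummary]
    full_fit: FitResult
    B: int
    n_redrawn: int


@dataclass
class ShiftEstimate:
    """Per-resample long-minus-short difference of one location parameter."""

    parameter: str
    differences: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    significant: bool
    ci_nonoverlap: bool  # secondary criterion: the two per-duration CIs do not overlap


def _duration_key(name: str, duration: float) -> str:
    return f"{name}@{duration:g}"


class _Prepared:
    """Observation table unpacked into arrays, transforms pre-applied."""

    def __init__(self, observations: pd.DataFrame, tp: TransformParams):
        for col in REQUIRED_COLUMNS:
            if col not in observations.columns:
                raise ValueError(f"observations lack required column {col!r}")
        df = observations.reset_index(drop=True)
        self.ta = df["time_allocation"].to_numpy(float)
        self.f = df["pulse_frequency_pps"].to_numpy(float)
        self.p = df["price_s"].to_numpy(float)
        self.d = df["train_duration_s"].to_numpy(float)
        if np.any(self.ta < 0) or np.any(self.ta > 1):
            raise ValueError("time_allocation outside [0, 1]")
        self.durations = sorted(set(self.d))
        if len(self.durations) != 2:
            raise ValueError(
                f"observations must span exactly two train durations, got {self.durations}"
            )
        self.masks = [np.flatnonzero(self.d == dur) for dur in self.durations]
        with np.errstate(divide="ignore"):
            self.ln_ff = np.log(frequency_following(self.f, tp.frequency_following))
            self.ln_sp = np.log(subjective_price(self.p, tp.subjective_price))
        self.tp = tp
        self.n = len(df)
        self.df = df

    def point_groups(self) -> list[np.ndarray]:
        """Row indices grouped by design point (duration, frequency, price)."""
        key = pd.MultiIndex.from_arrays([self.d, self.f, self.p])
        return [np.asarray(idx) for _, idx in pd.Series(range(self.n), index=key).groupby(level=[0, 1, 2])]


def _single_residual_fn(prep: _Prepared, spec: FitSpec):
    tp = prep.tp

    def model_ta(theta: np.ndarray) -> np.ndarray:
        a, g = np.exp(theta[0]), np.exp(theta[1])
        ta_min = theta[2]
        out = np.empty(prep.n)
        for k, dur in enumerate(prep.durations):
            lf_hm, lp_e, ta_max = theta[3 + 3 * k : 6 + 3 * k]
            ln_ff_hm = np.log(frequency_following(np.exp(lf_hm), tp.frequency_following))
            ln_sp_e = np.log(subjective_price(np.exp(lp_e), tp.subjective_price))
            idx = prep.masks[k]
            ln_u = log_expit(g * (prep.ln_ff[idx] - ln_ff_hm))
            ln_payoff = ln_u - (prep.ln_sp[idx] - ln_sp_e)
            out[idx] = (ta_max - ta_min) * expit(a * ln_payoff) + ta_min
        return out

    return model_ta


def _dual_shape(prep: _Prepared, spec: FitSpec, theta: np.ndarray):
    """(a, g, ta_min, {duration: ta_max}) from ``fixed`` or the tail of theta."""
    if spec.fixed:
        return (
            float(spec.fixed["a"]),
            float(spec.fixed["g"]),
            float(spec.fixed["ta_min"]),
            {float(k): float(v) for k, v in spec.fixed["ta_max"].items()},
        )
    a, g = float(np.exp(theta[6])), float(np.exp(theta[7]))
    ta_min = float(theta[8])
    ta_max = {dur: float(theta[9 + k]) for k, dur in enumerate(prep.durations)}
    return a, g, ta_min, ta_max


def _dual_residual_fn(prep: _Prepared, spec: FitSpec):
    def model_ta(theta: np.ndarray) -> np.ndarray:
        c1, c2, r1, r2 = np.exp(theta[:4])
        w = theta[4]
        ln_ps = theta[5]
        a, g, ta_min, ta_max = _dual_shape(prep, spec, theta)
        out = np.empty(prep.n)
        for k, dur in enumerate(prep.durations):
            idx = prep.masks[k]
            ln_d1 = np.log(r1 * (1.0 + c1 / dur))
            ln_d2 = np.log(r2 * (1.0 + c2 / dur))
            u1 = expit(g * (prep.ln_ff[idx] - ln_d1))
            u2 = expit(g * (prep.ln_ff[idx] - ln_d2))
            intensity = w * u1 + (1.0 - w) * u2
            with np.errstate(divide="ignore"):
                ln_payoff = np.log(intensity) + ln_ps - prep.ln_sp[idx]
            out[idx] = (ta_max[dur] - ta_min) * expit(a * ln_payoff) + ta_min
        return out

    return model_ta


def _half_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """Abscissa (log-interpolated) where a noisy profile crosses ``level``."""
    order = np.argsort(x)
    x, y = np.log(x[order]), y[order]
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            t = (level - y0) / (y1 - y0)
            return float(np.exp(x[i] + t * (x[i + 1] - x[i])))
    return None


def _single_init(prep: _Prepared, spec: FitSpec) -> np.ndarray:
    """Data-driven starting vector for the single fit.

    ``f_hm`` starts at the frequency sweep's half-rise, ``p_e`` at the
    price sweep's half-fall, falling back to geometric medians when the
    profile never crosses halfway.
    """
    ta_lo = float(np.quantile(prep.ta, 0.1))
    ta_hi = float(np.quantile(prep.ta, 0.9))
    halfway = (ta_lo + ta_hi) / 2.0
    theta = [np.log(4.0), np.log(4.0), np.clip(ta_lo, *spec.ta_min_bounds)]
    has_sweeps = "sweep_type" in prep.df.columns
    for k, dur in enumerate(prep.durations):
        sub = prep.df[prep.df["train_duration_s"] == dur]
        f_hm = p_e = None
        if has_sweeps:
            fs = sub[sub["sweep_type"] == "frequency"]
            if len(fs):
                prof = fs.groupby("pulse_frequency_pps")["time_allocation"].mean()
                f_hm = _half_crossing(
                    prof.index.to_numpy(float), prof.to_numpy(float), halfway
                )
            ps = sub[sub["sweep_type"] == "price"]
            if len(ps):
                prof = ps.groupby("price_s")["time_allocation"].mean()
                p_e = _half_crossing(
                    prof.index.to_numpy(float), prof.to_numpy(float), halfway
                )
        if f_hm is None:
            f_hm = float(np.exp(np.median(np.log(sub["pulse_frequency_pps"]))))
        if p_e is None:
            p_e = float(np.exp(np.median(np.log(sub["price_s"]))))
        theta += [
            np.log(np.clip(f_hm, *spec.f_hm_bounds)),
            np.log(np.clip(p_e, *spec.p_e_bounds)),
            np.clip(ta_hi, *spec.ta_max_bounds),
        ]
    return np.asarray(theta)


def _single_bounds(prep: _Prepared, spec: FitSpec):
    lo = [np.log(spec.a_bounds[0]), np.log(spec.g_bounds[0]), spec.ta_min_bounds[0]]
    hi = [np.log(spec.a_bounds[1]), np.log(spec.g_bounds[1]), spec.ta_min_bounds[1]]
    for _ in prep.durations:
        lo += [np.log(spec.f_hm_bounds[0]), np.log(spec.p_e_bounds[0]), spec.ta_max_bounds[0]]
        hi += [np.log(spec.f_hm_bounds[1]), np.log(spec.p_e_bounds[1]), spec.ta_max_bounds[1]]
    return np.asarray(lo), np.asarray(hi)


def _dual_init(prep: _Prepared, spec: FitSpec, tp: TransformParams) -> np.ndarray:
    plateau = firing_plateau(tp.frequency_following)
    c0 = np.sqrt(spec.chronaxie_min * spec.chronaxie_max)
    theta = [
        np.log(c0 / 2),
        np.log(min(2 * c0, spec.chronaxie_max)),
        np.log(plateau / 8),
        np.log(plateau / 3),
        0.5,
        np.log(2.0 * subjective_price(np.median(prep.p), tp.subjective_price)),
    ]
    if not spec.fixed:
        ta_lo = float(np.quantile(prep.ta, 0.1))
        ta_hi = float(np.quantile(prep.ta, 0.9))
        theta += [np.log(4.0), np.log(4.0), np.clip(ta_lo, *spec.ta_min_bounds)]
        theta += [np.clip(ta_hi, *spec.ta_max_bounds)] * len(prep.durations)
    return np.asarray(theta)


def _dual_bounds(prep: _Prepared, spec: FitSpec, tp: TransformParams):
    sp_lo = tp.subjective_price.sp_min
    lo = [
        np.log(spec.chronaxie_min), np.log(spec.chronaxie_min),
        np.log(spec.rheobase_bounds[0]), np.log(spec.rheobase_bounds[0]),
        0.0, np.log(sp_lo * 1.05),
    ]
    hi = [
        np.log(spec.chronaxie_max), np.log(spec.chronaxie_max),
        np.log(spec.rheobase_bounds[1]), np.log(spec.rheobase_bounds[1]),
        1.0, np.log(1e4),
    ]
    if not spec.fixed:
        lo += [np.log(spec.a_bounds[0]), np.log(spec.g_bounds[0]), spec.ta_min_bounds[0]]
        hi += [np.log(spec.a_bounds[1]), np.log(spec.g_bounds[1]), spec.ta_min_bounds[1]]
        lo += [spec.ta_max_bounds[0]] * len(prep.durations)
        hi += [spec.ta_max_bounds[1]] * len(prep.durations)
    return np.asarray(lo), np.asarray(hi)


def _result_from_theta(
    prep: _Prepared, spec: FitSpec, theta: np.ndarray, objective: float,
    converged: bool, lo: np.ndarray, hi: np.ndarray,
) -> FitResult:
    names: list[str] = []
    active = {}
    degenerate = float(np.ptp(prep.ta)) < 1e-12
    if spec.kind == "single":
        a, g = float(np.exp(theta[0])), float(np.exp(theta[1]))
        ta_min = float(theta[2])
        blocks = {}
        est = {"a": a, "g": g, "ta_min": ta_min}
        names = ["a", "g", "ta_min"]
        for k, dur in enumerate(prep.durations):
            f_hm = float(np.exp(theta[3 + 3 * k]))
            p_e = float(np.exp(theta[4 + 3 * k]))
            ta_max = float(theta[5 + 3 * k])
            blocks[dur] = DurationBlock(f_hm=f_hm, p_e=p_e, ta_max=ta_max)
            est[_duration_key("f_hm", dur)] = f_hm
            est[_duration_key("p_e", dur)] = p_e
            est[_duration_key("ta_max", dur)] = ta_max
            names += [
                _duration_key("f_hm", dur),
                _duration_key("p_e", dur),
                _duration_key("ta_max", dur),
            ]
        params: SingleMountainParams | DualMountainParams = SingleMountainParams(
            a=a, g=g, ta_min=ta_min, blocks=blocks
        )
        n_free = len(theta)
    else:
        c1, c2, r1, r2 = (float(v) for v in np.exp(theta[:4]))
        w = float(theta[4])
        ps = float(np.exp(theta[5]))
        if c1 > c2:  # identify integrators by ordering chronaxies
            c1, c2, r1, r2, w = c2, c1, r2, r1, 1.0 - w
            theta = np.concatenate(
                [[np.log(c1), np.log(c2), np.log(r1), np.log(r2), w, theta[5]], theta[6:]]
            )
        a, g, ta_min, ta_max = _dual_shape(prep, spec, theta)
        params = DualMountainParams(
            integrator1=StrengthDurationParams(rheobase=r1, chronaxie=c1),
            integrator2=StrengthDurationParams(rheobase=r2, chronaxie=c2),
            w=w,
            price_scale=ps,
            a=a,
            g=g,
            ta_min=ta_min,
            ta_max=ta_max,
        )
        est = {
            "chronaxie1": c1, "chronaxie2": c2,
            "rheobase1": r1, "rheobase2": r2,
            "w": w, "price_scale": ps,
        }
        names = list(est)
        if not spec.fixed:
            est.update({"a": a, "g": g, "ta_min": ta_min})
            names += ["a", "g", "ta_min"]
            for dur in prep.durations:
                est[_duration_key("ta_max", dur)] = ta_max[dur]
                names.append(_duration_key("ta_max", dur))
        n_free = len(theta)
    for name, x, l, h in zip(names, theta, lo, hi):
        active[name] = bool(min(x - l, h - x) < 1e-8)
    return FitResult(
        kind=spec.kind,
        params=params,
        estimates=est,
        objective=float(objective),
        converged=converged,
        active_bounds=active,
        n_obs=prep.n,
        n_free=n_free,
        x=np.asarray(theta, float),
        degenerate=degenerate,
    )


def _fit_prepared(
    prep: _Prepared,
    spec: FitSpec,
    seed: int,
    weights: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    n_starts: int | None = None,
) -> FitResult:
    tp = prep.tp
    if spec.kind == "single":
        model_fn = _single_residual_fn(prep, spec)
        lo, hi = _single_bounds(prep, spec)
        init = _single_init(prep, spec) if x0 is None else np.asarray(x0, float)
    else:
        model_fn = _dual_residual_fn(prep, spec)
        lo, hi = _dual_bounds(prep, spec, tp)
        init = _dual_init(prep, spec, tp) if x0 is None else np.asarray(x0, float)
    init = np.clip(init, lo, hi)
    sqrt_w = np.ones(prep.n) if weights is None else np.sqrt(np.asarray(weights, float))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return (model_fn(theta) - prep.ta) * sqrt_w

    rng = np.random.default_rng(seed)
    n_starts = spec.n_starts if n_starts is None else n_starts
    best: tuple[float, tuple, np.ndarray, bool] | None = None
    n_ok = 0
    for s in range(n_starts):
        start = init.copy()
        if s > 0:  # log-uniform jitter around the data-driven start
            start = np.clip(start + rng.uniform(-0.3, 0.3, size=start.shape), lo, hi)
        try:
            sol = least_squares(
                residuals, start, bounds=(lo, hi), method="trf",
                xtol=spec.xtol, ftol=spec.ftol, max_nfev=spec.max_nfev,
            )
        except Exception:  # numerical breakdown from a bad start
            continue
        if sol.status <= 0:
            continue
        n_ok += 1
        key = (float(sol.cost), tuple(np.round(sol.x, 12)))
        if best is None or key < best[:2]:
            best = (*key, sol.x, True)
    if best is None:
        raise RuntimeError(
            f"no optimizer start converged ({n_starts} starts, kind={spec.kind})"
        )
    cost, _, x, converged = best
    return _result_from_theta(prep, spec, x, 2.0 * cost, converged, lo, hi)


def fit_mountain(
    observations: pd.DataFrame,
    spec: FitSpec | None = None,
    tp: TransformParams = DEFAULT_TRANSFORMS,
    seed: int = 0,
    x0: np.ndarray | None = None,
) -> FitResult:
    """Jointly fit the mountain surface to an observation table.

    Minimises the summed squared time-allocation residuals over all
    observations at both train durations, with shape parameters shared and
    location/ceiling parameters per duration, via bounded trust-region
    least squares with a seeded multistart.  ``objective`` on the result is
    the residual sum of squares.  Degenerate data (zero TA variance) are
    fitted but flagged.
    """
    spec = spec or FitSpec()
    prep = _Prepared(observations, tp)
    result = _fit_prepared(prep, spec, seed, x0=x0)
    if result.degenerate:
        logger.warning("observations have zero variance; fit is flagged degenerate")
    return result


def percentile_ci(estimates: np.ndarray, B: int | None = None) -> tuple[float, float, int]:
    """Percentile interval by the drop-⌈0.025·B⌉-per-tail order-statistic rule.

    Returns (low, high, n_excluded_per_tail); both endpoints are elements
    of the estimate multiset (no interpolation).
    """
    est = np.sort(np.asarray(estimates, float))
    B = len(est) if B is None else B
    k = int(np.ceil(0.025 * B))
    return float(est[k]), float(est[B - 1 - k]), k


def resample_weights(
    point_groups: list[np.ndarray], n_rows: int, rng: np.random.Generator
) -> np.ndarray:
    """One bootstrap resample as per-row replicate counts.

    Drawing n values with replacement from a design point's n observations
    is equivalent to a multinomial count vector over its rows, so every
    resample conserves each point's sample size exactly.
    """
    weights = np.zeros(n_rows)
    for idx in point_groups:
        n = len(idx)
        weights[idx] = rng.multinomial(n, np.full(n, 1.0 / n))
    return weights


def bootstrap_fit(
    observations: pd.DataFrame,
    spec: FitSpec | None = None,
    B: int = 1000,
    seed: int = 0,
    tp: TransformParams = DEFAULT_TRANSFORMS,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Case bootstrap at the design-point level with joint refits.

    For each of ``B`` resamples, every design point's replicate set is
    resampled with replacement at its own size and the surface refitted
    (warm-started at the full-data estimates).  Resample fits that fail are
    redrawn, with the count reported; if more than ``max_failure_rate * B``
    redraws are needed the run aborts.
    """
    spec = spec or FitSpec()
    prep = _Prepared(observations, tp)
    full = _fit_prepared(prep, spec, seed)
    groups = prep.point_groups()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    rows: list[dict[str, float]] = []
    n_redrawn = 0
    max_redraws = int(np.ceil(max_failure_rate * B))
    while len(rows) < B:
        weights = resample_weights(groups, prep.n, rng)
        try:
            res = _fit_prepared(prep, spec, seed, weights=weights, x0=full.x, n_starts=1)
        except RuntimeError:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError(
                    f"bootstrap aborted: {n_redrawn} failed resample fits "
                    f"(ceiling {max_redraws} for B={B})"
                )
            continue
        rows.append(res.estimates)
    if n_redrawn:
        logger.info("bootstrap redrew %d failed resample fit(s)", n_redrawn)

    est_df = pd.DataFrame(rows)
    summaries = {}
    for name in est_df.columns:
        vec = est_df[name].to_numpy(float)
        lo, hi, k = percentile_ci(vec, B)
        summaries[name] = BootstrapSummary(
            parameter=name,
            estimates=vec,
            mean=float(vec.mean()),
            ci_low=lo,
            ci_high=hi,
            n_excluded_per_tail=k,
        )
    return BootstrapResult(
        estimates=est_df, summaries=summaries, full_fit=full, B=B, n_redrawn=n_redrawn
    )


def shift_inference(
    boot_long: BootstrapSummary, boot_short: BootstrapSummary
) -> ShiftEstimate:
    """Train-duration shift of one location parameter, long minus short.

    Both summaries must come from the same bootstrap run so that resample
    indices pair up (each resample's per-duration estimates come from one
    joint fit).  The shift is significant when the percentile interval of
    the per-resample differences excludes zero; the secondary criterion
    (non-overlap of the two parameters' own intervals) is reported too.
    """
    if len(boot_long.estimates) != len(boot_short.estimates):
        raise ValueError(
            "mismatched bootstrap sizes: summaries are not from the same run"
        )
    diffs = boot_long.estimates - boot_short.estimates
    lo, hi, _ = percentile_ci(diffs)
    significant = not (lo <= 0.0 <= hi)
    nonoverlap = boot_long.ci_low > boot_short.ci_high or boot_short.ci_low > boot_long.ci_high
    return ShiftEstimate(
        parameter=boot_long.parameter,
        differences=diffs,
        median=float(np.median(diffs)),
        ci_low=lo,
        ci_high=hi,
        significant=significant,
        ci_nonoverlap=nonoverlap,
    )


def duration_shift_report(
    boot: BootstrapResult,
    short: float = 0.25,
    long: float = 1.0,
    parameters: tuple[str, ...] = ("f_hm", "p_e", "ta_max"),
) -> dict[str, ShiftEstimate]:
    """Shift estimates (long minus short) for each per-duration parameter."""
    out = {}
    for name in parameters:
        key_l, key_s = _duration_key(name, long), _duration_key(name, short)
        if key_l not in boot.summaries or key_s not in boot.summaries:
            continue
        est = shift_inference(boot.summaries[key_l], boot.summaries[key_s])
        out[name] = replace(est, parameter=name)
    return out


def compare_models(observations: pd.DataFrame, *fits: FitResult) -> pd.DataFrame:
    """Gaussian-likelihood AIC/BIC table for converged fits (lower is better).

    AIC = n ln(RSS/n) + 2k and BIC = n ln(RSS/n) + k ln n with k the number
    of free parameters; non-converged fits are excluded with a warning.
    """
    n = len(observations)
    rows = []
    for fit in fits:
        if not fit.converged:
            warnings.warn(
                f"{fit.kind} fit did not converge; excluded from comparison",
                stacklevel=2,
            )
            continue
        rss = max(fit.objective, 1e-300)
        k = fit.n_free
        rows.append(
            {
                "model": fit.kind,
                "rss": fit.objective,
                "n_free": k,
                "n_obs": n,
                "aic": n * np.log(rss / n) + 2 * k,
                "bic": n * np.log(rss / n) + k * np.log(n),
            }
        )
    return pd.DataFrame(rows).sort_values("bic", ignore_index=True) if rows else pd.DataFrame(
        columns=["model", "rss", "n_free", "n_obs", "aic", "bic"]
    )
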