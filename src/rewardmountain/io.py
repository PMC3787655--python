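"""Observation-table I/O, run configuration, and report assembly.

The long-format observation CSV is the interchange format of the pipeline:
one row per test trial with columns ``subject``, ``train_duration_s``,
``pulse_frequency_pps``, ``price_s``, ``sweep_type``, ``survey``,
``time_allocation``.  Replicates at a design point are rows, which matches
the resampling unit of the bootstrap.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .fitting import BootstrapResult, ShiftEstimate
from .mountain import DurationBlock, SingleMountainParams
from .synthetic import GroundTruth, build_pseudo_sweeps
from .transforms import (
    FrequencyFollowingParams,
    SubjectivePriceParams,
    TransformParams,
)

__all__ = [
    "OBSERVATION_COLUMNS",
    "ObservationValidationError",
    "read_observations",
    "write_observations",
    "assemble_shift_report",
    "format_shift_report",
    "RunConfig",
    "run_manifest",
]

OBSERVATION_COLUMNS = (
    "subject",
    "train_duration_s",
    "pulse_frequency_pps",
    "price_s",
    "sweep_type",
    "survey",
    "time_allocation",
)


class ObservationValidationError(ValueError):
    """Raised for schema or range violations, with CSV line numbers."""


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read and validate an observation CSV.

    Checks the full column schema, TA in [0, 1], positive prices and
    frequencies, and positive train durations; failures carry 1-based CSV
    line numbers (the header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise ObservationValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    problems = []

    def check(mask: pd.Series, message: str) -> None:
        for i in df.index[mask][:10]:
            problems.append(f"line {i + 2}: {message}")

    ta = df["time_allocation"]
    check(ta.isna() | (ta < 0) | (ta > 1), "time_allocation outside [0, 1]")
    check(df["price_s"] <= 0, "price_s must be positive")
    check(df["pulse_frequency_pps"] <= 0, "pulse_frequency_pps must be positive")
    check(df["train_duration_s"] <= 0, "train_duration_s must be positive")
    if problems:
        raise ObservationValidationError(f"{path}:\n" + "\n".join(problems))
    return df


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    """Write an observation table with the canonical column order."""
    df.loc[:, list(OBSERVATION_COLUMNS)].to_csv(path, index=False)


def assemble_shift_report(
    shifts: dict[str, ShiftEstimate],
    boot: BootstrapResult | None = None,
    subject: str = "synthetic",
    short: float = 0.25,
    long: float = 1.0,
) -> pd.DataFrame:
    """One row per parameter: median long-minus-short shift, CI, star.

    ``starred`` marks shifts whose 95% percentile interval excludes zero.
    When the bootstrap result is provided, per-duration means of the
    ceiling ``ta_max`` are appended for context; otherwise the report is
    partial and a warning is issued.
    """
    rows = []
    for name, est in shifts.items():
        rows.append(
            {
                "subject": subject,
                "parameter": name,
                "median_shift": est.median,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "significant": est.significant,
                "ci_nonoverlap": est.ci_nonoverlap,
                "starred": "*" if est.significant else "",
            }
        )
    report = pd.DataFrame(rows)
    if boot is None:
        warnings.warn("no bootstrap result supplied; ta_max context omitted", stacklevel=2)
        return report
    for dur in (short, long):
        key = f"ta_max@{dur:g}"
        if key in boot.summaries:
            s = boot.summaries[key]
            report[f"ta_max_{dur:g}s_mean"] = s.mean
    return report


def format_shift_report(report: pd.DataFrame) -> str:
    """Human-readable rendering of the shift table."""
    if report.empty:
        return "no shift estimates\n"
    lines = ["train-duration shifts (long - short), percentile 95% CIs", ""]
    for row in report.itertuples(index=False):
        lines.append(
            f"  {row.parameter:>8s}: {row.median_shift:+10.4f} "
            f"[{row.ci_low:+10.4f}, {row.ci_high:+10.4f}] {row.starred}"
        )
    lines.append("")
    lines.append("  * = 95% confidence interval does not include zero")
    return "\n".join(lines) + "\n"


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulate/fit/bootstrap run."""

    seed: int = 0
    n_surveys: int = 8
    B: int = 1000
    noise_concentration: float = 40.0
    transforms: dict = field(
        default_factory=lambda: {
            "sp_min": 1.75, "sp_bend": 0.57, "f_bend": 20.63, "f_near_max": 342.9,
        }
    )
    truth: dict = field(
        default_factory=lambda: {
            "a": 4.0, "g": 4.0, "ta_min": 0.08,
            "blocks": {
                0.25: {"f_hm": 220.0, "p_e": 8.0, "ta_max": 0.92},
                1.0: {"f_hm": 110.0, "p_e": 8.0, "ta_max": 0.88},
            },
        }
    )
    design: dict = field(
        default_factory=lambda: {
            "f_span_decades": 1.0, "p_span_decades": 1.0,
            "low_price": 3.5, "high_frequency": 310.0,
        }
    )
    fit: dict = field(default_factory=lambda: {"kind": "single", "n_starts": 8})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ObservationValidationError(f"unknown config key {key!r}")
            if isinstance(getattr(cfg, key), dict):
                merged = dict(getattr(cfg, key))
                merged.update(value)
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def transform_params(self) -> TransformParams:
        t = self.transforms
        return TransformParams(
            subjective_price=SubjectivePriceParams(t["sp_min"], t["sp_bend"]),
            frequency_following=FrequencyFollowingParams(t["f_bend"], t["f_near_max"]),
        )

    def ground_truth(self) -> GroundTruth:
        t = self.truth
        blocks = {
            float(d): DurationBlock(b["f_hm"], b["p_e"], b["ta_max"])
            for d, b in t["blocks"].items()
        }
        model = SingleMountainParams(
            a=t["a"], g=t["g"], ta_min=t["ta_min"], blocks=blocks
        )
        return GroundTruth(
            model=model,
            tp=self.transform_params(),
            noise_concentration=self.noise_concentration,
            n_surveys=self.n_surveys,
        )

    def pseudo_sweeps(self):
        truth = self.ground_truth()
        sweeps = []
        for dur, blk in sorted(truth.model.blocks.items()):
            sweeps.extend(
                build_pseudo_sweeps(blk.f_hm, blk.p_e, dur, **self.design)
            )
        return sweeps


def run_manifest(config: RunConfig, **extra) -> dict:
    """Reproducibility manifest: config hash, seeds, B, package version."""
    blob = json.dumps(asdict(config), sort_keys=True, default=float)
    return {
        "package_version": __version__,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": config.seed,
        "B": config.B,
        **extra,
    }
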