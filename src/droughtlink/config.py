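"""Pipeline configuration.

All fixed constants of the exposure definitions live here, once: the dry-month
threshold (SPEI <= -1), the count-method minimum run length (5 consecutive dry
months), the sum-method cumulative threshold (-17.5), the recent-and-long rule
(strictly more than 12 consecutive dry months within the trailing 24), the
top-decile rule for the extreme categories, and the 48-month exposure window
ending the month before the interview.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SamplerSettings:
    """MCMC settings for the association model."""

    chains: int = 4
    draws: int = 750
    warmup: int = 500

    def validate(self) -> None:
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for split-Rhat")
        if self.draws < 4 or self.warmup < 10:
            raise ValueError("draws must be >= 4 and warmup >= 10")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run.

    Attributes
    ----------
    window_months:
        Length of the exposure window preceding each interview (months).
    recent_subwindow_months:
        Trailing sub-window used by the recent-and-long category.
    dry_threshold:
        A month is dry when SPEI <= this value.
    min_run_length:
        Minimum consecutive dry months for the count (duration) method.
    sum_threshold:
        A dry run is a sum-method (intensity) drought when its summed SPEI
        is <= this value.
    recent_long_min_run:
        recent-and-long requires STRICTLY more than this many consecutive
        dry months inside the trailing sub-window.
    extreme_percentile:
        Tail mass defining "top 10%" cutoffs for very-dry and
        prolonged-and-extreme.
    aggregation_mode:
        ``cell_then_average``: compute drought measures per grid cell, then
        coverage-weight-average them to districts (default).
        ``average_then_index``: average SPEI series to the district first,
        then compute measures on the district series.
    missing_data_policy:
        Only ``complete_case`` is supported.
    """

    window_months: int = 48
    recent_subwindow_months: int = 24
    dry_threshold: float = -1.0
    min_run_length: int = 5
    sum_threshold: float = -17.5
    recent_long_min_run: int = 12
    extreme_percentile: float = 0.10
    seed: int = 0
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    missing_data_policy: str = "complete_case"
    aggregation_mode: str = "cell_then_average"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (self.window_months >= self.recent_subwindow_months >= 1):
            raise ValueError(
                "window_months >= recent_subwindow_months >= 1 required, got "
                f"{self.window_months}, {self.recent_subwindow_months}"
            )
        if self.min_run_length < 1:
            raise ValueError("min_run_length must be >= 1")
        if not (0.0 < self.extreme_percentile < 1.0):
            raise ValueError("extreme_percentile must lie strictly in (0, 1)")
        if self.sum_threshold >= 0:
            raise ValueError("sum_threshold must be negative")
        if self.dry_threshold >= 0:
            raise ValueError("dry_threshold must be negative")
        if self.recent_long_min_run < 0:
            raise ValueError("recent_long_min_run must be >= 0")
        if self.missing_data_policy != "complete_case":
            raise ValueError("only complete_case missing-data policy is supported")
        if self.aggregation_mode not in ("cell_then_average", "average_then_index"):
            raise ValueError(f"unknown aggregation_mode {self.aggregation_mode!r}")
        self.sampler.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a plain-text key: value config file (YAML subset)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sampler = SamplerSettings(**raw.pop("sampler", {}))
        return cls(sampler=sampler, **raw)

    def echo(self) -> dict:
        """Resolved-config dictionary for provenance logging."""
        return asdict(self)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.echo(), fh, sort_keys=False)


def month_index(year: int, month: int) -> int:
    """Calendar month as a single integer: year*12 + (month - 1)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return year * 12 + month - 1


def index_to_year_month(idx: int) -> tuple[int, int]:
    """Inverse of :func:`month_index`."""
    return idx // 12, idx % 12 + 1
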