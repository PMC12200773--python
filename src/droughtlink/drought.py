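"""Run-length drought characterisation of monthly SPEI series.

A month is *dry* when its SPEI is at or below the dry threshold (default -1).
Two independent drought definitions operate on maximal runs of consecutive
dry months:

* **count method** (duration): a run of at least ``min_run_length`` (default 5)
  consecutive dry months is a drought; every month of the run counts.
* **sum method** (intensity): a run whose summed SPEI is at or below
  ``sum_threshold`` (default -17.5) is a drought; every month of the run
  counts, regardless of the run's length.

Each qualifying run is one *drought cycle* — an independent drought event
starting at the first month of the run and ending when conditions no longer
meet the threshold. Months satisfying both methods form the *both* measure,
whose maximal stretches are the both-cycles.

The *standardized dryness intensity* (sdi) compares areas on intensity alone:

    sdi = (sum of SPEI over sum-method cycles) / (average months per cycle)

where average months per cycle = (total sum-method drought months) /
(number of sum-method cycles). It is undefined (NaN) where no sum-method
cycle exists.

Four exposure categories summarise a 48-month window:

* slight-to-moderate — at least one mildly dry month (-1 < SPEI < 0);
* very dry — sdi in the most-negative decile across the sample;
* recent-and-long — a dry run of strictly more than 12 months within the
  trailing 24 months;
* prolonged-and-extreme — months meeting both methods in the top decile
  across the sample (and at least one such month).

Categories are not exclusive; a unit may carry several flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig

#: Sentinel for an undefined standardized dryness intensity (no sum-method cycle).
SDI_UNDEFINED = float("nan")


@dataclass
class SpeiSeries:
    """Contiguous monthly SPEI values for one spatial unit.

    ``values`` may contain NaN for missing months; missing months are never
    dry. Values outside [-10, 10] are rejected as corrupt.
    """

    unit_id: str
    start_month: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError(f"{self.unit_id}: series must be 1-D with length >= 1")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (np.abs(finite) > 10).any():
            bad = finite[np.abs(finite) > 10][0]
            raise ValueError(f"{self.unit_id}: SPEI value {bad} outside [-10, 10]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def end_month(self) -> int:
        return self.start_month + len(self) - 1

    def slice_window(self, window: tuple[int, int]) -> np.ndarray:
        """Values for the closed month range ``window``; error if not covered."""
        start, end = window
        if start < self.start_month or end > self.end_month:
            missing = sorted(
                set(range(start, end + 1))
                - set(range(self.start_month, self.end_month + 1))
            )
            raise ValueError(
                f"unit {self.unit_id}: window {window} not covered; "
                f"missing months {missing[:5]}{'...' if len(missing) > 5 else ''}"
            )
        off = start - self.start_month
        return self.values[off : off + (end - start + 1)]


@dataclass
class DryRun:
    """A maximal stretch of consecutive dry months."""

    start_month: int
    end_month: int
    sum_spei: float

    @property
    def length(self) -> int:
        return self.end_month - self.start_month + 1


@dataclass
class DroughtCycle:
    """One independent drought event under a given method."""

    start_month: int
    end_month: int
    method: str  # count | sum | both
    sum_spei: float

    @property
    def n_months(self) -> int:
        return self.end_month - self.start_month + 1


@dataclass
class DroughtWindowSummary:
    """All drought measures for one unit over one window.

    Counts may be fractional after grid-to-district averaging.
    """

    unit_id: str
    window: tuple[int, int]
    n_dry: float
    n_count: float
    n_sum: float
    n_both: float
    cycles_count: float
    cycles_sum: float
    cycles_both: float
    sdi: float  # NaN when undefined
    recent_max_run: float
    n_slight_moderate: float

    @property
    def sdi_defined(self) -> bool:
        return not math.isnan(self.sdi)


@dataclass
class CategoryThresholds:
    """Sample-wide percentile cutoffs for the two extreme categories."""

    sdi_cutoff: float  # NaN when no unit has a defined sdi
    both_cutoff: float
    n_units_sdi: int = 0
    n_units_both: int = 0


@dataclass
class ExposureProfile:
    """Four (possibly overlapping) exposure-category flags for one unit."""

    unit_id: str
    slight_to_moderate: bool
    very_dry: bool
    recent_and_long: bool
    prolonged_extreme: bool

    def as_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "slight_to_moderate": self.slight_to_moderate,
            "very_dry": self.very_dry,
            "recent_and_long": self.recent_and_long,
            "prolonged_extreme": self.prolonged_extreme,
        }


def flag_dry_months(values: np.ndarray, dry_threshold: float = -1.0) -> np.ndarray:
    """Boolean dry-month flags: True where SPEI <= dry_threshold.

    NaN (missing) months are never dry.
    """
    values = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        return (values <= dry_threshold) & np.isfinite(values)


def extract_runs(
    dry_flags: np.ndarray, values: np.ndarray, start_month: int = 0
) -> list[DryRun]:
    """Maximal runs of consecutive dry months, in order.

    ``values`` supplies the SPEI sums; runs partition the dry months exactly.
    """
    flags = np.asarray(dry_flags, dtype=bool)
    values = np.asarray(values, dtype=float)
    if flags.shape != values.shape:
        raise ValueError("dry_flags and values must be aligned")
    runs: list[DryRun] = []
    padded = np.concatenate(([False], flags, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    for s, e in zip(starts, ends):
        runs.append(
            DryRun(
                start_month=start_month + int(s),
                end_month=start_month + int(e),
                sum_spei=float(values[s : e + 1].sum()),
            )
        )
    return runs


def _flags_from_runs(
    runs: list[DryRun], n: int, start_month: int, qualifies
) -> tuple[np.ndarray, list[DroughtCycle]]:
    flags = np.zeros(n, dtype=bool)
    cycles: list[DroughtCycle] = []
    for run in runs:
        method = qualifies(run)
        if method is None:
            continue
        s = run.start_month - start_month
        flags[s : s + run.length] = True
        cycles.append(
            DroughtCycle(
                start_month=run.start_month,
                end_month=run.end_month,
                method=method,
                sum_spei=run.sum_spei,
            )
        )
    return flags, cycles


def count_method(
    runs: list[DryRun], n: int, start_month: int = 0, min_run_length: int = 5
) -> tuple[np.ndarray, list[DroughtCycle]]:
    """Duration criterion: runs of at least ``min_run_length`` dry months."""
    return _flags_from_runs(
        runs, n, start_month, lambda r: "count" if r.length >= min_run_length else None
    )


def sum_method(
    runs: list[DryRun], n: int, start_month: int = 0, sum_threshold: float = -17.5
) -> tuple[np.ndarray, list[DroughtCycle]]:
    """Intensity criterion: runs whose summed SPEI is <= ``sum_threshold``.

    Applies to maximal dry runs of any length; a short run of severely
    negative months qualifies.
    """
    return _flags_from_runs(
        runs, n, start_month, lambda r: "sum" if r.sum_spei <= sum_threshold else None
    )


def combine_methods(
    count_flags: np.ndarray,
    sum_flags: np.ndarray,
    values: np.ndarray,
    start_month: int = 0,
) -> tuple[np.ndarray, list[DroughtCycle]]:
    """Months meeting both criteria; both-cycles are their maximal stretches."""
    count_flags = np.asarray(count_flags, dtype=bool)
    sum_flags = np.asarray(sum_flags, dtype=bool)
    both = count_flags & sum_flags
    cycles = [
        DroughtCycle(r.start_month, r.end_month, "both", r.sum_spei)
        for r in extract_runs(both, np.asarray(values, dtype=float), start_month)
    ]
    return both, cycles


def standardized_intensity(
    total_sum_spei: float, n_sum_months: float, cycles_sum: float
) -> float:
    """sdi = summed SPEI over sum-method cycles / average months per cycle.

    Average months per cycle is n_sum_months / cycles_sum. Undefined (NaN)
    when there is no sum-method cycle; never reported as 0.
    """
    if cycles_sum == 0:
        return SDI_UNDEFINED
    avg_cycle_months = n_sum_months / cycles_sum
    return float(total_sum_spei / avg_cycle_months)


def recent_max_run(
    runs: list[DryRun], window: tuple[int, int], recent_subwindow_months: int = 24
) -> int:
    """Longest dry run after truncation to the trailing sub-window.

    Each maximal dry run is clipped to the last ``recent_subwindow_months``
    months of the window; the maximum clipped overlap is returned. A run is
    counted by the months it contributes within the sub-window, not by where
    it started.
    """
    start, end = window
    if end - start + 1 < recent_subwindow_months:
        raise ValueError("window shorter than recent sub-window")
    sub_start = end - recent_subwindow_months + 1
    best = 0
    for run in runs:
        overlap = min(run.end_month, end) - max(run.start_month, sub_start) + 1
        best = max(best, overlap)
    return best


def summarize_window(
    series: SpeiSeries,
    window: tuple[int, int],
    config: PipelineConfig | None = None,
) -> DroughtWindowSummary:
    """Compute every drought measure for one unit over one closed window."""
    cfg = config or PipelineConfig()
    vals = series.slice_window(window)
    start = window[0]
    dry = flag_dry_months(vals, cfg.dry_threshold)
    runs = extract_runs(dry, vals, start)
    cflags, ccycles = count_method(runs, len(vals), start, cfg.min_run_length)
    sflags, scycles = sum_method(runs, len(vals), start, cfg.sum_threshold)
    bflags, bcycles = combine_methods(cflags, sflags, vals, start)
    with np.errstate(invalid="ignore"):
        mild = (vals > cfg.dry_threshold) & (vals < 0) & np.isfinite(vals)
    sdi = standardized_intensity(
        sum(c.sum_spei for c in scycles), float(sflags.sum()), len(scycles)
    )
    return DroughtWindowSummary(
        unit_id=series.unit_id,
        window=window,
        n_dry=float(dry.sum()),
        n_count=float(cflags.sum()),
        n_sum=float(sflags.sum()),
        n_both=float(bflags.sum()),
        cycles_count=float(len(ccycles)),
        cycles_sum=float(len(scycles)),
        cycles_both=float(len(bcycles)),
        sdi=sdi,
        recent_max_run=float(
            recent_max_run(runs, window, cfg.recent_subwindow_months)
        ),
        n_slight_moderate=float(mild.sum()),
    )


def compute_thresholds(
    summaries: list[DroughtWindowSummary], extreme_percentile: float = 0.10
) -> CategoryThresholds:
    """Sample-wide cutoffs for the very-dry and prolonged-and-extreme flags.

    ``sdi_cutoff`` is the ``extreme_percentile`` empirical quantile (linear
    interpolation) of the defined sdi values — the most-negative tail, since
    sdi <= 0. ``both_cutoff`` is the ``1 - extreme_percentile`` quantile of
    the both-months count over all units. Ties at a cutoff fall inside the
    extreme category.
    """
    if not summaries:
        raise ValueError("no summaries provided")
    sdi_vals = np.array([s.sdi for s in summaries if s.sdi_defined])
    both_vals = np.array([s.n_both for s in summaries], dtype=float)
    if sdi_vals.size == 0:
        warnings.warn(
            "no unit has a defined standardized dryness intensity; "
            "very_dry will be false everywhere"
        )
        sdi_cutoff = SDI_UNDEFINED
    else:
        if sdi_vals.size < 10:
            warnings.warn(
                f"only {sdi_vals.size} units have a defined sdi; "
                "the percentile cutoff is unstable"
            )
        sdi_cutoff = float(np.quantile(sdi_vals, extreme_percentile))
    both_cutoff = float(np.quantile(both_vals, 1.0 - extreme_percentile))
    return CategoryThresholds(
        sdi_cutoff=sdi_cutoff,
        both_cutoff=both_cutoff,
        n_units_sdi=int(sdi_vals.size),
        n_units_both=int(both_vals.size),
    )


def assign_categories(
    summary: DroughtWindowSummary,
    thresholds: CategoryThresholds,
    recent_long_min_run: float = 12,
) -> ExposureProfile:
    """Apply sample-wide thresholds to one unit's window summary."""
    very_dry = (
        summary.sdi_defined
        and not math.isnan(thresholds.sdi_cutoff)
        and summary.sdi <= thresholds.sdi_cutoff
    )
    return ExposureProfile(
        unit_id=summary.unit_id,
        slight_to_moderate=summary.n_slight_moderate >= 1,
        very_dry=bool(very_dry),
        recent_and_long=summary.recent_max_run > recent_long_min_run,
        prolonged_extreme=summary.n_both > 0 and summary.n_both >= thresholds.both_cutoff,
    )
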