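"""Grid-to-district aggregation and respondent exposure linkage.

Drought measures are computed per 0.5-degree grid cell and averaged to the
respondent's census district (administrative level two) using coverage
weights — the fraction of the district's area each cell covers. Respondents
interviewed in the same district and month share one exposure computation,
keyed by (district, window end month). The exposure window is the closed
48-month range ending the month before the interview month.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig, month_index
from .drought import (
    SDI_UNDEFINED,
    DroughtWindowSummary,
    SpeiSeries,
    assign_categories,
    compute_thresholds,
    summarize_window,
)


@dataclass(frozen=True)
class DistrictWindowKey:
    district_id: str
    window_end_month: int


def load_cell_weights(path: str | Path) -> pd.DataFrame:
    """Read a district/cell/weight CSV; weights renormalised to sum to 1
    within each district."""
    w = pd.read_csv(path, dtype={"district_id": str, "cell_id": str})
    required = {"district_id", "cell_id", "weight"}
    if missing := required - set(w.columns):
        raise ValueError(f"weight table missing columns {sorted(missing)}")
    if (w["weight"] <= 0).any():
        bad = w.loc[w["weight"] <= 0]
        raise ValueError(f"non-positive weights for rows {bad.index.tolist()}")
    if w.duplicated(["district_id", "cell_id"]).any():
        raise ValueError("duplicate (district, cell) weight entries")
    w["weight"] = w["weight"] / w.groupby("district_id")["weight"].transform("sum")
    return w


_MEASURES = [
    "n_dry",
    "n_count",
    "n_sum",
    "n_both",
    "cycles_count",
    "cycles_sum",
    "cycles_both",
    "recent_max_run",
    "n_slight_moderate",
]


def aggregate_district(
    cell_summaries: dict[str, DroughtWindowSummary],
    weights: pd.DataFrame,
    district_id: str,
    window: tuple[int, int],
) -> DroughtWindowSummary:
    """Coverage-weighted mean of cell-level measures for one district window.

    sdi is averaged only over cells where it is defined, with the weight
    mass of those cells renormalised; if no covering cell has a defined
    sdi, the district sdi is undefined.
    """
    rows = weights.loc[weights["district_id"] == district_id]
    if rows.empty:
        raise ValueError(f"no weights for district {district_id}")
    cells = rows["cell_id"].tolist()
    for cell in cells:
        if cell not in cell_summaries:
            raise ValueError(
                f"district {district_id}: missing summary for cell {cell}"
            )
    w = rows["weight"].to_numpy(dtype=float)
    w = w / w.sum()
    agg: dict[str, float] = {}
    for m in _MEASURES:
        vals = np.array([getattr(cell_summaries[c], m) for c in cells], dtype=float)
        agg[m] = float(vals @ w)
    sdi_vals = np.array([cell_summaries[c].sdi for c in cells], dtype=float)
    defined = np.isfinite(sdi_vals)
    if defined.any():
        wd = w[defined] / w[defined].sum()
        sdi = float(sdi_vals[defined] @ wd)
    else:
        sdi = SDI_UNDEFINED
    return DroughtWindowSummary(
        unit_id=district_id, window=window, sdi=sdi, **agg
    )


def window_for_interview(
    interview_year: int, interview_month: int, config: PipelineConfig | None = None
) -> tuple[int, int]:
    """Closed month range of ``window_months`` ending the month before the
    interview month."""
    cfg = config or PipelineConfig()
    end = month_index(interview_year, interview_month) - 1
    return end - cfg.window_months + 1, end


def average_series(
    cell_series: dict[str, SpeiSeries],
    weights: pd.DataFrame,
    district_id: str,
) -> SpeiSeries:
    """Coverage-weighted average of the raw SPEI series (average_then_index
    mode). All covering cells must share the same time axis."""
    rows = weights.loc[weights["district_id"] == district_id]
    if rows.empty:
        raise ValueError(f"no weights for district {district_id}")
    cells = rows["cell_id"].tolist()
    series = []
    for cell in cells:
        if cell not in cell_series:
            raise ValueError(f"district {district_id}: missing series for cell {cell}")
        series.append(cell_series[cell])
    starts = {s.start_month for s in series}
    lengths = {len(s) for s in series}
    if len(starts) > 1 or len(lengths) > 1:
        raise ValueError(f"district {district_id}: cells have mismatched time axes")
    w = rows["weight"].to_numpy(dtype=float)
    w = w / w.sum()
    stacked = np.vstack([s.values for s in series])
    return SpeiSeries(
        unit_id=district_id, start_month=series[0].start_month, values=w @ stacked
    )


def district_window_summaries(
    cell_series: dict[str, SpeiSeries],
    weights: pd.DataFrame,
    keys: set[DistrictWindowKey],
    config: PipelineConfig | None = None,
) -> dict[DistrictWindowKey, DroughtWindowSummary]:
    """District-level window summaries for every requested key.

    In ``cell_then_average`` mode (default) measures are computed per cell
    and then weighted-averaged; in ``average_then_index`` mode the SPEI
    series is averaged first and measures are computed on the district
    series. Categorical thresholds are applied downstream in both modes.
    """
    cfg = config or PipelineConfig()
    out: dict[DistrictWindowKey, DroughtWindowSummary] = {}
    for key in sorted(keys, key=lambda k: (k.district_id, k.window_end_month)):
        window = (key.window_end_month - cfg.window_months + 1, key.window_end_month)
        if cfg.aggregation_mode == "average_then_index":
            dseries = average_series(cell_series, weights, key.district_id)
            out[key] = summarize_window(dseries, window, cfg)
        else:
            cells = weights.loc[
                weights["district_id"] == key.district_id, "cell_id"
            ].tolist()
            cell_summaries = {
                c: summarize_window(cell_series[c], window, cfg) for c in cells
            }
            out[key] = aggregate_district(
                cell_summaries, weights, key.district_id, window
            )
    return out


def link_exposure(
    cohort: pd.DataFrame,
    cell_series: dict[str, SpeiSeries],
    weights: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Attach the four exposure flags to each respondent.

    Returns ``(linked, rejects, meta)``. Respondents whose district has no
    weight entry or whose window is not covered by the SPEI series land in
    ``rejects`` with a reason code and are excluded from the linked table.
    ``meta`` carries the thresholds and the exposure-distribution counts
    (exclusive and overlapping category membership).
    """
    cfg = config or PipelineConfig()
    cohort = cohort.copy()
    known = set(weights["district_id"])
    reasons = []
    keys: set[DistrictWindowKey] = set()
    for _, row in cohort.iterrows():
        end = window_for_interview(
            int(row["interview_year"]), int(row["interview_month"]), cfg
        )[1]
        if row["district_id"] not in known:
            reasons.append("unmatched_district")
            continue
        try:
            keys.add(DistrictWindowKey(str(row["district_id"]), end))
        except Exception:  # pragma: no cover
            reasons.append("bad_key")
    ok_keys: dict[DistrictWindowKey, DroughtWindowSummary] = {}
    failed_keys: set[DistrictWindowKey] = set()
    for key in keys:
        try:
            ok_keys.update(
                district_window_summaries(cell_series, weights, {key}, cfg)
            )
        except ValueError:
            failed_keys.add(key)

    thresholds = compute_thresholds(
        list(ok_keys.values()), cfg.extreme_percentile
    )
    profiles = {
        key: assign_categories(s, thresholds, cfg.recent_long_min_run)
        for key, s in ok_keys.items()
    }

    flag_cols = ["slight_to_moderate", "very_dry", "recent_and_long", "prolonged_extreme"]
    linked_rows, reject_rows = [], []
    for _, row in cohort.iterrows():
        window = window_for_interview(
            int(row["interview_year"]), int(row["interview_month"]), cfg
        )
        key = DistrictWindowKey(str(row["district_id"]), window[1])
        if row["district_id"] not in known:
            reject_rows.append({**row, "reject_reason": "unmatched_district"})
            continue
        if key in failed_keys:
            reject_rows.append({**row, "reject_reason": "window_not_covered"})
            continue
        prof = profiles[key]
        rec = dict(row)
        rec.update({c: getattr(prof, c) for c in flag_cols})
        rec["window_start"] = window[0]
        rec["window_end"] = window[1]
        linked_rows.append(rec)
    linked = pd.DataFrame(linked_rows)
    rejects = pd.DataFrame(reject_rows)
    if not rejects.empty:
        warnings.warn(f"{len(rejects)} respondents excluded; see rejects table")

    meta = {
        "thresholds": {
            "sdi_cutoff": None
            if math.isnan(thresholds.sdi_cutoff)
            else thresholds.sdi_cutoff,
            "both_cutoff": thresholds.both_cutoff,
            "n_units_sdi": thresholds.n_units_sdi,
            "n_units_both": thresholds.n_units_both,
        },
        "exposure_distribution": _exposure_distribution(linked, flag_cols),
        "n_linked": int(len(linked)),
        "n_rejected": int(len(rejects)),
    }
    return linked, rejects, meta


def _exposure_distribution(linked: pd.DataFrame, flag_cols: list[str]) -> dict:
    """Counts of exclusive and overlapping category membership."""
    if linked.empty:
        return {"total": {c: 0 for c in flag_cols}, "exclusive": {}, "pattern": {}}
    total = {c: int(linked[c].sum()) for c in flag_cols}
    exclusive = {
        c: int((linked[c] & (linked[flag_cols].sum(axis=1) == 1)).sum())
        for c in flag_cols
    }
    pattern = (
        linked[flag_cols]
        .astype(int)
        .astype(str)
        .agg("".join, axis=1)
        .value_counts()
        .to_dict()
    )
    return {"total": total, "exclusive": exclusive, "pattern": pattern}
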