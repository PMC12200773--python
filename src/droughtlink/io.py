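"""Readers and writers for the pipeline's external formats.

SPEI grids are accepted as long-format CSV (cell_id, year, month, spei) or
as a CF-style NetCDF cube (time x lat x lon); cohort, weight and exposure
tables are CSV; model summaries and diagnostics are JSON.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .config import month_index
from .drought import SpeiSeries

COHORT_REQUIRED = [
    "respondent_id",
    "country_id",
    "district_id",
    "interview_year",
    "interview_month",
    "age",
    "in_school",
    "ever_partnered",
    "poor_household",
    "sv_lifetime",
    "sv_recent_raw",
]

_BOOL_CODES = {"yes": True, "no": False, "1": True, "0": False,
               "true": True, "false": False}
RECENT_CODES = {"yes", "no", "not_applicable", "missing"}


def _series_from_long(group: pd.DataFrame, cell_id: str) -> SpeiSeries:
    idx = group.apply(
        lambda r: month_index(int(r["year"]), int(r["month"])), axis=1
    ).to_numpy()
    order = np.argsort(idx, kind="stable")
    idx, vals = idx[order], group["spei"].to_numpy(dtype=float)[order]
    if np.unique(idx).size != idx.size:
        raise ValueError(f"duplicate (cell, month) rows for cell {cell_id}")
    start, end = int(idx[0]), int(idx[-1])
    full = np.full(end - start + 1, np.nan)
    full[idx - start] = vals  # gaps stay NaN: flagged missing, not dropped
    return SpeiSeries(unit_id=str(cell_id), start_month=start, values=full)


def read_spei_grid(path: str | Path, format: str = "csv_long") -> dict[str, SpeiSeries]:
    """Read a gridded SPEI product into one series per cell.

    ``csv_long`` requires columns cell_id, year, month, spei; months need
    not be contiguous in the file — gaps become explicit missing (NaN)
    months. Duplicate (cell, month) rows and a non-monotone time axis are
    hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv_long":
        df = pd.read_csv(path, dtype={"cell_id": str})
        required = {"cell_id", "year", "month", "spei"}
        if missing := required - set(df.columns):
            raise ValueError(f"SPEI CSV missing columns {sorted(missing)}")
        return {
            str(cid): _series_from_long(g, str(cid))
            for cid, g in df.groupby("cell_id", sort=True)
        }
    if format == "netcdf":
        return _read_spei_netcdf(path)
    raise ValueError(f"unknown SPEI format {format!r}")


def _read_spei_netcdf(path: Path) -> dict[str, SpeiSeries]:
    with xr.open_dataset(path, engine="scipy", decode_times=True) as ds:
        if "spei" not in ds:
            raise ValueError("NetCDF file has no 'spei' variable")
        da = ds["spei"].load()
    times = pd.DatetimeIndex(da["time"].values)
    idx = np.array([month_index(t.year, t.month) for t in times])
    if not (np.diff(idx) > 0).all():
        raise ValueError("non-monotone time axis in NetCDF SPEI file")
    if not (np.diff(idx) == 1).all():
        raise ValueError("non-contiguous monthly time axis in NetCDF SPEI file")
    out: dict[str, SpeiSeries] = {}
    for lat in da["lat"].values:
        for lon in da["lon"].values:
            cell = f"{float(lat):g}_{float(lon):g}"
            vals = da.sel(lat=lat, lon=lon).values.astype(float)
            out[cell] = SpeiSeries(unit_id=cell, start_month=int(idx[0]), values=vals)
    return out


def write_spei_csv(series: dict[str, SpeiSeries], path: str | Path) -> None:
    rows = []
    for cell, s in sorted(series.items()):
        for i, v in enumerate(s.values):
            m = s.start_month + i
            rows.append(
                {"cell_id": cell, "year": m // 12, "month": m % 12 + 1, "spei": v}
            )
    pd.DataFrame(rows).dropna(subset=["spei"]).to_csv(path, index=False)


def write_spei_netcdf(series: dict[str, SpeiSeries], path: str | Path) -> None:
    """Write cell series as a CF-style cube; cells become synthetic lat/lon
    positions along a half-degree grid. All series must share one time axis."""
    cells = sorted(series)
    starts = {series[c].start_month for c in cells}
    lengths = {len(series[c]) for c in cells}
    if len(starts) > 1 or len(lengths) > 1:
        raise ValueError("all series must share one time axis for NetCDF export")
    start = starts.pop()
    n = lengths.pop()
    time = pd.to_datetime(
        [f"{(start + i) // 12:04d}-{(start + i) % 12 + 1:02d}-01" for i in range(n)]
    )
    lats = np.arange(len(cells)) * 0.5
    data = np.stack([series[c].values for c in cells], axis=1)[:, :, None]
    ds = xr.Dataset(
        {"spei": (("time", "lat", "lon"), data)},
        coords={"time": time, "lat": lats, "lon": [0.0]},
    )
    ds.to_netcdf(path, engine="scipy")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read respondent records, preserving the skip-pattern encoding.

    ``sv_recent_raw`` keeps its four-level coding (yes / no / not_applicable
    / missing); ``not_applicable`` is the survey skip for respondents who
    reported no lifetime violence. Unknown category codes raise an error
    naming the offending rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path, dtype={"district_id": str, "country_id": str, "respondent_id": str}
    )
    if missing := set(COHORT_REQUIRED) - set(df.columns):
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")

    bad_age = pd.to_numeric(df["age"], errors="coerce").isna()
    if bad_age.any():
        raise ValueError(
            f"non-numeric age in rows {df.index[bad_age].tolist()[:10]}"
        )
    df["age"] = pd.to_numeric(df["age"])

    for col in ("in_school", "ever_partnered", "poor_household", "sv_lifetime"):
        codes = df[col].astype(str).str.strip().str.lower()
        bad = ~codes.isin(_BOOL_CODES)
        if bad.any():
            raise ValueError(
                f"unknown codes in column {col!r}, rows "
                f"{df.index[bad].tolist()[:10]}: "
                f"{sorted(codes[bad].unique())[:5]}"
            )
        df[col] = codes.map(_BOOL_CODES)

    raw = df["sv_recent_raw"].astype(str).str.strip().str.lower()
    bad = ~raw.isin(RECENT_CODES)
    if bad.any():
        raise ValueError(
            f"unknown sv_recent_raw codes in rows {df.index[bad].tolist()[:10]}: "
            f"{sorted(raw[bad].unique())[:5]}"
        )
    df["sv_recent_raw"] = raw
    if "weight" in df.columns:
        df["weight"] = pd.to_numeric(df["weight"])
        if (df["weight"] <= 0).any():
            raise ValueError("non-positive survey weights")
    return df
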