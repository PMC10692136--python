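"""Standardisation of raw long-format plankton monitoring records.

The pipeline mirrors common practice for heterogeneous long-term monitoring
data: unnamed/unidentified taxa are removed; a taxon absent from a sampling
date (but recorded on others) is assigned an explicit zero density (constant
search effort implies below-detection rather than not-sampled); densities are
averaged to monthly and yearly means; species are pooled to genus after
averaging; and a genus is dropped if it disappears for strictly longer than
12 consecutive months.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "standardise_records",
    "aggregate_resolution",
    "filter_genera",
    "assemble_lake_dataset",
    "read_long_csv",
    "read_driver_csv",
    "LakeDataset",
]

REQUIRED_COLUMNS = ("lake", "date", "taxon", "trophic_level", "density")

_UNNAMED_PATTERN = re.compile(r"\b(?:unidentified|unknown|unnamed)\b", re.IGNORECASE)


class ValidationError(ValueError):
    """Raised for records violating the input contract."""


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format plankton CSV (lake, date, trophic_level, genus, density)."""
    df = pd.read_csv(path, parse_dates=["date"])
    if "taxon" not in df.columns and "genus" in df.columns:
        df = df.assign(taxon=df["genus"])
    return df


def read_driver_csv(path) -> pd.DataFrame:
    """Read a driver CSV (lake, date, temperature, nitrate, phosphorus)."""
    return pd.read_csv(path, parse_dates=["date"])


def standardise_records(records: pd.DataFrame) -> pd.DataFrame:
    """Remove unnamed taxa and zero-fill missing (date, taxon) combinations.

    For every lake, the set of sampling dates is the union of dates with any
    record; each retained taxon then gets one record per sampling date, with
    density 0 where none was observed.  Idempotent.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = records.copy()
    if df.empty:
        return df
    neg = df[df["density"] < 0]
    if len(neg):
        raise ValidationError(
            f"negative densities in {len(neg)} rows (first offending rows:\n"
            f"{neg.head().to_string()})"
        )
    named = ~df["taxon"].astype(str).str.match(r"^\s*$") & ~df["taxon"].astype(
        str
    ).str.contains(_UNNAMED_PATTERN)
    df = df[named]

    out = []
    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != "genus"]
    for lake, sub in df.groupby("lake", sort=True):
        dates = np.sort(sub["date"].unique())
        taxa = sub[["taxon", "trophic_level"]].drop_duplicates()
        if "genus" in sub.columns:
            taxa = sub[["taxon", "trophic_level", "genus"]].drop_duplicates()
        full = taxa.merge(pd.DataFrame({"date": dates}), how="cross")
        full["lake"] = lake
        keys = ["date", "taxon", "trophic_level"]
        merged = full.merge(sub.drop(columns=extra_cols), on=["lake"] + keys + (
            ["genus"] if "genus" in sub.columns else []
        ), how="left")
        merged["density"] = merged["density"].fillna(0.0)
        out.append(merged)
    result = pd.concat(out, ignore_index=True)
    # deduplicate repeated records of the same taxon/date (mean density)
    group_cols = [c for c in result.columns if c != "density"]
    result = result.groupby(group_cols, as_index=False, sort=True, dropna=False)[
        "density"
    ].mean()
    lead = [c for c in ("lake", "date", "taxon", "trophic_level", "genus") if c in result]
    rest = [c for c in result.columns if c not in lead]
    return result[lead + rest]


def _period_key(dates: pd.Series, resolution: str):
    if resolution == "monthly":
        return dates.dt.to_period("M")
    if resolution == "yearly":
        return dates.dt.year
    raise ValueError(f"unknown resolution {resolution!r}")


def aggregate_resolution(
    records: pd.DataFrame, resolution: str
) -> dict[tuple[str, str], pd.DataFrame]:
    """Aggregate standardised records into community matrices.

    Within each period (calendar month or year) a taxon's densities are
    averaged arithmetically; species are then summed into their genus.
    Returns ``{(lake, trophic_level): matrix}`` where each matrix has a
    contiguous period index (periods with no sampling are explicit NaN rows)
    and genus columns.
    """
    df = records.copy()
    if "genus" not in df.columns:
        df["genus"] = df["taxon"]
    df["period"] = _period_key(df["date"], resolution)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for (lake, level), sub in df.groupby(["lake", "trophic_level"], sort=True):
        # average species within period first, then pool to genus
        species_mean = sub.groupby(["period", "taxon", "genus"], sort=True)[
            "density"
        ].mean()
        genus = species_mean.groupby(["period", "genus"]).sum().unstack("genus")
        if resolution == "monthly":
            full_idx = pd.period_range(genus.index.min(), genus.index.max(), freq="M")
        else:
            full_idx = pd.RangeIndex(genus.index.min(), genus.index.max() + 1)
        genus = genus.reindex(full_idx)
        genus.index.name = "period"
        out[(lake, level)] = genus
    return out


def _longest_zero_run(col: pd.Series) -> int:
    """Longest run of consecutive zero months (NaN breaks a run)."""
    is_zero = (col == 0).to_numpy()
    best = run = 0
    for z in is_zero:
        run = run + 1 if z else 0
        best = max(best, run)
    return best


def filter_genera(
    monthly: pd.DataFrame, max_gap_months: int = 12
) -> pd.DataFrame:
    """Drop genus columns that disappear for strictly longer than 12 months.

    The rule is defined on the monthly matrix: a column with any all-zero run
    of ``max_gap_months + 1`` or more consecutive months is removed.  A run of
    exactly ``max_gap_months`` is retained.
    """
    keep = [
        c for c in monthly.columns if _longest_zero_run(monthly[c]) <= max_gap_months
    ]
    return monthly[keep]


@dataclass
class LakeDataset:
    """Paired community and driver tables for one lake × trophic level × resolution."""

    lake: str
    trophic_level: str
    resolution: str
    community: pd.DataFrame  # genus columns
    drivers: pd.DataFrame  # temperature/nitrate/phosphorus
    total_density: pd.Series  # sum over genus columns


def assemble_lake_dataset(
    community: pd.DataFrame,
    drivers: pd.DataFrame,
    lake: str = "",
    trophic_level: str = "",
    resolution: str = "yearly",
) -> LakeDataset:
    """Inner-join a community matrix with its driver table on the time index.

    Both tables must share resolution (index dtype); an empty overlap is an
    error naming the two spans.  The total-density series (sum over genus
    columns, NaN where all genera are missing) is attached for classification.
    """
    joined_idx = community.index.intersection(drivers.index)
    if len(joined_idx) == 0:
        raise ValueError(
            "no temporal overlap between community "
            f"[{community.index.min()}..{community.index.max()}] and drivers "
            f"[{drivers.index.min()}..{drivers.index.max()}] "
            "(resolution mismatch or disjoint spans)"
        )
    comm = community.loc[joined_idx]
    drv = drivers.loc[joined_idx]
    total = comm.sum(axis=1, min_count=1)
    total.name = "total_density"
    return LakeDataset(
        lake=lake,
        trophic_level=trophic_level,
        resolution=resolution,
        community=comm,
        drivers=drv,
        total_density=total,
    )
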