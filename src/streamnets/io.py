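"""Schema-validated CSV input/output for every pipeline table.

All tables are RFC-4180 CSV with a header row, UTF-8, ISO-8601 dates.
Readers raise :class:`~streamnets.errors.InputError` naming the offending
column (and row, where applicable); writers emit columns in a canonical
order so that runs are byte-reproducible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import OGD_GROUPS
from .errors import InputError

log = logging.getLogger("streamnets")

_SEASONS = {"spring", "fall"}
_STREAM_TYPES = {"wadeable", "semiwadeable"}
_DEV_TYPES = {"conventional", "unconventional"}
_STATUSES = {"active", "inactive"}


def _require_columns(df: pd.DataFrame, columns, table: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InputError(f"{table} table is missing column(s): {missing}")


def _require_unique(df: pd.DataFrame, column: str, table: str) -> None:
    dup = df[column][df[column].duplicated()]
    if len(dup):
        raise InputError(f"{table} table has duplicate {column}: {dup.iloc[0]!r}")


def _parse_dates(df: pd.DataFrame, column: str, table: str) -> None:
    try:
        df[column] = pd.to_datetime(df[column], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise InputError(f"{table} table column {column!r}: non-parsable date ({exc})") from exc


def _check_enum(df: pd.DataFrame, column: str, allowed, table: str) -> None:
    bad = ~df[column].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise InputError(
            f"{table} table row {row}: {column}={df[column].iloc[row]!r} not in {sorted(allowed)}"
        )


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["sample_id", "huc8", "ecoregion", "amd_present", "dlc", "season",
         "stream_type", "sample_date", "catchment_area_km2"],
        "samples",
    )
    _require_unique(df, "sample_id", "samples")
    _parse_dates(df, "sample_date", "samples")
    _check_enum(df, "season", _SEASONS, "samples")
    _check_enum(df, "stream_type", _STREAM_TYPES, "samples")
    df["amd_present"] = df["amd_present"].astype(bool)
    if ((df["dlc"] < 0) | (df["dlc"] > 1)).any():
        raise InputError("samples table column 'dlc': values must lie in [0, 1]")
    if (df["catchment_area_km2"] <= 0).any():
        raise InputError("samples table column 'catchment_area_km2': values must be positive")
    log.info("read %d samples from %s", len(df), path)
    return df


def read_taxa(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["taxon_id", "order", "ffg", "tolerance"], "taxa")
    _require_unique(df, "taxon_id", "taxa")
    if ((df["tolerance"] < 0) | (df["tolerance"] > 10)).any():
        raise InputError("taxa table column 'tolerance': values must lie in [0, 10]")
    log.info("read %d taxa from %s", len(df), path)
    return df


def read_counts(path, taxa: pd.DataFrame | None = None, samples: pd.DataFrame | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "taxon_id", "count"], "counts")
    if (df["count"] < 0).any():
        row = int(np.flatnonzero((df["count"] < 0).to_numpy())[0])
        raise InputError(f"counts table row {row}: negative count")
    if taxa is not None:
        unknown = ~df["taxon_id"].isin(taxa["taxon_id"])
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise InputError(
                f"counts table row {row}: unknown taxon_id {df['taxon_id'].iloc[row]!r}"
            )
    if samples is not None:
        unknown = ~df["sample_id"].isin(samples["sample_id"])
        if unknown.any():
            row = int(np.flatnonzero(unknown.to_numpy())[0])
            raise InputError(
                f"counts table row {row}: unknown sample_id {df['sample_id'].iloc[row]!r}"
            )
    log.info("read %d count records from %s", len(df), path)
    return df


def read_wells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["well_id", "x", "y", "dev_type", "spud_date", "status"], "wells")
    _require_unique(df, "well_id", "wells")
    _parse_dates(df, "spud_date", "wells")
    _check_enum(df, "dev_type", _DEV_TYPES, "wells")
    _check_enum(df, "status", _STATUSES, "wells")
    log.info("read %d wells from %s", len(df), path)
    return df


def read_catchments(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "wkt"], "catchments")
    _require_unique(df, "sample_id", "catchments")
    return df


def read_membership(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["well_id", "sample_id"], "membership")
    return df


def read_attribution(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["sample_id", "cogd_density", "uogd_density", "cogd_present",
         "uogd_present", "n_cog_wells", "n_uog_wells"],
        "attribution",
    )
    _require_unique(df, "sample_id", "attribution")
    df["cogd_present"] = df["cogd_present"].astype(bool)
    df["uogd_present"] = df["uogd_present"].astype(bool)
    return df


def read_metrics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "richness", "shannon", "ept_richness", "ibi"], "metrics")
    _require_unique(df, "sample_id", "metrics")
    return df


def read_ensemble(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["huc8", "ogd_group", "rep", "size", "connectance", "modularity", "mean_strength"],
        "ensemble",
    )
    _check_enum(df, "ogd_group", set(OGD_GROUPS), "ensemble")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Canonical CSV writer: ISO dates, no index, '%.10g' floats."""
    out = df.copy()
    for column in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[column]):
            out[column] = out[column].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.10g")
    log.info("wrote %d rows to %s", len(out), path)
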