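"""Well-to-catchment attribution and development-density computation.

Wells are attributed to every catchment polygon containing them (catchments
may nest); a point on a polygon boundary counts as inside. Only wells that
are active and were spudded strictly before a sample's collection date count
toward that sample's densities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely import wkt as shapely_wkt

from .errors import InputError

ATTRIBUTION_COLUMNS = [
    "sample_id",
    "cogd_density",
    "uogd_density",
    "cogd_present",
    "uogd_present",
    "n_cog_wells",
    "n_uog_wells",
]


def assign_wells(
    wells: pd.DataFrame,
    catchments: pd.DataFrame | None = None,
    membership: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Map each well to the catchments containing it.

    Either ``catchments`` (columns ``sample_id, wkt``, simple polygons) or a
    precomputed ``membership`` table (columns ``well_id, sample_id``) must be
    supplied; membership takes precedence when both are given.

    Returns a (well_id, sample_id) assignment table. Boundary points count
    as inside. Self-intersecting polygons are rejected.
    """
    if membership is not None:
        missing = set(membership["well_id"]) - set(wells["well_id"])
        if missing:
            raise InputError(f"membership references unknown well_id(s): {sorted(missing)[:5]}")
        return membership.loc[:, ["well_id", "sample_id"]].reset_index(drop=True)
    if catchments is None:
        raise InputError("either a catchment polygon table or a membership table is required")

    polygons = []
    for row in catchments.itertuples(index=False):
        poly = shapely_wkt.loads(row.wkt)
        if not poly.is_valid:
            raise InputError(f"catchment polygon for sample {row.sample_id!r} is not a simple polygon")
        polygons.append((row.sample_id, poly))

    points = shapely.points(wells["x"].to_numpy(float), wells["y"].to_numpy(float))
    well_ids = wells["well_id"].to_numpy()
    frames = []
    for sample_id, poly in polygons:
        # covers(), unlike contains(), includes the boundary
        inside = shapely.covers(poly, points)
        if inside.any():
            frames.append(
                pd.DataFrame({"well_id": well_ids[inside], "sample_id": sample_id})
            )
    if not frames:
        return pd.DataFrame(columns=["well_id", "sample_id"])
    return pd.concat(frames, ignore_index=True)


def well_density(samples: pd.DataFrame, wells: pd.DataFrame, assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-sample development densities and presence flags.

    Counts active wells spudded strictly before each sample's date, split by
    development type; density = count / catchment area. One output row per
    sample, including samples with no assigned wells.
    """
    if (samples["catchment_area_km2"] <= 0).any():
        bad = samples.loc[samples["catchment_area_km2"] <= 0, "sample_id"].iloc[0]
        raise InputError(f"sample {bad!r} has non-positive catchment area")

    merged = assignment.merge(wells, on="well_id", how="left").merge(
        samples[["sample_id", "sample_date"]], on="sample_id", how="inner"
    )
    eligible = merged[
        (merged["status"] == "active")
        & (pd.to_datetime(merged["spud_date"]) < pd.to_datetime(merged["sample_date"]))
    ]
    counts = (
        eligible.groupby(["sample_id", "dev_type"]).size().unstack(fill_value=0)
        if len(eligible)
        else pd.DataFrame()
    )
    out = samples[["sample_id", "catchment_area_km2"]].copy()
    for dev_type, col in (("conventional", "n_cog_wells"), ("unconventional", "n_uog_wells")):
        if dev_type in counts.columns:
            out[col] = out["sample_id"].map(counts[dev_type]).fillna(0).astype(int)
        else:
            out[col] = 0
    out["cogd_density"] = out["n_cog_wells"] / out["catchment_area_km2"]
    out["uogd_density"] = out["n_uog_wells"] / out["catchment_area_km2"]
    out["cogd_present"] = out["n_cog_wells"] >= 1
    out["uogd_present"] = out["n_uog_wells"] >= 1
    return out[ATTRIBUTION_COLUMNS].reset_index(drop=True)


def brute_force_assign(wells: pd.DataFrame, rectangles: pd.DataFrame) -> pd.DataFrame:
    """Independent containment oracle for axis-aligned rectangles.

    ``rectangles`` has columns ``sample_id, minx, miny, maxx, maxy``.
    Closed-interval comparisons implement the boundary-inside convention.
    """
    pairs = []
    for well in wells.itertuples(index=False):
        for rect in rectangles.itertuples(index=False):
            if rect.minx <= well.x <= rect.maxx and rect.miny <= well.y <= rect.maxy:
                pairs.append({"well_id": well.well_id, "sample_id": rect.sample_id})
    return pd.DataFrame(pairs, columns=["well_id", "sample_id"])
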