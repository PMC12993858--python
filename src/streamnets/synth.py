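"""Synthetic data generator with planted stress effects and co-occurrence blocks.

Produces three linked tables — taxon traits, collection-event samples with
per-taxon counts, and well records with catchment geometry — in which the
"truth" (per-stressor log-abundance slopes, latent block memberships, planted
well densities) is known, so every downstream stage can be validated without
external data.

Abundances follow a log-linear multinomial model: the expected log-abundance
of taxon ``t`` at sample ``i`` is

    a_t + g(tol_t) * (b_cogd*z_cogd_i + b_uogd*z_uogd_i + b_dlc*z_dlc_i)
        + block_strength * u[i, block(t)]

where ``g(tol) = (5 - tol) / 5`` grades the response by pollution tolerance
(negative planted slopes depress sensitive taxa and boost tolerant ones),
the stressors are sd-scaled but not centered — zero development means zero
stress, so the planted response is monotone in density — and ``u`` are
shared standard-normal latent site factors, one per block, which induce
positive within-block co-occurrence. Totals are drawn uniformly in
``target_total ± tolerance_halfwidth`` and allocated multinomially, so
per-sample totals are exactly controlled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FFGS, OGD_GROUPS, ORDERS, SimulationConfig
from .errors import ConfigurationError, InputError

# substream tags so the one global seed yields independent streams per stage
_STREAM_TAXA = 101
_STREAM_SAMPLES = 202
_STREAM_WELLS = 303

_ALL_FFGS = FFGS + ("unknown", "piercer")
_FFG_PROBS = np.array([0.30, 0.15, 0.18, 0.15, 0.12, 0.06, 0.04])
_ORDER_PROBS = np.array([0.20, 0.13, 0.15, 0.52])


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_taxa(config: SimulationConfig) -> pd.DataFrame:
    """Draw the taxon trait table.

    Returns a frame with columns ``taxon_id, order, ffg, tolerance, block``.
    The first five taxa are pinned to one analyzed FFG each so every group is
    represented; blocks cycle so that exactly ``n_blocks`` labels occur.
    """
    if config.n_taxa < 10:
        raise ConfigurationError(
            f"n_taxa={config.n_taxa} too small to cover the functional feeding groups (need >= 10)"
        )
    rng = _rng(config, _STREAM_TAXA)
    n = config.n_taxa
    order = rng.choice(ORDERS, size=n, p=_ORDER_PROBS)
    ffg = rng.choice(_ALL_FFGS, size=n, p=_FFG_PROBS)
    ffg[: len(FFGS)] = FFGS  # guarantee coverage of the five analyzed groups
    tolerance = rng.uniform(0.0, 10.0, size=n).round(1)
    block = rng.permutation(np.arange(n) % config.n_blocks)
    return pd.DataFrame(
        {
            "taxon_id": [f"T{i + 1:04d}" for i in range(n)],
            "order": order,
            "ffg": ffg,
            "tolerance": tolerance,
            "block": block,
        }
    )


def tolerance_response(tolerance: np.ndarray) -> np.ndarray:
    """Response grade g(tol) = max(0, (5 - tol)/5): 1 at tolerance 0,
    fading linearly to 0 at 5 and above.

    Only sensitive taxa respond in absolute abundance ("sensitive decline,
    tolerant persist"); the relative abundance of tolerant taxa then rises
    mechanically through the fixed-total multinomial renormalization.
    """
    return np.clip((5.0 - np.asarray(tolerance, dtype=float)) / 5.0, 0.0, None)


def _scale_or_zero(x: np.ndarray) -> np.ndarray:
    """Divide by the sample sd without centering (zero keeps meaning
    "no stress"); zero-variance input maps to all-zero stress."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0.0:
        return np.zeros_like(x)
    return x / sd


def _draw_dates(rng, n, season):
    """ISO dates in the spring (Apr–Jun) or fall (Sep–Oct) window."""
    years = rng.integers(2012, 2022, size=n)
    offsets = rng.integers(0, 75, size=n)
    starts = np.where(season == "spring", "-04-01", "-09-01")
    base = pd.to_datetime([f"{y}{s}" for y, s in zip(years, starts)])
    return base + pd.to_timedelta(offsets, unit="D")


def generate_samples(
    config: SimulationConfig, taxa: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Draw samples and per-taxon counts with the planted effect structure.

    Returns ``(samples, counts, truth)`` where ``counts`` is long-format
    (sample_id, taxon_id, count; zero counts omitted) and ``truth`` holds
    the latent-truth tables (``samples``: planted densities and composite
    stress; ``taxa``: baseline log-abundance, response grade, block).

    The ``planted_n_cogd_wells`` / ``planted_n_uogd_wells`` columns of the
    samples table are latent truth consumed by :func:`generate_wells`;
    densities are defined as count/area so the attribution stage recovers
    them exactly.
    """
    if taxa is None or len(taxa) == 0:
        raise InputError("taxa table is empty")
    strata = config.stratum_map()
    if not strata:
        raise ConfigurationError("stratum map is empty")
    rng = _rng(config, _STREAM_SAMPLES)

    rows = []
    for (huc8, group) in sorted(strata, key=lambda k: (k[0], OGD_GROUPS.index(k[1]))):
        n = strata[(huc8, group)]
        season = np.where(rng.random(n) < config.p_fall, "fall", "spring")
        stream_type = np.where(
            rng.random(n) < config.p_semiwadeable, "semiwadeable", "wadeable"
        )
        amd = rng.random(n) < config.p_amd
        dlc = rng.uniform(0.0, config.dlc_max, size=n)
        area = np.exp(rng.normal(0.8, 0.4, size=n))
        dates = _draw_dates(rng, n, season)

        def planted_counts(present):
            if not present:
                return np.zeros(n, dtype=int)
            target = rng.uniform(0.3, 2.0, size=n)
            return np.maximum(1, np.rint(target * area).astype(int))

        n_cogd = planted_counts(group in ("cogd_only", "both"))
        n_uogd = planted_counts(group in ("uogd_only", "both"))
        for j in range(n):
            rows.append(
                {
                    "huc8": huc8,
                    "ogd_group": group,
                    "ecoregion": f"ECO{rng.integers(1, config.n_ecoregions + 1)}",
                    "amd_present": bool(amd[j]),
                    "dlc": float(dlc[j]),
                    "season": season[j],
                    "stream_type": stream_type[j],
                    "sample_date": dates[j],
                    "catchment_area_km2": float(area[j]),
                    "planted_n_cogd_wells": int(n_cogd[j]),
                    "planted_n_uogd_wells": int(n_uogd[j]),
                }
            )
    samples = pd.DataFrame(rows)
    samples.insert(0, "sample_id", [f"S{i + 1:06d}" for i in range(len(samples))])

    cogd_density = samples["planted_n_cogd_wells"] / samples["catchment_area_km2"]
    uogd_density = samples["planted_n_uogd_wells"] / samples["catchment_area_km2"]
    z = {
        "cogd": _scale_or_zero(cogd_density.to_numpy()),
        "uogd": _scale_or_zero(uogd_density.to_numpy()),
        "dlc": _scale_or_zero(samples["dlc"].to_numpy()),
    }
    stress = sum(config.effect_sizes[k] * z[k] for k in ("cogd", "uogd", "dlc"))

    n_samples, n_taxa = len(samples), len(taxa)
    base = rng.normal(0.0, 1.0, size=n_taxa)
    grade = tolerance_response(taxa["tolerance"].to_numpy())
    blocks = taxa["block"].to_numpy()
    site_factors = rng.normal(0.0, 1.0, size=(n_samples, config.n_blocks))

    eta = (
        base[None, :]
        + stress[:, None] * grade[None, :]
        + config.block_strength * site_factors[:, blocks]
    )
    eta -= eta.max(axis=1, keepdims=True)  # softmax stability
    probs = np.exp(eta)
    # extirpation: a net-negative planted response also removes the taxon
    # outright with probability 1 - exp(suppression), so richness declines
    # monotonically with stress instead of merely re-shuffling shares
    suppression = np.minimum(0.0, stress)[:, None] * grade[None, :]
    extirpated = rng.random(size=(n_samples, n_taxa)) > np.exp(suppression)
    probs[extirpated] = 0.0
    probs /= probs.sum(axis=1, keepdims=True)

    lo = config.target_total - config.tolerance_halfwidth
    hi = config.target_total + config.tolerance_halfwidth
    totals = rng.integers(lo, hi + 1, size=n_samples)
    counts_matrix = np.vstack(
        [rng.multinomial(totals[i], probs[i]) for i in range(n_samples)]
    )

    sample_idx, taxon_idx = np.nonzero(counts_matrix)
    counts = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy()[sample_idx],
            "taxon_id": taxa["taxon_id"].to_numpy()[taxon_idx],
            "count": counts_matrix[sample_idx, taxon_idx],
        }
    )

    truth_samples = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "ogd_group": samples["ogd_group"],
            "cogd_density": cogd_density,
            "uogd_density": uogd_density,
            "composite_stress": stress,
        }
    )
    truth_taxa = pd.DataFrame(
        {
            "taxon_id": taxa["taxon_id"],
            "block": blocks,
            "base_log_abundance": base,
            "tolerance_response": grade,
            "slope_cogd": config.effect_sizes["cogd"] * grade,
            "slope_uogd": config.effect_sizes["uogd"] * grade,
            "slope_dlc": config.effect_sizes["dlc"] * grade,
        }
    )
    samples = samples.drop(columns=["ogd_group"])
    return samples, counts, {"samples": truth_samples, "taxa": truth_taxa}


def generate_wells(
    samples: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Emit well records, square catchment polygons, and catchment membership.

    Each sample gets a disjoint square catchment of its recorded area; the
    planted numbers of active, pre-sampling-date wells of each development
    type are placed uniformly inside it. Decoy wells — active wells spudded
    after the sample date and inactive wells spudded before — are added to
    exercise the attribution filters, and never alter planted densities.

    Returns ``(wells, catchments, membership)``; ``catchments`` carries WKT
    polygons, ``membership`` the (well_id, sample_id) containment pairs.
    """
    if samples is None or len(samples) == 0:
        raise InputError("samples table is empty")
    rng = _rng(config, _STREAM_WELLS)
    sides = np.sqrt(samples["catchment_area_km2"].to_numpy())
    spacing = float(sides.max()) + 1.0

    wells_rows, catch_rows, member_rows = [], [], []
    wid = 0

    def add_well(x, y, dev_type, spud, status):
        nonlocal wid
        wid += 1
        wells_rows.append(
            {
                "well_id": f"W{wid:06d}",
                "x": float(x),
                "y": float(y),
                "dev_type": dev_type,
                "spud_date": spud,
                "status": status,
            }
        )
        return f"W{wid:06d}"

    for idx, row in enumerate(samples.itertuples(index=False)):
        side = sides[idx]
        x0, y0 = idx * spacing, 0.0
        wkt = (
            f"POLYGON (({x0} {y0}, {x0 + side} {y0}, "
            f"{x0 + side} {y0 + side}, {x0} {y0 + side}, {x0} {y0}))"
        )
        catch_rows.append({"sample_id": row.sample_id, "wkt": wkt})
        date = pd.Timestamp(row.sample_date)

        planted = [("conventional", row.planted_n_cogd_wells),
                   ("unconventional", row.planted_n_uogd_wells)]
        for dev_type, n in planted:
            for _ in range(int(n)):
                spud = date - pd.Timedelta(days=int(rng.integers(30, 3000)))
                w = add_well(
                    x0 + rng.uniform(0, side), y0 + rng.uniform(0, side),
                    dev_type, spud, "active",
                )
                member_rows.append({"well_id": w, "sample_id": row.sample_id})
        # decoys: must never count toward any sample's attribution
        if rng.random() < 0.5:
            spud = date + pd.Timedelta(days=int(rng.integers(1, 730)))
            w = add_well(
                x0 + rng.uniform(0, side), y0 + rng.uniform(0, side),
                rng.choice(["conventional", "unconventional"]), spud, "active",
            )
            member_rows.append({"well_id": w, "sample_id": row.sample_id})
        if rng.random() < 0.5:
            spud = date - pd.Timedelta(days=int(rng.integers(30, 3000)))
            w = add_well(
                x0 + rng.uniform(0, side), y0 + rng.uniform(0, side),
                rng.choice(["conventional", "unconventional"]), spud, "inactive",
            )
            member_rows.append({"well_id": w, "sample_id": row.sample_id})

    wells = pd.DataFrame(
        wells_rows, columns=["well_id", "x", "y", "dev_type", "spud_date", "status"]
    )
    catchments = pd.DataFrame(catch_rows, columns=["sample_id", "wkt"])
    membership = pd.DataFrame(member_rows, columns=["well_id", "sample_id"])
    return wells, catchments, membership
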