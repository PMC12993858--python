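"""Per-sample taxonomic and functional bioassessment metrics.

Includes richness, Shannon diversity (natural log), sensitive-EPT richness
(Ephemeroptera/Plecoptera/Trichoptera with pollution tolerance 0-4),
functional-feeding-group proportions (unknown/piercer individuals excluded),
mean pollution tolerance, and a surrogate composite condition index on
[0, 100] built by rescaling component metrics between calibrated floors and
ceilings.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_IBI_CALIBRATION, EXCLUDED_FFGS, FFGS
from .errors import ConfigurationError, InputError, UndefinedMetricError

EPT_ORDERS = frozenset({"Ephemeroptera", "Plecoptera", "Trichoptera"})
SENSITIVE_TOLERANCE_MAX = 4.0  # "0-4" boundary is inclusive


def richness(counts) -> int:
    """Number of taxa with count > 0."""
    counts = np.asarray(list(counts.values()) if isinstance(counts, Mapping) else counts)
    return int((counts > 0).sum())


def shannon(counts) -> float:
    """Shannon diversity H = -sum p*ln(p) over taxa with p > 0 (nats)."""
    counts = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts, dtype=float
    )
    total = counts.sum()
    if total <= 0:
        raise UndefinedMetricError("Shannon diversity is undefined for an empty sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def _trait_lookup(counts: Mapping[str, int], traits: pd.DataFrame, column: str) -> pd.Series:
    lookup = traits.set_index("taxon_id")[column]
    missing = [t for t in counts if t not in lookup.index]
    if missing:
        raise InputError(f"no trait row for taxon_id(s): {missing[:5]}")
    return lookup


def ept_richness(counts: Mapping[str, int], traits: pd.DataFrame) -> int:
    """Richness of present sensitive E/P/T taxa (tolerance <= 4, inclusive)."""
    orders = _trait_lookup(counts, traits, "order")
    tol = traits.set_index("taxon_id")["tolerance"]
    return sum(
        1
        for taxon, n in counts.items()
        if n > 0 and orders[taxon] in EPT_ORDERS and tol[taxon] <= SENSITIVE_TOLERANCE_MAX
    )


def ffg_proportions(counts: Mapping[str, int], traits: pd.DataFrame) -> dict[str, float]:
    """Individual-based proportions over the five analyzed FFGs.

    Individuals of unknown/piercer taxa are removed from both numerator and
    denominator. Raises when no classified individuals remain.
    """
    ffg = _trait_lookup(counts, traits, "ffg")
    totals = {g: 0.0 for g in FFGS}
    classified = 0.0
    for taxon, n in counts.items():
        if n <= 0:
            continue
        group = ffg[taxon]
        if group in EXCLUDED_FFGS:
            continue
        totals[group] += n
        classified += n
    if classified == 0:
        raise UndefinedMetricError("no individuals with an analyzed FFG classification")
    return {g: totals[g] / classified for g in FFGS}


def mean_tolerance(
    counts: Mapping[str, int], traits: pd.DataFrame, weighting: str = "unweighted"
) -> float:
    """Mean pollution tolerance over present taxa.

    ``weighting`` is "unweighted" (default: each present taxon counts once)
    or "abundance" (individual-weighted).
    """
    if weighting not in ("unweighted", "abundance"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")
    tol = _trait_lookup(counts, traits, "tolerance")
    present = {t: n for t, n in counts.items() if n > 0}
    if not present:
        raise UndefinedMetricError("mean tolerance is undefined for an empty sample")
    if weighting == "unweighted":
        return float(np.mean([tol[t] for t in present]))
    weights = np.array(list(present.values()), dtype=float)
    values = np.array([tol[t] for t in present], dtype=float)
    return float((weights * values).sum() / weights.sum())


def surrogate_ibi(
    components: Mapping[str, float],
    calibration: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Composite condition score on [0, 100].

    Each component — richness, ept_richness, shannon, and
    ``tolerance_complement`` (10 − mean tolerance) — is rescaled to [0, 100]
    by clamped linear interpolation between its calibrated floor and
    ceiling; the index is the arithmetic mean of the component scores.
    """
    calibration = calibration if calibration is not None else DEFAULT_IBI_CALIBRATION
    scores = []
    for name, value in components.items():
        if name not in calibration:
            raise ConfigurationError(f"calibration does not cover component {name!r}")
        floor, ceiling = calibration[name]
        if floor == ceiling:
            raise ConfigurationError(f"calibration floor equals ceiling for {name!r}")
        scores.append(100.0 * min(1.0, max(0.0, (value - floor) / (ceiling - floor))))
    if not scores:
        raise ConfigurationError("no components supplied")
    return float(np.mean(scores))


def sample_metrics(
    samples: pd.DataFrame,
    counts: pd.DataFrame,
    traits: pd.DataFrame,
    calibration: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Metric table with one row per sample.

    ``counts`` is long-format (sample_id, taxon_id, count). FFG proportions
    are NaN for samples without classified individuals.
    """
    grouped = {
        sid: dict(zip(g["taxon_id"], g["count"]))
        for sid, g in counts.groupby("sample_id")
    }
    rows = []
    for sid in samples["sample_id"]:
        c = grouped.get(sid, {})
        row = {"sample_id": sid}
        if not c:
            rows.append(row)
            continue
        row["richness"] = richness(c)
        row["shannon"] = shannon(c)
        row["ept_richness"] = ept_richness(c, traits)
        row["mean_tolerance"] = mean_tolerance(c, traits)
        try:
            row.update({f"prop_{g}": v for g, v in ffg_proportions(c, traits).items()})
        except UndefinedMetricError:
            row.update({f"prop_{g}": np.nan for g in FFGS})
        row["ibi"] = surrogate_ibi(
            {
                "richness": row["richness"],
                "ept_richness": row["ept_richness"],
                "shannon": row["shannon"],
                "tolerance_complement": 10.0 - row["mean_tolerance"],
            },
            calibration,
        )
        rows.append(row)
    return pd.DataFrame(rows)
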