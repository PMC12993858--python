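"""Eligible-subset filtering, stratification, and the replicated network ensemble.

Network construction is restricted to spring, wadeable, AMD-free samples
with developed land cover <= 20%. Samples are classified by the joint
conventional/unconventional presence pattern; each (HUC8, class) stratum
with at least ``min_n`` samples contributes ``reps`` networks, each built
from ``k`` samples drawn without replacement using an RNG substream keyed by
(seed, huc8, group, rep) so results are independent of processing order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OGD_GROUPS
from .errors import ConfigurationError, InputError
from . import cooccur

ENSEMBLE_METRIC_COLUMNS = [
    "size",
    "connectance",
    "modularity",
    "mean_strength",
    "mean_tolerance",
    "prop_collector-gatherer",
    "prop_filter-collector",
    "prop_predator",
    "prop_scraper",
    "prop_shredder",
]


@dataclass
class Stratum:
    huc8: str
    ogd_group: str
    members: list[str]

    @property
    def n(self) -> int:
        return len(self.members)


def filter_subset(samples: pd.DataFrame, dlc_max: float = 0.20) -> pd.DataFrame:
    """Samples eligible for network construction: spring, wadeable, no AMD
    in the catchment, and DLC <= dlc_max (boundary inclusive)."""
    keep = (
        (samples["season"] == "spring")
        & (samples["stream_type"] == "wadeable")
        & (~samples["amd_present"].astype(bool))
        & (samples["dlc"] <= dlc_max)
    )
    return samples.loc[keep].reset_index(drop=True)


def classify(attribution: pd.DataFrame) -> pd.Series:
    """Joint 4-way OGD group from the two presence flags."""
    cogd = attribution["cogd_present"].astype(bool)
    uogd = attribution["uogd_present"].astype(bool)
    group = np.select(
        [~cogd & ~uogd, cogd & ~uogd, ~cogd & uogd],
        ["none", "cogd_only", "uogd_only"],
        default="both",
    )
    return pd.Series(group, index=attribution.index, name="ogd_group")


def enumerate_strata(
    subset: pd.DataFrame, min_n: int = 15
) -> list[Stratum]:
    """Eligible (huc8, ogd_group) strata, ordered by huc8 then group.

    ``subset`` must carry ``huc8`` and ``ogd_group`` columns; a stratum is
    eligible when it holds at least ``min_n`` samples (boundary inclusive).
    """
    strata = []
    for (huc8, group), members in subset.groupby(["huc8", "ogd_group"], sort=False):
        ids = sorted(members["sample_id"])
        if len(ids) >= min_n:
            strata.append(Stratum(huc8=huc8, ogd_group=group, members=ids))
    strata.sort(key=lambda s: (s.huc8, OGD_GROUPS.index(s.ogd_group)))
    return strata


def _substream(seed: int, huc8: str, group: str, rep: int) -> np.random.Generator:
    """Keyed RNG: invariant to stratum processing order."""
    key = [seed, zlib.crc32(huc8.encode()), OGD_GROUPS.index(group), rep]
    return np.random.default_rng(np.random.SeedSequence(key))


def run_ensemble(
    subset: pd.DataFrame,
    counts: pd.DataFrame,
    traits: pd.DataFrame,
    strata: list[Stratum],
    sample_ibi: pd.Series | None = None,
    reps: int = 100,
    k: int = 10,
    n_perm: int = 100,
    q_threshold: float = 1e-4,
    seed: int = 0,
) -> pd.DataFrame:
    """Replicated network ensemble metric table.

    Per stratum per repetition: draw ``k`` distinct samples, build the
    observation matrix against regional statistics computed once over the
    whole eligible subset, infer the FDR-filtered network, and emit one row
    of topology/composition metrics plus (when ``sample_ibi`` is given,
    indexed by sample_id) the mean surrogate condition index of the ``k``
    subsampled samples. Row count is always len(strata) * reps.
    """
    if reps <= 0 or k <= 0:
        raise ConfigurationError("reps and k must be positive")
    for stratum in strata:
        if k > stratum.n:
            raise ConfigurationError(
                f"k={k} exceeds stratum ({stratum.huc8}, {stratum.ogd_group}) size {stratum.n}"
            )
    if counts["sample_id"].isna().any():
        raise InputError("counts table has missing sample ids")

    counts_wide = (
        counts.pivot_table(
            index="sample_id", columns="taxon_id", values="count", fill_value=0
        )
        .reindex(subset["sample_id"], fill_value=0)
        .astype(np.int64)
    )
    # regional stats over the full filtered subset; drop never-seen taxa
    counts_wide = counts_wide.loc[:, (counts_wide > 0).any(axis=0)]
    frequency, pools = cooccur.regional_stats(counts_wide)

    rows = []
    for stratum in strata:
        for rep in range(reps):
            rng = _substream(seed, stratum.huc8, stratum.ogd_group, rep)
            chosen = list(rng.choice(stratum.members, size=k, replace=False))
            obs = cooccur.build_matrix(counts_wide, chosen, frequency, pools)
            edges = cooccur.fdr_filter(
                cooccur.ses_edges(obs, n_perm=n_perm, rng=rng), q_threshold
            )
            row = {"huc8": stratum.huc8, "ogd_group": stratum.ogd_group, "rep": rep}
            row.update(cooccur.topology(obs, edges, traits))
            if sample_ibi is not None:
                row["ibi"] = float(sample_ibi.loc[chosen].mean())
            rows.append(row)
    return pd.DataFrame(rows)
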