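"""Significance-filtered co-occurrence networks from 10-sample matrices.

The inference pipeline is: build a taxa x 10-site abundance matrix, compare
each taxon pair's statistic against richness-preserving null communities
(default 100 permutations), convert the standardized effect size (SES) to a
two-sided normal p-value, retain pairs passing a Benjamini-Hochberg false
discovery rate threshold (default 1e-4), and summarize the resulting graph
(size, connectance, modularity, mean |SES|) and its node composition.

Each null community preserves every site's richness: taxa are drawn without
replacement with probability proportional to their regional occurrence
frequency (Gumbel top-k, equivalent to sequential weighted draws), and each
drawn taxon's abundance is resampled with replacement from its regional
pool of observed nonzero abundances.

The three delegated choices — the pairwise statistic (Pearson on ln(x+1)),
the null abundance model, and the FDR procedure (BH step-up) — are each
isolated behind a single function so alternatives can be swapped.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import FFGS
from .errors import InputError

EDGE_COLUMNS = ["taxon_a", "taxon_b", "r_obs", "ses", "p", "q", "retained"]


@contextlib.contextmanager
def warnings_suppressed():
    # nanmean/nanstd warn on all-NaN slices; those entries are filtered after
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@dataclass
class ObservationMatrix:
    """Taxa x sites abundance matrix plus the regional statistics the null
    sampler needs (occurrence frequency and nonzero-abundance pool per
    taxon, computed over the full filtered sample subset)."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_sites) nonnegative ints
    regional_frequency: np.ndarray  # (n_taxa,)
    abundance_pools: list[np.ndarray] = field(repr=False, default_factory=list)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def site_richness(self) -> np.ndarray:
        return (self.matrix > 0).sum(axis=0)


def regional_stats(counts_wide: pd.DataFrame) -> tuple[pd.Series, dict[str, np.ndarray]]:
    """Occurrence frequency and nonzero-abundance pool per taxon.

    ``counts_wide`` is samples x taxa. Frequency is the fraction of samples
    where the taxon occurs; the pool is the multiset of its nonzero counts.
    """
    occur = counts_wide > 0
    frequency = occur.sum(axis=0) / len(counts_wide)
    pools = {
        taxon: counts_wide.loc[occur[taxon], taxon].to_numpy(dtype=float)
        for taxon in counts_wide.columns
    }
    return frequency, pools


def build_matrix(
    counts_wide: pd.DataFrame,
    sample_ids: list[str],
    frequency: pd.Series,
    pools: dict[str, np.ndarray],
) -> ObservationMatrix:
    """Observation matrix for one subsample of (typically 10) samples.

    Rows are restricted to taxa present in at least one of the selected
    samples; column order follows ``sample_ids``.
    """
    if len(set(sample_ids)) != len(sample_ids):
        raise InputError("duplicate sample ids in subsample")
    sub = counts_wide.loc[sample_ids]
    present = sub.columns[(sub > 0).any(axis=0)]
    matrix = sub[present].to_numpy(dtype=np.int64).T
    return ObservationMatrix(
        taxa=list(present),
        matrix=matrix,
        regional_frequency=frequency[present].to_numpy(dtype=float),
        abundance_pools=[pools[t] for t in present],
    )


def null_matrix(obs: ObservationMatrix, rng: np.random.Generator) -> np.ndarray:
    """One richness-preserving null community matrix.

    Per site, draws exactly the observed number of taxa without replacement
    with probability proportional to regional frequency, then fills each
    drawn cell with an abundance resampled from that taxon's regional pool.
    """
    weights = obs.regional_frequency
    if np.any(weights <= 0):
        raise InputError("regional frequencies must be positive for all matrix taxa")
    n_taxa, n_sites = obs.matrix.shape
    richness = obs.site_richness
    if richness.max(initial=0) > n_taxa:
        raise InputError("site richness exceeds the available taxon pool")
    # Gumbel top-k == sequential weighted sampling without replacement
    keys = np.log(weights)[:, None] + rng.gumbel(size=(n_taxa, n_sites))
    order = np.argsort(-keys, axis=0)
    null = np.zeros_like(obs.matrix)
    for j in range(n_sites):
        chosen = order[: richness[j], j]
        for t in chosen:
            pool = obs.abundance_pools[t]
            null[t, j] = pool[rng.integers(len(pool))]
    return null


def _pool_arrays(obs: ObservationMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Regional abundance pools padded into one (n_taxa, max_len) array."""
    lens = np.array([len(p) for p in obs.abundance_pools], dtype=np.int64)
    if np.any(lens == 0):
        raise InputError("every matrix taxon needs a nonempty regional abundance pool")
    arr = np.zeros((len(lens), lens.max()), dtype=float)
    for i, pool in enumerate(obs.abundance_pools):
        arr[i, : len(pool)] = pool
    return arr, lens


def null_stack(obs: ObservationMatrix, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """``n_perm`` richness-preserving null matrices, (n_perm, n_taxa, n_sites).

    Same sampling scheme as :func:`null_matrix`, vectorized across sites and
    permutations: Gumbel top-k selects each site's taxa proportionally to
    regional frequency without replacement, and abundances are resampled
    uniformly from each taxon's regional pool.
    """
    weights = obs.regional_frequency
    if np.any(weights <= 0):
        raise InputError("regional frequencies must be positive for all matrix taxa")
    n_taxa, n_sites = obs.matrix.shape
    richness = obs.site_richness
    if richness.max(initial=0) > n_taxa:
        raise InputError("site richness exceeds the available taxon pool")
    keys = np.log(weights)[None, :, None] + rng.gumbel(size=(n_perm, n_taxa, n_sites))
    order = np.argsort(-keys, axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(
        ranks, order, np.broadcast_to(np.arange(n_taxa)[None, :, None], order.shape), axis=1
    )
    mask = ranks < richness[None, None, :]
    pool_arr, pool_len = _pool_arrays(obs)
    draw = (rng.random(size=(n_perm, n_taxa, n_sites)) * pool_len[None, :, None]).astype(np.int64)
    abundances = pool_arr[np.arange(n_taxa)[None, :, None], draw]
    return np.where(mask, abundances, 0.0)


def pair_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of ln(abundance + 1) vectors; NaN when either
    vector has zero variance (the undefined flag, not an error)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if (x == x[0]).all() or (y == y[0]).all():
        return float("nan")
    return float(np.corrcoef(np.log1p(x), np.log1p(y))[0, 1])


def _corr_stack(stack: np.ndarray) -> np.ndarray:
    """Pairwise pair-statistic matrices for a (..., n_taxa, n_sites) stack;
    pairs involving a constant vector give NaN."""
    stack = np.asarray(stack, dtype=float)
    constant = (stack == stack[..., :1]).all(axis=-1)  # exact, pre-transform
    logm = np.log1p(stack)
    centered = logm - logm.mean(axis=-1, keepdims=True)
    norm = np.sqrt((centered * centered).sum(axis=-1))
    constant |= norm == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norm[..., None]
    corr = unit @ unit.swapaxes(-1, -2)
    corr = np.clip(corr, -1.0, 1.0)
    bad = constant[..., :, None] | constant[..., None, :]
    corr[bad] = np.nan
    return corr


def _corr_all_pairs(matrix: np.ndarray) -> np.ndarray:
    """Full pairwise matrix of the pair statistic; constant rows give NaN."""
    return _corr_stack(matrix[None])[0]


#: null sds below this are treated as exactly zero (degenerate null)
SD_FLOOR = 1e-12


def standardized_effect(r_obs: float, null_values: np.ndarray) -> float:
    """SES = (r_obs - mean(null)) / sd(null), sample sd (ddof=1).

    NaN when fewer than two defined null values or when their sd is zero
    (below :data:`SD_FLOOR`, absorbing float rounding of identical values).
    """
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[~np.isnan(null_values)]
    if len(null_values) < 2:
        return float("nan")
    sd = null_values.std(ddof=1)
    if sd <= SD_FLOOR:
        return float("nan")
    return float((r_obs - null_values.mean()) / sd)


def ses_edges(
    obs: ObservationMatrix,
    n_perm: int = 100,
    rng: np.random.Generator | None = None,
    nulls: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-pair observed statistic, SES over null permutations, and p-value.

    ``nulls`` may supply precomputed null matrices (for oracle testing);
    otherwise ``n_perm`` matrices are drawn with ``rng``. Pairs whose
    statistic is undefined in the observation, or whose null distribution is
    degenerate, are excluded. p = 2*(1 - Phi(|ses|)).
    """
    if nulls is None:
        if n_perm < 2:
            raise InputError("n_perm must be >= 2")
        if rng is None:
            raise InputError("an rng is required when nulls are not supplied")
        stack = null_stack(obs, n_perm, rng)
    else:
        stack = np.stack([np.asarray(m, dtype=float) for m in nulls])
    n_taxa = len(obs.taxa)
    r_obs = _corr_all_pairs(obs.matrix)
    null_corr = _corr_stack(stack)  # (n_perm, t, t)

    defined = ~np.isnan(null_corr)
    n_defined = defined.sum(axis=0)
    with warnings_suppressed():
        null_mean = np.nanmean(null_corr, axis=0)
        null_sd = np.nanstd(null_corr, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = (r_obs - null_mean) / null_sd
    keep = ~np.isnan(r_obs) & (n_defined >= 2) & (null_sd > SD_FLOOR)

    a_idx, b_idx = np.triu_indices(n_taxa, k=1)
    mask = keep[a_idx, b_idx]
    a_idx, b_idx = a_idx[mask], b_idx[mask]
    ses_vals = ses[a_idx, b_idx]
    taxa = np.asarray(obs.taxa, dtype=object)
    return pd.DataFrame(
        {
            "taxon_a": taxa[a_idx],
            "taxon_b": taxa[b_idx],
            "r_obs": r_obs[a_idx, b_idx],
            "ses": ses_vals,
            "p": 2.0 * stats.norm.sf(np.abs(ses_vals)),
        },
        columns=["taxon_a", "taxon_b", "r_obs", "ses", "p"],
    )


def fdr_filter(edges: pd.DataFrame, q_threshold: float = 1e-4) -> pd.DataFrame:
    """Benjamini-Hochberg step-up over all tested pairs of the network;
    ``retained`` is q < q_threshold."""
    edges = edges.copy()
    if len(edges) == 0:
        edges["q"] = pd.Series(dtype=float)
        edges["retained"] = pd.Series(dtype=bool)
        return edges[EDGE_COLUMNS] if set(EDGE_COLUMNS) <= set(edges.columns) else edges
    _, q, _, _ = multipletests(edges["p"].to_numpy(), method="fdr_bh")
    edges["q"] = q
    edges["retained"] = q < q_threshold
    return edges


def modularity(
    nodes: list[str], edges: pd.DataFrame, communities: list[set[str]] | None = None
) -> float:
    """Newman modularity of |SES|-weighted retained edges.

    With ``communities`` None, the partition is found by deterministic
    greedy agglomeration (nodes inserted in sorted order). Returns 0.0 for
    edgeless graphs.
    """
    import networkx as nx

    retained = edges[edges["retained"]] if "retained" in edges.columns else edges
    if len(retained) == 0:
        return 0.0
    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    for row in retained.itertuples(index=False):
        graph.add_edge(row.taxon_a, row.taxon_b, weight=abs(row.ses))
    if communities is None:
        communities = nx.algorithms.community.greedy_modularity_communities(
            graph, weight="weight"
        )
    return float(
        nx.algorithms.community.modularity(graph, communities, weight="weight")
    )


def topology(
    obs: ObservationMatrix, edges: pd.DataFrame, traits: pd.DataFrame
) -> dict[str, float]:
    """Topology and node-composition metrics of one network.

    size counts all matrix rows (isolated taxa included); connectance is
    retained edges over size*(size-1)/2; mean_strength is mean |SES| over
    retained edges (0 when none); composition is unweighted over node taxa.
    """
    size = len(obs.taxa)
    if size < 2:
        raise InputError("connectance is undefined for networks of fewer than 2 taxa")
    retained = edges[edges["retained"]] if "retained" in edges.columns else edges
    n_edges = len(retained)
    out = {
        "size": size,
        "connectance": n_edges / (size * (size - 1) / 2),
        "mean_strength": float(retained["ses"].abs().mean()) if n_edges else 0.0,
        "modularity": modularity(obs.taxa, retained),
    }
    node_traits = traits.set_index("taxon_id").loc[obs.taxa]
    out["mean_tolerance"] = float(node_traits["tolerance"].mean())
    ffg_counts = node_traits["ffg"].value_counts()
    classified = sum(ffg_counts.get(g, 0) for g in FFGS)
    for g in FFGS:
        out[f"prop_{g}"] = (ffg_counts.get(g, 0) / classified) if classified else float("nan")
    return out


def to_graphml(obs: ObservationMatrix, edges: pd.DataFrame, traits: pd.DataFrame, path) -> None:
    """Write the retained-edge network as GraphML with ffg/tolerance node
    attributes and the SES edge attribute."""
    import networkx as nx

    node_traits = traits.set_index("taxon_id")
    graph = nx.Graph()
    for taxon in obs.taxa:
        graph.add_node(
            taxon,
            ffg=str(node_traits.loc[taxon, "ffg"]),
            tolerance=float(node_traits.loc[taxon, "tolerance"]),
        )
    retained = edges[edges["retained"]] if "retained" in edges.columns else edges
    for row in retained.itertuples(index=False):
        graph.add_edge(row.taxon_a, row.taxon_b, ses=float(row.ses))
    nx.write_graphml(graph, path)
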