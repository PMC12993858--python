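import math

import numpy as np
import pandas as pd
import pytest

from streamnets import cooccur
from streamnets.errors import InputError


def _obs_from_matrix(matrix, frequency=None):
    """ObservationMatrix with regional stats derived from the matrix itself."""
    matrix = np.asarray(matrix, dtype=np.int64)
    n = len(matrix)
    taxa = [f"T{i}" for i in range(n)]
    if frequency is None:
        frequency = (matrix > 0).mean(axis=1)
    pools = [
        row[row > 0].astype(float) if (row > 0).any() else np.array([1.0])
        for row in matrix
    ]
    return cooccur.ObservationMatrix(
        taxa=taxa,
        matrix=matrix,
        regional_frequency=np.asarray(frequency, dtype=float),
        abundance_pools=pools,
    )


class TestBuildMatrix:
    def _wide(self):
        rng = np.random.default_rng(1)
        data = rng.integers(0, 8, size=(12, 6))
        data[:, 5] = 0  # taxon absent everywhere
        wide = pd.DataFrame(
            data, index=[f"S{i}" for i in range(12)], columns=[f"T{i}" for i in range(6)]
        )
        freq, pools = cooccur.regional_stats(wide)
        return wide, freq, pools

    def test_absent_taxon_dropped(self):
        wide, freq, pools = self._wide()
        sel = [f"S{i}" for i in range(10)]
        # taxon 5 has zero regional frequency; avoid it via present-rows rule
        obs = cooccur.build_matrix(wide, sel, freq, pools)
        assert "T5" not in obs.taxa

    def test_all_present_taxa_kept(self):
        wide, freq, pools = self._wide()
        sel = [f"S{i}" for i in range(10)]
        present = (wide.loc[sel] > 0).any(axis=0).sum()
        obs = cooccur.build_matrix(wide, sel, freq, pools)
        assert len(obs.taxa) == present == obs.matrix.shape[0]

    def test_column_order_preserved(self):
        wide, freq, pools = self._wide()
        sel = [f"S{i}" for i in (3, 1, 4, 0, 2, 5, 6, 7, 8, 9)]
        obs = cooccur.build_matrix(wide, sel, freq, pools)
        np.testing.assert_array_equal(obs.matrix[:, 0], wide.loc["S3", obs.taxa].to_numpy())

    def test_duplicate_sample_ids_rejected(self):
        wide, freq, pools = self._wide()
        with pytest.raises(InputError):
            cooccur.build_matrix(wide, ["S0"] * 10, freq, pools)


class TestNullMatrix:
    def test_site_richness_preserved(self, rng):
        obs = _obs_from_matrix(np.random.default_rng(2).integers(0, 5, size=(15, 10)))
        null = cooccur.null_matrix(obs, rng)
        np.testing.assert_array_equal((null > 0).sum(axis=0), obs.site_richness)

    def test_null_stack_richness_preserved(self, rng):
        obs = _obs_from_matrix(np.random.default_rng(3).integers(0, 5, size=(15, 10)))
        stack = cooccur.null_stack(obs, 50, rng)
        for null in stack:
            np.testing.assert_array_equal((null > 0).sum(axis=0), obs.site_richness)

    def test_zero_frequency_taxon_rejected(self, rng):
        matrix = np.ones((3, 10), dtype=int)
        obs = _obs_from_matrix(matrix, frequency=[0.5, 0.0, 0.5])
        with pytest.raises(InputError):
            cooccur.null_matrix(obs, rng)

    def test_abundances_come_from_regional_pools(self, rng):
        matrix = np.array([[7, 7, 0, 7, 7, 7, 0, 7, 7, 7],
                           [3, 0, 3, 3, 3, 3, 3, 0, 3, 3]])
        obs = _obs_from_matrix(matrix)
        null = cooccur.null_matrix(obs, rng)
        assert set(null[0][null[0] > 0]) <= {7.0}
        assert set(null[1][null[1] > 0]) <= {3.0}

    def test_draw_frequency_proportional_at_richness_one(self, rng):
        # at site richness 1 the inclusion probability is exactly the
        # normalized regional frequency; check +-3 Monte-Carlo SE
        matrix = np.zeros((4, 1), dtype=int)
        matrix[0, 0] = 1  # single site with richness 1
        freq = np.array([0.5, 0.25, 0.15, 0.10])
        obs = _obs_from_matrix(matrix, frequency=freq)
        n_draws = 10_000
        stack = cooccur.null_stack(obs, n_draws, rng)
        hits = (stack[:, :, 0] > 0).sum(axis=0)
        p = freq / freq.sum()
        se = np.sqrt(p * (1 - p) * n_draws)
        assert np.all(np.abs(hits - n_draws * p) <= 3 * se)


class TestPairStatistic:
    def test_identical_vectors(self):
        x = np.array([1, 2, 3, 0, 5, 1, 2, 3, 0, 5])
        assert cooccur.pair_statistic(x, x) == pytest.approx(1.0)

    def test_alternating_occurrences_anticorrelated(self):
        x = np.array([1, 0] * 5)
        y = np.array([0, 1] * 5)
        assert cooccur.pair_statistic(x, y) == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(cooccur.pair_statistic(np.full(10, 4), np.arange(10)))

    def test_matches_log_transformed_pearson(self, rng):
        from scipy import stats

        x, y = rng.integers(0, 9, 10), rng.integers(0, 9, 10)
        want = stats.pearsonr(np.log1p(x), np.log1p(y)).statistic
        assert cooccur.pair_statistic(x, y) == pytest.approx(want, abs=1e-12)


class TestStandardizedEffect:
    def test_ses_zero_when_obs_equals_null_mean(self):
        assert cooccur.standardized_effect(0.2, [0.1, 0.2, 0.3]) == pytest.approx(0.0)
        p = 2 * (1 - 0.5)
        assert p == pytest.approx(1.0)

    def test_ses_from_spec_example(self):
        assert cooccur.standardized_effect(0.4, [0.1, 0.2, 0.3]) == pytest.approx(2.0)

    def test_degenerate_null_flagged(self):
        assert math.isnan(cooccur.standardized_effect(0.4, [0.2, 0.2, 0.2]))
        assert math.isnan(cooccur.standardized_effect(0.4, [0.2]))


def _brute_force_ses(obs, nulls):
    """Independent loop-based reimplementation of the SES computation."""
    from scipy import stats as sps

    def corr(u, v):
        lu, lv = np.log1p(u.astype(float)), np.log1p(v.astype(float))
        if lu.std() == 0 or lv.std() == 0:
            return float("nan")
        return float(np.corrcoef(lu, lv)[0, 1])

    out = {}
    n = len(obs.taxa)
    for a in range(n):
        for b in range(a + 1, n):
            r = corr(obs.matrix[a], obs.matrix[b])
            if math.isnan(r):
                continue
            null_vals = [corr(m[a], m[b]) for m in nulls]
            null_vals = [v for v in null_vals if not math.isnan(v)]
            if len(null_vals) < 2:
                continue
            mean = sum(null_vals) / len(null_vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in null_vals) / (len(null_vals) - 1))
            if sd == 0:
                continue
            ses = (r - mean) / sd
            out[(obs.taxa[a], obs.taxa[b])] = (ses, 2 * sps.norm.sf(abs(ses)))
    return out


class TestSesEdges:
    def test_matches_brute_force_oracle(self, rng):
        obs = _obs_from_matrix(np.random.default_rng(7).integers(0, 6, size=(4, 10)))
        nulls = [cooccur.null_matrix(obs, rng) for _ in range(25)]
        got = cooccur.ses_edges(obs, nulls=nulls)
        want = _brute_force_ses(obs, nulls)
        assert set(zip(got["taxon_a"], got["taxon_b"])) == set(want)
        for row in got.itertuples(index=False):
            ses, p = want[(row.taxon_a, row.taxon_b)]
            assert row.ses == pytest.approx(ses, abs=1e-10)
            assert row.p == pytest.approx(p, abs=1e-10)

    def test_site_relabeling_invariance(self, rng):
        obs = _obs_from_matrix(np.random.default_rng(8).integers(0, 6, size=(6, 10)))
        perm = np.random.default_rng(9).permutation(10)
        obs_perm = cooccur.ObservationMatrix(
            taxa=obs.taxa,
            matrix=obs.matrix[:, perm],
            regional_frequency=obs.regional_frequency,
            abundance_pools=obs.abundance_pools,
        )
        nulls = [cooccur.null_matrix(obs, np.random.default_rng(5)) for _ in range(10)]
        a = cooccur.ses_edges(obs, nulls=nulls)
        b = cooccur.ses_edges(obs_perm, nulls=nulls)
        np.testing.assert_allclose(a["ses"], b["ses"], atol=1e-12)

    def test_all_constant_rows_give_empty_table(self, rng):
        obs = _obs_from_matrix(np.full((3, 10), 2))
        edges = cooccur.ses_edges(obs, n_perm=10, rng=rng)
        assert len(edges) == 0


class TestFdrFilter:
    def test_hand_computed_bh_example(self):
        edges = pd.DataFrame(
            {"taxon_a": list("abc"), "taxon_b": list("xyz"),
             "r_obs": [0.9, 0.1, 0.0], "ses": [5.0, 0.5, 0.1],
             "p": [1e-6, 0.5, 0.9]}
        )
        out = cooccur.fdr_filter(edges, q_threshold=1e-4)
        # BH by hand: q = (3e-6, 0.75, 0.9); only the first passes 1e-4
        assert out["retained"].tolist() == [True, False, False]
        assert out["q"].iloc[0] == pytest.approx(3e-6)

    def test_all_p_one_retains_nothing(self):
        edges = pd.DataFrame({"taxon_a": list("ab"), "taxon_b": list("xy"),
                              "r_obs": [0, 0], "ses": [0, 0], "p": [1.0, 1.0]})
        assert not cooccur.fdr_filter(edges).retained.any()

    def test_single_pair_m_equals_one(self):
        edges = pd.DataFrame({"taxon_a": ["a"], "taxon_b": ["b"],
                              "r_obs": [0.9], "ses": [4.1], "p": [5e-5]})
        assert cooccur.fdr_filter(edges, 1e-4).retained.all()

    def test_q_at_least_p(self, rng):
        p = rng.uniform(0, 1, 40)
        edges = pd.DataFrame({"taxon_a": [f"a{i}" for i in range(40)],
                              "taxon_b": [f"b{i}" for i in range(40)],
                              "r_obs": 0.0, "ses": 0.0, "p": p})
        out = cooccur.fdr_filter(edges)
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_empty_table_valid(self):
        out = cooccur.fdr_filter(pd.DataFrame(columns=["taxon_a", "taxon_b", "r_obs", "ses", "p"]))
        assert len(out) == 0 and "retained" in out.columns


def _edges(pairs, ses=5.0, retained=True):
    return pd.DataFrame(
        [{"taxon_a": a, "taxon_b": b, "r_obs": 0.9, "ses": ses, "p": 0.0,
          "q": 0.0, "retained": retained} for a, b in pairs]
    )


class TestTopology:
    def _traits_for(self, taxa):
        return pd.DataFrame(
            {"taxon_id": taxa, "order": "other", "ffg": "predator",
             "tolerance": 5.0}
        )

    def test_connectance_four_edges_five_nodes(self):
        obs = _obs_from_matrix(np.eye(5, 10, dtype=int) + 1)
        edges = _edges([("T0", "T1"), ("T1", "T2"), ("T2", "T3"), ("T3", "T4")])
        out = cooccur.topology(obs, edges, self._traits_for(obs.taxa))
        assert out["connectance"] == pytest.approx(0.4)
        assert out["size"] == 5

    def test_complete_graph_connectance_one_modularity_zero(self):
        obs = _obs_from_matrix(np.eye(4, 10, dtype=int) + 1)
        pairs = [(f"T{i}", f"T{j}") for i in range(4) for j in range(i + 1, 4)]
        out = cooccur.topology(obs, _edges(pairs, ses=1.0), self._traits_for(obs.taxa))
        assert out["connectance"] == pytest.approx(1.0)
        # single community over a complete unit-weight graph
        assert cooccur.modularity(obs.taxa, _edges(pairs, ses=1.0),
                                  communities=[set(obs.taxa)]) == pytest.approx(0.0)

    def test_two_triangles_modularity_half(self):
        obs = _obs_from_matrix(np.eye(6, 10, dtype=int) + 1)
        pairs = [("T0", "T1"), ("T1", "T2"), ("T0", "T2"),
                 ("T3", "T4"), ("T4", "T5"), ("T3", "T5")]
        edges = _edges(pairs, ses=1.0)
        # Newman formula by hand: 2 * (0.5 - 0.25) = 0.5
        assert cooccur.modularity(obs.taxa, edges) == pytest.approx(0.5)
        out = cooccur.topology(obs, edges, self._traits_for(obs.taxa))
        assert out["modularity"] == pytest.approx(0.5)

    def test_no_edges_reports_zeros(self):
        obs = _obs_from_matrix(np.eye(3, 10, dtype=int) + 1)
        empty = _edges([]).iloc[0:0]
        out = cooccur.topology(obs, empty, self._traits_for(obs.taxa))
        assert out["connectance"] == 0.0
        assert out["mean_strength"] == 0.0
        assert out["modularity"] == 0.0

    def test_mean_strength_uses_absolute_ses(self):
        obs = _obs_from_matrix(np.eye(3, 10, dtype=int) + 1)
        edges = pd.concat([_edges([("T0", "T1")], ses=-3.0), _edges([("T1", "T2")], ses=5.0)])
        out = cooccur.topology(obs, edges, self._traits_for(obs.taxa))
        assert out["mean_strength"] == pytest.approx(4.0)

    def test_composition_metrics(self, traits):
        matrix = np.eye(3, 10, dtype=int) + 1
        obs = _obs_from_matrix(matrix)
        obs.taxa = ["T1", "T2", "T7"]  # CG tol 2, shredder tol 4, unknown tol 1
        out = cooccur.topology(obs, _edges([]).iloc[0:0], traits)
        assert out["mean_tolerance"] == pytest.approx((2 + 4 + 1) / 3)
        assert out["prop_collector-gatherer"] == pytest.approx(0.5)
        assert out["prop_shredder"] == pytest.approx(0.5)

    def test_single_taxon_network_rejected(self, traits):
        obs = _obs_from_matrix(np.ones((1, 10), dtype=int))
        with pytest.raises(InputError):
            cooccur.topology(obs, _edges([]).iloc[0:0], traits)

    def test_adding_edge_increases_connectance(self):
        obs = _obs_from_matrix(np.eye(5, 10, dtype=int) + 1)
        tr = self._traits_for(obs.taxa)
        e1 = _edges([("T0", "T1")])
        e2 = _edges([("T0", "T1"), ("T2", "T3")])
        assert (
            cooccur.topology(obs, e2, tr)["connectance"]
            > cooccur.topology(obs, e1, tr)["connectance"]
        )


def test_graphml_round_trip(tmp_path, traits):
    import networkx as nx

    matrix = np.eye(2, 10, dtype=int) + 1
    obs = _obs_from_matrix(matrix)
    obs.taxa = ["T1", "T2"]
    edges = _edges([("T1", "T2")], ses=3.5)
    path = tmp_path / "net.graphml"
    cooccur.to_graphml(obs, edges, traits, path)
    g = nx.read_graphml(path)
    assert g.nodes["T1"]["ffg"] == "collector-gatherer"
    assert g.edges["T1", "T2"]["ses"] == pytest.approx(3.5)
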