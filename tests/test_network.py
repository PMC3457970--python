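"""Anchored shortest-path inference, pruning, coherency, pathway stats."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from metkinsig import (
    AnchoredNetworkModel,
    AnchoredPathway,
    GeneSet,
    PPINetwork,
    SimulationConfig,
    build_anchored_network,
    coherency_prognosis_correlation,
    coherency_ranking,
    edge_correlation_test,
    pathway_differentiation_test,
    pathway_prognosis_test,
    prognosis_ranking,
    prune_contained,
    simulate_cell_model,
    simulate_ppi,
    zscore_per_gene,
)
from metkinsig.network import shortest_confidence_path
from metkinsig.simulate import gene_ids


def net(edges, overrides=(), removed=()):
    g = nx.Graph()
    for u, v, c in edges:
        g.add_edge(u, v, confidence=c)
    return PPINetwork(g, set(overrides), set(removed))


def brute_force_best_path(ppi, anchor, terminal):
    """Exhaustive enumeration of simple paths, same tie-break order."""
    g = ppi.working_graph()
    best = None
    for path in nx.all_simple_paths(g, anchor, terminal):
        if any(not ppi.allows(u, v) for u, v in zip(path[:-1], path[1:])):
            continue
        w = sum(-np.log(g[u][v]["confidence"]) for u, v in zip(path[:-1], path[1:]))
        key = (w, len(path) - 1, tuple(str(n) for n in path))
        if best is None or key < best[0]:
            best = (key, path)
    return best


class TestShortestPath:
    def test_two_hop_beats_weaker_direct_edge(self):
        # -ln 0.9 = 0.105 > 2 * -ln 0.99 = 0.020
        ppi = net([("A", "T", 0.9), ("A", "M", 0.99), ("M", "T", 0.99)])
        path, w = shortest_confidence_path(ppi, "A", "T")
        assert path == ["A", "M", "T"]
        assert w == pytest.approx(-2 * np.log(0.99))

    def test_directed_override_blocks_reverse_traversal(self):
        ppi = net([("A", "M", 0.99), ("M", "T", 0.99), ("A", "T", 0.5)],
                  overrides={("T", "M")})  # M->T traversal forbidden
        path, _ = shortest_confidence_path(ppi, "A", "T")
        assert path == ["A", "T"]

    def test_removed_nodes_excluded(self):
        ppi = net([("A", "M", 0.99), ("M", "T", 0.99), ("A", "T", 0.5)],
                  removed={"M"})
        path, _ = shortest_confidence_path(ppi, "A", "T")
        assert path == ["A", "T"]

    def test_tie_break_lexicographic(self):
        # two equal-weight 2-hop routes: via B and via C -> B wins
        ppi = net([("A", "B", 0.9), ("B", "T", 0.9),
                   ("A", "C", 0.9), ("C", "T", 0.9)])
        path, _ = shortest_confidence_path(ppi, "A", "T")
        assert path == ["A", "B", "T"]

    def test_matches_exhaustive_enumeration_on_small_graphs(self):
        rng = np.random.default_rng(23)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["confidence"] = float(rng.uniform(0.05, 1.0))
            ppi = PPINetwork(g)
            anchor, terminal = 0, n - 1
            got = shortest_confidence_path(ppi, anchor, terminal)
            expected = brute_force_best_path(ppi, anchor, terminal)
            if expected is None:
                assert got is None
            else:
                (key, path) = expected
                assert got[0] == path
                assert got[1] == pytest.approx(key[0])
                checked += 1
        assert checked >= 100


class TestBuildAnchoredNetwork:
    def test_planted_paths_recovered(self):
        cfg = SimulationConfig(n_genes=600, ppi_n_nodes=260, ppi_n_edges=900, seed=7,
                               planted_group_sizes={("down", 10): 40})
        terminals = gene_ids(600)[:40]
        ppi, planted = simulate_ppi(cfg, "MET", terminals)
        pathways, sub, left_out = build_anchored_network(ppi, "MET", terminals)
        assert not left_out
        recovered = sum(tuple(planted[p.terminal]) == p.nodes for p in pathways)
        assert recovered >= 0.95 * len(pathways)
        # pathway invariants: consecutive edges exist, nodes distinct
        for p in pathways:
            assert len(set(p.nodes)) == len(p.nodes)
            for u, v in zip(p.nodes[:-1], p.nodes[1:]):
                assert ppi.graph.has_edge(u, v)
            assert p.weight >= 0

    def test_missing_terminal_reported_not_fatal(self):
        ppi = net([("A", "B", 0.9), ("B", "T", 0.9)])
        pathways, _, left_out = build_anchored_network(ppi, "A", ["T", "GHOST"])
        assert [p.terminal for p in pathways] == ["T"]
        assert left_out == ["GHOST"]

    def test_absent_anchor_errors(self):
        ppi = net([("A", "B", 0.9)])
        with pytest.raises(ValueError, match="anchor"):
            build_anchored_network(ppi, "X", ["B"])


class TestPruneContained:
    def _pw(self, *nodes):
        return AnchoredPathway(tuple(nodes), 1.0)

    def test_longer_superpath_removed(self):
        kept = prune_contained([self._pw("A", "B", "C"), self._pw("A", "B", "C", "D")])
        assert [p.nodes for p in kept] == [("A", "B", "C")]

    def test_disjoint_untouched(self):
        paths = [self._pw("A", "B", "C"), self._pw("A", "X", "Y")]
        assert prune_contained(paths) == paths

    def test_three_nested_only_shortest_survives(self):
        paths = [self._pw("A", "B"), self._pw("A", "B", "C"),
                 self._pw("A", "B", "C", "D")]
        kept = prune_contained(paths)
        assert [p.nodes for p in kept] == [("A", "B")]

    def test_non_contiguous_subset_not_pruned(self):
        # shares nodes but not as a contiguous run
        paths = [self._pw("A", "B", "C"), self._pw("A", "X", "B", "Y", "C")]
        assert len(prune_contained(paths)) == 2


class TestCoherency:
    def _z(self, rows: dict) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_identical_profiles_give_one(self):
        z = self._z({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        coh, used, skipped = coherency_ranking(AnchoredPathway(("a", "b", "c"), 0.0), z)
        assert coh == pytest.approx(1.0)
        assert used == 2 and skipped == 0

    def test_anticorrelated_pair(self):
        z = self._z({"a": [1, 2, 3], "b": [3, 2, 1]})
        coh, _, _ = coherency_ranking(AnchoredPathway(("a", "b"), 0.0), z)
        assert coh == pytest.approx(-1.0)

    def test_reversal_invariance_and_order_sensitivity(self):
        rng = np.random.default_rng(29)
        z = self._z({k: rng.normal(0, 1, 10) for k in "abcd"})
        fwd, _, _ = coherency_ranking(AnchoredPathway(tuple("abcd"), 0.0), z)
        rev, _, _ = coherency_ranking(AnchoredPathway(tuple("dcba"), 0.0), z)
        swapped, _, _ = coherency_ranking(AnchoredPathway(tuple("acbd"), 0.0), z)
        assert fwd == pytest.approx(rev)
        assert swapped != pytest.approx(fwd)

    def test_missing_gene_pairs_skipped(self):
        z = self._z({"a": [1, 2, 3], "c": [1, 2, 3]})
        coh, used, skipped = coherency_ranking(AnchoredPathway(("a", "b", "c"), 0.0), z)
        assert np.isnan(coh) and used == 0 and skipped == 2

    def test_bounds_on_simulated_pathways(self, small_model):
        matrix, _ = small_model
        cell_z = zscore_per_gene(matrix.values, by=matrix.sample_meta["cell_line"])
        rng = np.random.default_rng(31)
        genes = list(matrix.genes)
        for _ in range(25):
            chain = tuple(rng.choice(genes, size=4, replace=False))
            coh, used, _ = coherency_ranking(AnchoredPathway(chain, 0.0), cell_z)
            if used:
                assert -1.0 - 1e-9 <= coh <= 1.0 + 1e-9


class TestRankings:
    def test_prognosis_ranking_hand_values(self):
        assert prognosis_ranking([0.001, 0.01, 0.05]) == pytest.approx(np.log10(0.05))
        assert prognosis_ranking([1.0, 1.0]) == pytest.approx(0.0)
        assert np.isnan(prognosis_ranking([np.nan, np.nan]))

    def test_prognosis_ranking_monotone(self):
        base = [0.001, 0.01, 0.02]
        worse = [0.001, 0.01, 0.2]
        assert prognosis_ranking(worse) >= prognosis_ranking(base)

    def test_spearman_extremes(self):
        x = [0.1, 0.5, 0.9, 1.3]
        rho, _ = coherency_prognosis_correlation(x, x)
        assert rho == pytest.approx(1.0)
        rho, _ = coherency_prognosis_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_too_few_pathways_errors(self):
        with pytest.raises(ValueError):
            coherency_prognosis_correlation([0.1, 0.2], [0.3, 0.4])


class TestPathwayTests:
    def test_identical_groups_p_near_one(self):
        table = pd.DataFrame({f"s{i}": [0.5] for i in range(8)},
                             index=["p1"])
        table.loc["p1"] = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        groups = pd.Series(["high"] * 4 + ["low"] * 4, index=table.columns)
        res = pathway_differentiation_test(table, groups)
        assert res.loc["p1", "p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_planted_pathway_differentiates(self, small_model, planted_signature):
        matrix, _ = small_model
        z = zscore_per_gene(matrix.values)
        genes = sorted(planted_signature.genes)[:4]
        pw = AnchoredPathway(tuple(genes), 0.0)
        table = pd.DataFrame({pw.pathway_id: z.loc[list(pw.nodes)].mean(axis=0)}).T
        res = pathway_differentiation_test(table, matrix.sample_meta["met_group"])
        assert res.iloc[0]["p_value"] < 0.05

    def test_prognosis_shape_three_cohorts(self):
        rng = np.random.default_rng(37)
        patients = [f"p{i}" for i in range(30)]
        tables, labels = {}, {}
        for c in ("c1", "c2", "c3"):
            tables[c] = pd.DataFrame(rng.normal(0, 1, (2, 30)),
                                     index=["pw1", "pw2"], columns=patients)
            labels[c] = pd.Series(rng.choice(["good", "bad"], 30), index=patients)
        res = pathway_prognosis_test(tables, labels)
        assert res.shape == (2, 3)
        assert set(res.columns) == {"c1", "c2", "c3"}

    def test_cohort_without_both_classes_is_na(self):
        patients = [f"p{i}" for i in range(10)]
        tables = {"c": pd.DataFrame(np.ones((1, 10)), index=["pw"], columns=patients)}
        labels = {"c": pd.Series("bad", index=patients)}
        res = pathway_prognosis_test(tables, labels)
        assert res["c"].isna().all()


class TestEdgeCorrelation:
    def test_coregulated_subnetwork_detected(self):
        rng = np.random.default_rng(41)
        n_samp = 24
        latent = rng.normal(0, 1, n_samp)
        rows = {}
        sub_edges = nx.Graph()
        for i in range(30):
            rows[f"s{i}"] = latent + rng.normal(0, 0.5, n_samp)
        for i in range(29):
            sub_edges.add_edge(f"s{i}", f"s{i+1}", confidence=0.9)
        bg = nx.Graph()
        for i in range(200):
            rows[f"b{i}"] = rng.normal(0, 1, n_samp)
        for i in range(199):
            bg.add_edge(f"b{i}", f"b{i+1}", confidence=0.5)
        z = zscore_per_gene(pd.DataFrame.from_dict(rows, orient="index"))
        res = edge_correlation_test(sub_edges, z, PPINetwork(bg))
        assert res.wmw_p_greater < 0.001
        assert len(res.background_correlations) == 199

    def test_insufficient_pairs_errors(self):
        z = zscore_per_gene(pd.DataFrame(np.random.default_rng(0).normal(0, 1, (4, 6)),
                                         index=list("abcd")))
        sub = nx.Graph()
        sub.add_edge("a", "b", confidence=0.9)
        bg = nx.Graph()
        bg.add_edge("c", "d", confidence=0.5)
        with pytest.raises(ValueError, match="insufficient"):
            edge_correlation_test(sub, z, PPINetwork(bg))


class TestAnchoredNetworkModel:
    def test_fit_summary_and_pruning(self):
        cfg = SimulationConfig(n_genes=400, ppi_n_nodes=160, ppi_n_edges=600, seed=47,
                               planted_group_sizes={("down", 10): 20})
        terminals = gene_ids(400)[:20]
        ppi, _ = simulate_ppi(cfg, "MET", terminals)
        res = AnchoredNetworkModel(ppi, "MET", terminals).fit()
        assert len(res.pathways) >= 1
        # pruned: no pathway contains another contiguously
        for a, b in itertools.combinations(res.pathways, 2):
            long, short = (a, b) if len(a.nodes) > len(b.nodes) else (b, a)
            seq, sub = long.nodes, short.nodes
            contig = any(seq[i:i + len(sub)] in (sub, sub[::-1])
                         for i in range(len(seq) - len(sub) + 1))
            assert not contig
        assert "Anchored network inference" in res.summary()

    def test_end_to_end_attachments(self, small_config, small_model, planted_signature):
        from metkinsig import simulate_cohort

        matrix, _ = small_model
        terminals = sorted(planted_signature.genes)[:15]
        ppi, _ = simulate_ppi(small_config, "MET", terminals)
        res = AnchoredNetworkModel(ppi, "MET", terminals).fit()
        diff = res.attach_differentiation(matrix)
        coh = res.attach_coherency(matrix)
        cohorts = [simulate_cohort(small_config, planted_signature, name=f"c{k}",
                                   seed_offset=50 + k) for k in range(2)]
        prog = res.attach_prognosis(cohorts)
        table = res.pathway_table()
        assert len(diff) == len(res.pathways)
        assert coh.index.equals(table.index)
        assert prog.shape[1] == 2
        assert table["prognosis_rank"].notna().any()
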