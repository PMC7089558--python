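"""Correlation network estimation, thresholding, and layout."""

import math

import numpy as np
import pandas as pd
import pytest

import patnet as pn
from patnet.network import NetworkResults, _phi_pvalue, fruchterman_reingold

from .conftest import cohort_from_columns


def small_results(weights: dict, pvalues: dict | None = None) -> NetworkResults:
    """Hand-built 4-node network for thresholding unit tests.

    ``weights``/``pvalues`` map (i, j) pairs of 'a','b','c','d' to values.
    """
    ids = ["a", "b", "c", "d"]
    w = pd.DataFrame(np.nan, index=ids, columns=ids)
    p = pd.DataFrame(np.nan, index=ids, columns=ids)
    m = pd.DataFrame(100, index=ids, columns=ids)
    for (i, j), value in weights.items():
        w.at[i, j] = w.at[j, i] = value
        pv = (pvalues or {}).get((i, j), 0.001)
        p.at[i, j] = p.at[j, i] = pv
    retained = w.notna()
    np.fill_diagonal(retained.values, False)
    nodes = pd.DataFrame({"id": ids, "label": ids, "subscale": ["s"] * 4})
    return NetworkResults(
        level="item", nodes=nodes, weights=w, pvalues=p, pair_counts=m,
        retained=retained,
    )


class TestCorrelationMatrix:
    def test_phi_from_2x2_table(self, catalog):
        # a=30 both-risk, b=20, c=20, d=30 -> phi = (ad-bc)/sqrt(...) = 0.2
        x = [1] * 30 + [1] * 20 + [0] * 20 + [0] * 30
        y = [1] * 30 + [0] * 20 + [1] * 20 + [0] * 30
        cohort = cohort_from_columns(catalog, {"11a": x, "11b": y})
        results = pn.correlation_matrix(cohort, level="item")
        assert results.weights.at["11a", "11b"] == pytest.approx(0.2)
        assert results.pair_counts.at["11a", "11b"] == 100

    def test_identical_columns_correlate_perfectly(self, catalog):
        x = [0, 1] * 30
        cohort = cohort_from_columns(catalog, {"11a": x, "11b": x})
        results = pn.correlation_matrix(cohort, level="item")
        assert results.weights.at["11a", "11b"] == pytest.approx(1.0)
        assert results.pvalues.at["11a", "11b"] == 0.0

    def test_independent_columns_near_zero(self, catalog):
        rng = np.random.default_rng(0)
        cohort = cohort_from_columns(
            catalog,
            {"11a": rng.integers(0, 2, 10_000), "11b": rng.integers(0, 2, 10_000)},
        )
        r = pn.correlation_matrix(cohort).weights.at["11a", "11b"]
        assert abs(r) < 0.05

    def test_zero_variance_columns_excluded(self, catalog):
        cohort = cohort_from_columns(catalog, {"11a": [1.0] * 40})
        results = pn.correlation_matrix(cohort)
        assert "11a" in results.excluded
        assert "11a" not in results.node_ids
        assert len(results.node_ids) == 37

    def test_weights_invariant_to_row_order(self, all_cohort):
        results = pn.correlation_matrix(all_cohort)
        shuffled = pn.Cohort(
            frame=all_cohort.frame.sample(frac=1.0, random_state=1).reset_index(drop=True),
            catalog=all_cohort.catalog,
        )
        results2 = pn.correlation_matrix(shuffled)
        pd.testing.assert_frame_equal(results.weights, results2.weights)

    def test_split_half_consistency(self, big_all_cohort):
        """Networks from disjoint halves of one large cohort agree edgewise."""
        frame = big_all_cohort.frame
        halves = [
            pn.Cohort(frame.iloc[:5000].reset_index(drop=True), big_all_cohort.catalog),
            pn.Cohort(frame.iloc[5000:].reset_index(drop=True), big_all_cohort.catalog),
        ]
        w1 = pn.correlation_matrix(halves[0]).weights
        w2 = pn.correlation_matrix(halves[1]).weights
        common = w1.index.intersection(w2.index)
        diff = (w1.loc[common, common] - w2.loc[common, common]).abs().to_numpy()
        off = diff[np.triu_indices_from(diff, k=1)]
        assert np.nanmean(off) < 0.03
        assert np.nanmax(off) < 0.15

    def test_subscale_level_network_has_seven_nodes(self, all_cohort):
        results = pn.correlation_matrix(all_cohort, level="subscale")
        assert set(results.node_ids) <= set(pn.SUBSCALES)
        assert results.level == "subscale"

    def test_too_small_cohort_rejected(self, catalog):
        cohort = cohort_from_columns(catalog, {"11a": [0, 1]})
        with pytest.raises(ValueError):
            pn.correlation_matrix(cohort)

    def test_tetrachoric_exceeds_phi_in_magnitude(self, all_cohort):
        phi = pn.correlation_matrix(all_cohort, method="pearson")
        tet = pn.correlation_matrix(all_cohort, method="tetrachoric")
        pair = ("14a", "14b")  # within-subscale, strongly correlated
        assert abs(tet.weights.at[pair]) >= abs(phi.weights.at[pair]) - 0.02


class TestSignificanceThreshold:
    def test_small_correlation_dropped_at_population_scale(self):
        # r = 0.05 over m = 100 has p ~ 0.62 under the t transform
        assert _phi_pvalue(0.05, 100) == pytest.approx(0.622, abs=0.005)
        results = small_results({("a", "b"): 0.05, ("c", "d"): 0.9})
        results.pvalues.at["a", "b"] = results.pvalues.at["b", "a"] = _phi_pvalue(0.05, 100)
        out = results.threshold_significance(0.05)
        assert not out.retained.at["a", "b"]
        assert out.retained.at["c", "d"]
        # dropped edge keeps its weight as metadata
        assert out.weights.at["a", "b"] == pytest.approx(0.05)

    def test_vacuous_and_empty_thresholds(self):
        results = small_results({("a", "b"): 0.3, ("b", "c"): -0.4})
        assert results.threshold_significance(1.0).retained.to_numpy().sum() == 4
        assert results.threshold_significance(0.0).retained.to_numpy().sum() == 0

    def test_never_adds_edges_and_idempotent(self, all_cohort):
        results = pn.correlation_matrix(all_cohort)
        once = results.threshold_significance(0.05)
        twice = once.threshold_significance(0.05)
        assert (once.retained.to_numpy() <= results.retained.to_numpy()).all()
        assert (twice.retained.to_numpy() == once.retained.to_numpy()).all()


class TestProportionalThreshold:
    def test_keep_all_is_identity_on_edges(self):
        results = small_results({("a", "b"): 0.3, ("b", "c"): -0.4, ("c", "d"): 0.1})
        out = results.threshold_proportional(1.0)
        assert (out.retained.to_numpy() == results.retained.to_numpy()).all()

    def test_keeps_largest_absolute_weights(self):
        weights = {("a", "b"): 0.2, ("a", "c"): -0.8, ("a", "d"): 0.5,
                   ("b", "c"): 0.1, ("b", "d"): 0.3, ("c", "d"): 0.05}
        # 6 edges with distinct |w|; keep 2 of 6
        out = small_results(weights).threshold_proportional(2 / 6)
        kept = {
            tuple(r[["node_i", "node_j"]])
            for _, r in out.edges(retained_only=True).iterrows()
        }
        assert kept == {("a", "c"), ("a", "d")}

    def test_tie_broken_by_pair_order(self):
        # |w| = {0.9, 0.5, 0.5, 0.1}: keep 2 -> 0.9 plus the first 0.5
        weights = {("a", "b"): 0.9, ("a", "c"): 0.5, ("b", "c"): 0.5,
                   ("a", "d"): 0.1}
        out = small_results(weights).threshold_proportional(0.5)
        kept = {
            tuple(r[["node_i", "node_j"]])
            for _, r in out.edges(retained_only=True).iterrows()
        }
        assert kept == {("a", "b"), ("a", "c")}

    def test_bad_fraction_rejected(self):
        results = small_results({("a", "b"): 0.3})
        with pytest.raises(ValueError):
            results.threshold_proportional(0.0)
        with pytest.raises(ValueError):
            results.threshold_proportional(1.5)


class TestLayout:
    def test_single_node_at_origin(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("only")
        assert fruchterman_reingold(g, seed=1) == {"only": (0.0, 0.0)}

    def test_symmetric_triangle_is_equilateral(self):
        import networkx as nx

        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, abs_weight=1.0)
        pos = fruchterman_reingold(g, seed=3, iterations=500)
        pts = {k: np.array(v) for k, v in pos.items()}
        d = [np.linalg.norm(pts["a"] - pts["b"]),
             np.linalg.norm(pts["b"] - pts["c"]),
             np.linalg.norm(pts["a"] - pts["c"])]
        assert max(d) / min(d) < 1.05

    def test_two_blocks_separate(self):
        import networkx as nx

        g = nx.Graph()
        block1, block2 = ["a1", "a2", "a3"], ["b1", "b2", "b3"]
        for block in (block1, block2):
            for i, u in enumerate(block):
                for v in block[i + 1:]:
                    g.add_edge(u, v, abs_weight=1.0)
        g.add_edge("a1", "b1", abs_weight=0.05)
        pos = fruchterman_reingold(g, seed=0, iterations=500)
        pts = {k: np.array(v) for k, v in pos.items()}

        def mean_dist(pairs):
            return np.mean([np.linalg.norm(pts[u] - pts[v]) for u, v in pairs])

        within = [(u, v) for block in (block1, block2)
                  for i, u in enumerate(block) for v in block[i + 1:]]
        between = [(u, v) for u in block1 for v in block2]
        assert mean_dist(within) < mean_dist(between)

    def test_high_strength_nodes_near_centroid(self, all_cohort):
        results = pn.correlation_matrix(all_cohort).threshold_significance(0.05)
        pos = results.layout(seed=2, iterations=300)
        from patnet.metrics import centralities

        cent = centralities(results).set_index("id")
        pts = pd.DataFrame(pos, index=["x", "y"]).T
        centroid = pts.mean()
        dist = np.hypot(pts["x"] - centroid["x"], pts["y"] - centroid["y"])
        strength = cent.loc[dist.index, "strength"]
        top = dist[strength >= strength.quantile(0.75)]
        bottom = dist[strength <= strength.quantile(0.25)]
        assert top.mean() < bottom.mean()

    def test_deterministic_given_seed(self, all_cohort):
        results = pn.correlation_matrix(all_cohort).threshold_significance(0.05)
        assert results.layout(seed=5) == results.layout(seed=5)


def test_graphml_and_edge_csv_round_trip(tmp_path, all_cohort):
    import networkx as nx

    results = pn.correlation_matrix(all_cohort).threshold_significance(0.05)
    results.layout(seed=1, iterations=50)
    gml = tmp_path / "net.graphml"
    results.to_graphml(gml)
    g = nx.read_graphml(gml)
    assert g.number_of_nodes() == len(results.node_ids)
    assert g.number_of_edges() == len(results.edges(retained_only=True))
    csv_path = tmp_path / "edges.csv"
    results.to_edge_csv(csv_path)
    edges = pd.read_csv(csv_path, dtype={"node_i": str, "node_j": str})
    reread = edges.set_index(["node_i", "node_j"])
    original = results.edges().set_index(["node_i", "node_j"])
    assert reread["retained"].equals(original["retained"])
    np.testing.assert_allclose(reread["weight"], original["weight"])
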