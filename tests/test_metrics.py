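"""Graph measures against closed forms and brute-force oracles."""

import numpy as np
import pytest

import oracles
from conftest import complete_graph, cycle_graph, path_graph
from graphpm.connectome import WeightedGraph
from graphpm.metrics import (
    RoiMap,
    characteristic_path_length,
    distance_matrix,
    global_efficiency,
    mean_betweenness,
    mean_clustering,
    mean_local_efficiency,
    metric_vector,
    nodal_betweenness,
    nodal_clustering,
    nodal_local_efficiency,
)


def star_graph(leaves: int) -> WeightedGraph:
    n = leaves + 1
    w = np.zeros((n, n))
    w[0, 1:] = w[1:, 0] = 1.0
    return WeightedGraph(w)


class TestDistances:
    def test_unit_path_graph(self):
        g = path_graph(4)
        assert distance_matrix(g)[0, 3] == pytest.approx(3.0)

    def test_complete_graph_all_one(self):
        d = distance_matrix(complete_graph(5))
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(d[off], 1.0)

    def test_indirect_route_shorter(self):
        # lengths: 1-2 and 2-3 are 2 each, direct 1-3 is 5 -> go via 2
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        w[0, 2] = w[2, 0] = 0.2
        assert distance_matrix(WeightedGraph(w))[0, 2] == pytest.approx(4.0)


class TestClosedForms:
    """Complete unit-weight graph: every integration/segregation measure is
    1 and betweenness 0; empty graph: efficiencies 0."""

    def test_complete_graph_limits(self):
        g = complete_graph(5)
        assert global_efficiency(g) == pytest.approx(1.0)
        assert characteristic_path_length(g).value == pytest.approx(1.0)
        assert mean_clustering(g) == pytest.approx(1.0)
        assert mean_local_efficiency(g) == pytest.approx(1.0)
        np.testing.assert_allclose(nodal_betweenness(g), 0.0)

    def test_empty_graph_efficiency_zero(self):
        g = WeightedGraph(np.zeros((3, 3)))
        assert global_efficiency(g) == 0.0
        assert mean_clustering(g) == 0.0
        assert mean_local_efficiency(g) == 0.0
        with pytest.raises(ValueError):
            characteristic_path_length(g)

    def test_path_graph_efficiency(self):
        # ordered pairs of the 4-path: 2*(1+1+1+1/2+1/2+1/3)/12
        assert global_efficiency(path_graph(4)) == pytest.approx(13 / 18)

    def test_path_graph_cpl(self):
        assert characteristic_path_length(path_graph(4)).value == pytest.approx(10 / 6)

    def test_disconnected_cpl_flagged(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        res = characteristic_path_length(WeightedGraph(w))
        assert res.value == pytest.approx(1.0)
        assert not res.connected

    def test_weighted_triangle_clustering(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        w[1, 2] = w[2, 1] = 0.5
        c = nodal_clustering(WeightedGraph(w))
        assert c[0] == pytest.approx(0.5 ** (1 / 3), abs=1e-9)

    def test_star_graph_no_triangles(self):
        np.testing.assert_allclose(nodal_clustering(star_graph(3)), 0.0)

    def test_path_middle_node_local_efficiency_zero(self):
        assert nodal_local_efficiency(path_graph(3))[1] == 0.0

    def test_cycle_local_efficiency_zero(self):
        np.testing.assert_allclose(nodal_local_efficiency(cycle_graph(4)), 0.0)

    def test_path_betweenness(self):
        b = nodal_betweenness(path_graph(3))
        np.testing.assert_allclose(b, [0.0, 0.5, 0.0])

    def test_cycle_tie_splitting(self):
        np.testing.assert_allclose(nodal_betweenness(cycle_graph(4)), 0.5 / 6)


class TestMetricVector:
    def test_complete_graph_with_roi(self):
        mv = metric_vector(complete_graph(4), RoiMap({"L_ACC": [0]}), "s", "task")
        v = mv.values
        assert v["global_efficiency"] == pytest.approx(1.0)
        assert v["characteristic_path_length"] == pytest.approx(1.0)
        assert v["mean_clustering"] == pytest.approx(1.0)
        assert v["mean_local_efficiency"] == pytest.approx(1.0)
        assert v["mean_betweenness"] == pytest.approx(0.0)
        assert v["L_ACC:clustering"] == pytest.approx(1.0)
        assert v["L_ACC:local_efficiency"] == pytest.approx(1.0)
        assert v["L_ACC:betweenness"] == pytest.approx(0.0)

    def test_empty_graph_records_missing_path_length(self):
        mv = metric_vector(WeightedGraph(np.zeros((4, 4))))
        assert np.isnan(mv.values["characteristic_path_length"])
        assert not mv.connected
        assert mv.values["global_efficiency"] == 0.0

    def test_multi_node_roi_averaged(self, rng):
        w = oracles.random_weighted_graph(rng, 6, density=0.8)
        g = WeightedGraph(w)
        mv = metric_vector(g, RoiMap({"both": [1, 3]}))
        clu = nodal_clustering(g)
        assert mv.values["both:clustering"] == pytest.approx((clu[1] + clu[3]) / 2)

    def test_roi_index_out_of_range_raises(self):
        with pytest.raises(ValueError, match="references node"):
            metric_vector(complete_graph(3), RoiMap({"x": [5]}))

    def test_random_graph_matches_oracle_suite(self, rng):
        w = oracles.random_weighted_graph(rng, 8, density=0.6)
        g = WeightedGraph(w)
        mv = metric_vector(g, RoiMap({"r0": [0], "r5": [5]}))
        assert mv.values["global_efficiency"] == pytest.approx(
            oracles.global_efficiency(w), abs=1e-9
        )
        assert mv.values["r0:betweenness"] == pytest.approx(
            oracles.nodal_betweenness(w)[0], abs=1e-9
        )


class TestOracleEquivalence:
    """Production metrics agree with independent brute force on hundreds of
    random small graphs (the core correctness guarantee)."""

    @pytest.mark.parametrize("seed", range(4))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        for _ in range(50):
            n = int(rng.integers(4, 9))
            w = oracles.random_weighted_graph(rng, n, density=float(rng.uniform(0.3, 0.9)))
            g = WeightedGraph(w)
            np.testing.assert_allclose(g.d, oracles.floyd_warshall(w), atol=1e-9)
            assert global_efficiency(g) == pytest.approx(
                oracles.global_efficiency(w), abs=1e-9
            )
            np.testing.assert_allclose(
                nodal_clustering(g), oracles.nodal_clustering(w), atol=1e-9
            )
            np.testing.assert_allclose(
                nodal_local_efficiency(g), oracles.nodal_local_efficiency(w), atol=1e-9
            )
            np.testing.assert_allclose(
                nodal_betweenness(g), oracles.nodal_betweenness(w), atol=1e-9
            )
            try:
                cpl, _ = oracles.characteristic_path_length(w)
                assert characteristic_path_length(g).value == pytest.approx(cpl, abs=1e-9)
            except ValueError:
                with pytest.raises(ValueError):
                    characteristic_path_length(g)


class TestScaleAndMonotonicity:
    def test_weight_scaling_behaviour(self, rng):
        w = oracles.random_weighted_graph(rng, 7, density=0.7)
        g1, g5 = WeightedGraph(w), WeightedGraph(5.0 * w)
        assert global_efficiency(g5) == pytest.approx(5 * global_efficiency(g1))
        assert characteristic_path_length(g5).value == pytest.approx(
            characteristic_path_length(g1).value / 5
        )
        np.testing.assert_allclose(nodal_clustering(g5), nodal_clustering(g1), atol=1e-12)
        np.testing.assert_allclose(nodal_betweenness(g5), nodal_betweenness(g1), atol=1e-12)

    def test_adding_edge_never_decreases_efficiency(self, rng):
        for _ in range(10):
            w = oracles.random_weighted_graph(rng, 6, density=0.4)
            g = WeightedGraph(w)
            zeros = [(i, j) for i in range(6) for j in range(i + 1, 6) if w[i, j] == 0]
            if not zeros:
                continue
            i, j = zeros[int(rng.integers(len(zeros)))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
            assert global_efficiency(WeightedGraph(w2)) >= global_efficiency(g) - 1e-12

    def test_means_equal_average_of_nodal_values(self, rng):
        w = oracles.random_weighted_graph(rng, 7, density=0.6)
        g = WeightedGraph(w)
        assert mean_clustering(g) == pytest.approx(nodal_clustering(g).mean())
        assert mean_local_efficiency(g) == pytest.approx(nodal_local_efficiency(g).mean())
        assert mean_betweenness(g) == pytest.approx(nodal_betweenness(g).mean())
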