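import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_graph
from oracles import bf_ranksum_exact_p
from swallownet.construction import Network, sweep_grid
from swallownet.stats import SWEEP_METRICS, compare_scopes, metric_sweep, ranksum, subgraph


def _net(seed=0, n=10, p=0.5):
    return Network(random_graph(np.random.default_rng(seed), n, weighted=False, p=p), "binary")


class TestSubgraph:
    def test_full_node_set_is_identity(self):
        net = _net(1)
        sub = subgraph(net, range(10))
        np.testing.assert_array_equal(sub.adjacency, net.adjacency)

    def test_two_connected_nodes(self):
        adj = np.zeros((4, 4))
        adj[0, 2] = adj[2, 0] = 1
        sub = subgraph(Network(adj, "binary"), [0, 2])
        assert sub.n_edges == 1

    def test_labels_follow_selection(self):
        net = Network(np.zeros((3, 3)), "binary", labels=("a", "b", "c"))
        assert subgraph(net, [0, 2]).labels == ("a", "c")

    def test_bad_nodes_rejected(self):
        net = _net(2)
        with pytest.raises(ValueError):
            subgraph(net, [0, 99])
        with pytest.raises(ValueError):
            subgraph(net, [3])

    def test_swallowing_set_size_on_study_shaped_network(self):
        from swallownet.atlas import swallowing_nodes

        net = _net(3, n=90, p=0.3)
        sub = subgraph(net, swallowing_nodes())
        assert sub.n_nodes == 42


class TestRanksum:
    def test_fully_separated_samples_exact_p(self):
        res = ranksum([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_samples_degenerate(self):
        res = ranksum([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and res.p_two_sided == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 7, size=2)
        a = rng.standard_normal(n1)
        b = rng.standard_normal(n2) + rng.uniform(-1, 1)
        res = ranksum(a, b)
        assert res.p_two_sided == pytest.approx(bf_ranksum_exact_p(a, b), abs=1e-12)

    @given(st.data())
    def test_symmetry_under_sample_swap(self, data):
        a = data.draw(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=8))
        b = data.draw(st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=8))
        r_ab = ranksum(a, b)
        r_ba = ranksum(b, a)
        assert r_ab.U + r_ba.U == pytest.approx(len(a) * len(b))
        assert r_ab.p_two_sided == pytest.approx(r_ba.p_two_sided, rel=1e-9)

    def test_large_sample_normal_approximation_with_ties(self):
        rng = np.random.default_rng(1)
        a = np.round(rng.standard_normal(30), 1)
        b = np.round(rng.standard_normal(30) + 1.0, 1)
        res = ranksum(a, b)
        assert res.p_two_sided < 0.01
        assert res.z < 0  # first sample shifted down

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ranksum([], [1.0])


class TestMetricSweep:
    def _matrices(self, n_sub=3, n=12, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_sub):
            M = rng.uniform(-1, 1, (n, n))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            out.append(M)
        return out

    def test_table_dimensions(self):
        grid = sweep_grid()
        sweep = metric_sweep(self._matrices(), "whole_brain", grid)
        assert len(sweep.table) == 3 * 21
        assert set(SWEEP_METRICS) <= set(sweep.table.columns)

    def test_empty_network_conventions_at_unit_threshold(self):
        grid = np.array([1.0])
        sweep = metric_sweep(self._matrices(), "whole_brain", grid)
        row = sweep.table.iloc[0]
        assert row["K_mean"] == 0 and row["Cp"] == 0 and row["Eglob"] == 0

    def test_roi_scope_extracts_before_thresholding(self):
        mats = self._matrices()
        roi = [0, 1, 2, 3, 4]
        sweep = metric_sweep(mats, "swallowing_roi", np.array([0.0]), roi_nodes=roi)
        # K_mean at r=0 equals that of the ROI submatrix's dense graph
        sub = mats[0][np.ix_(roi, roi)]
        expected = (np.abs(sub) > 0).sum() / 5
        assert sweep.table.iloc[0]["K_mean"] == pytest.approx(expected)

    def test_roi_scope_requires_nodes(self):
        with pytest.raises(ValueError):
            metric_sweep(self._matrices(), "swallowing_roi", np.array([0.0]))

    def test_bad_grid_rejected(self):
        with pytest.raises(ValueError):
            metric_sweep(self._matrices(), "whole_brain", np.array([0.5, 0.2]))


class TestCompareScopes:
    def test_identical_scopes_never_significant(self):
        mats = TestMetricSweep()._matrices(n_sub=5)
        grid = np.array([0.1, 0.3, 0.5])
        sweep = metric_sweep(mats, "whole_brain", grid)
        roi_sweep = metric_sweep(mats, "swallowing_roi", grid, roi_nodes=range(12))
        result = compare_scopes(roi_sweep, sweep)
        assert len(result) == 3 * len(SWEEP_METRICS)
        valid = result.dropna(subset=["p"])
        assert (valid["p"] > 0.9).all()

    def test_planted_denser_roi_detected(self):
        rng = np.random.default_rng(6)
        mats = []
        roi = list(range(6))
        for _ in range(8):
            M = rng.uniform(-0.3, 0.3, (16, 16))
            M = (M + M.T) / 2
            # dense strongly-connected ROI block
            block = rng.uniform(0.7, 0.95, (6, 6))
            M[:6, :6] = (block + block.T) / 2
            np.fill_diagonal(M, 0)
            mats.append(M)
        grid = np.array([0.5])
        sweep_roi = metric_sweep(mats, "swallowing_roi", grid, roi_nodes=roi)
        sweep_whole = metric_sweep(mats, "whole_brain", grid)
        result = compare_scopes(sweep_roi, sweep_whole)
        cp = result[result["metric"] == "Cp"].iloc[0]
        assert cp["significant"] and cp["p"] < 0.05
        # ROI clustering exceeds whole-brain clustering at this threshold
        assert sweep_roi.table["Cp"].mean() > sweep_whole.table["Cp"].mean()

    def test_subject_order_invariance(self):
        mats = TestMetricSweep()._matrices(n_sub=4, seed=2)
        grid = np.array([0.2, 0.4])
        whole = metric_sweep(mats, "whole_brain", grid)
        roi = metric_sweep(mats, "swallowing_roi", grid, roi_nodes=range(5))
        shuffled = metric_sweep(mats[::-1], "swallowing_roi", grid, roi_nodes=range(5))
        r1 = compare_scopes(roi, whole)
        r2 = compare_scopes(shuffled, whole)
        np.testing.assert_allclose(r1["p"].to_numpy(), r2["p"].to_numpy(), atol=1e-12)

    def test_grid_mismatch_rejected(self):
        mats = TestMetricSweep()._matrices()
        s1 = metric_sweep(mats, "whole_brain", np.array([0.1]))
        s2 = metric_sweep(mats, "whole_brain", np.array([0.2]))
        with pytest.raises(ValueError):
            compare_scopes(s1, s2)
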