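"""Correlation matrices, SPM construction and the sliding-window variant."""
import itertools

import networkx as nx
import numpy as np
import pytest

from allostate import network as net
from allostate.network import (CorrelationMatrix, contact_adjacency,
                               correlation_matrix, spm, spm_windows,
                               subunit_counts, te_spm)
from allostate import synthdata as sd

from conftest import make_trajectory


def _corr(values, residues=None):
    values = np.asarray(values, dtype=float)
    n = len(values)
    residues = residues or [("A", str(i + 1)) for i in range(n)]
    return CorrelationMatrix(residues=residues, values=values)


class TestCorrelationMatrix:
    def _traj_from_displacements(self, disp, base_spacing=50.0):
        """Residues far apart so superposition barely couples them."""
        n_frames, n_res, _ = disp.shape
        base = np.zeros((n_res, 3))
        base[:, 0] = np.arange(n_res) * base_spacing
        return make_trajectory(base[None] + disp)

    def test_copied_displacements_fully_correlated(self, rng):
        disp_i = rng.normal(size=(200, 1, 3))
        other = rng.normal(size=(200, 2, 3))
        disp = np.concatenate([disp_i, disp_i, other], axis=1)
        traj = self._traj_from_displacements(disp)
        corr = correlation_matrix(traj, selection=list(range(4)), align=False)
        assert corr.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_displacements_anticorrelated(self, rng):
        disp_i = rng.normal(size=(200, 1, 3))
        other = rng.normal(size=(200, 1, 3))
        disp = np.concatenate([disp_i, -disp_i, other], axis=1)
        traj = self._traj_from_displacements(disp)
        corr = correlation_matrix(traj, selection=list(range(3)), align=False)
        assert corr.values[0, 1] == pytest.approx(-1.0, abs=1e-9)

    def test_symmetric_unit_diagonal_psd(self, rng):
        ens = sd.planted_ensemble(sd.PlantedNetworkSpec(seed=5, n_frames=500))
        corr = correlation_matrix(ens)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(corr.values).min() > -1e-8

    def test_planted_correlation_recovered(self):
        """Raw displacement correlations recover the planted target.

        align=False: the generator has no rigid-body drift by construction,
        and superposition deliberately removes collective motion, which the
        planted path is."""
        spec = sd.PlantedNetworkSpec(seed=3)
        ens = sd.planted_ensemble(spec)
        corr = correlation_matrix(ens, align=False)
        path = spec.planted_path()
        for i, j in zip(path[:-1], path[1:]):
            assert corr.values[i, j] == pytest.approx(spec.rho_path,
                                                      abs=0.05)

    def test_zero_variance_residue_raises_unless_masked(self, rng):
        disp = rng.normal(size=(100, 3, 3))
        disp[:, 1] = 0.0
        traj = self._traj_from_displacements(disp)
        with pytest.raises(ValueError, match="zero-variance"):
            correlation_matrix(traj, selection=[0, 1, 2], align=False)
        corr = correlation_matrix(traj, selection=[0, 1, 2], align=False,
                                  mask_zero_variance=True)
        assert np.isnan(corr.values[1, 0])
        assert corr.values[0, 2] == corr.values[0, 2]  # others defined

    def test_too_few_frames_raises(self):
        traj = make_trajectory(np.zeros((5, 4, 3)))
        with pytest.raises(ValueError, match="10 frames"):
            correlation_matrix(traj, selection=[0, 1])


class TestContactAdjacency:
    def test_cutoff_thresholds_mean_distance(self):
        frames = np.zeros((20, 2, 3))
        frames[:, 1, 0] = 4.0
        traj = make_trajectory(frames)
        assert contact_adjacency(traj, [0, 1], cutoff=6.0)[0, 1]
        assert not contact_adjacency(traj, [0, 1], cutoff=3.0)[0, 1]

    def test_no_self_edges(self):
        traj = make_trajectory(np.zeros((12, 3, 3)))
        adj = contact_adjacency(traj, [0, 1, 2], cutoff=5.0)
        assert not adj.diagonal().any()

    def test_matches_mean_distance_oracle(self, rng):
        frames = rng.normal(size=(30, 20, 3)) * 4
        traj = make_trajectory(frames)
        cutoff = 5.0
        adj = contact_adjacency(traj, list(range(20)), cutoff=cutoff)
        for i in range(20):
            for j in range(20):
                if i == j:
                    continue
                mean_d = np.mean([np.linalg.norm(f[i] - f[j])
                                  for f in frames])
                assert adj[i, j] == (mean_d < cutoff)


def _spm_usage_oracle(corr_values, adjacency):
    """Exhaustive oracle: enumerate all simple paths per pair, find the
    minimum-total-weight path, accumulate its edges."""
    n = len(corr_values)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    weights = -np.log(np.clip(np.abs(corr_values), 1e-12, 1.0))
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j]:
                g.add_edge(i, j, weight=float(weights[i, j]))
    usage = {tuple(sorted(e)): 0 for e in g.edges}
    for s, t in itertools.combinations(range(n), 2):
        best_cost, best_path = np.inf, None
        try:
            paths = nx.all_simple_paths(g, s, t)
        except nx.NodeNotFound:
            continue
        for path in paths:
            cost = sum(g[u][v]["weight"] for u, v in zip(path, path[1:]))
            if cost < best_cost - 1e-12:
                best_cost, best_path = cost, path
        if best_path is not None:
            for u, v in zip(best_path, best_path[1:]):
                usage[tuple(sorted((u, v)))] += 1
    return usage


class TestSpm:
    def test_three_node_chain_hand_enumeration(self):
        corr = _corr([[1.0, 0.9, 0.5],
                      [0.9, 1.0, 0.9],
                      [0.5, 0.9, 1.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        res = spm(corr, adj)
        # pairs: AB uses AB; BC uses BC; AC goes through B
        assert res.edges[(0, 1)]["usage"] == 2
        assert res.edges[(1, 2)]["usage"] == 2
        assert (0, 2) not in res.edges
        assert res.edges[(0, 1)]["width"] == 1.0

    def test_perfect_correlation_zero_weight_preferred(self):
        # direct edge 0-2 has weight -log 0.5; detour via 1 is free
        corr = _corr([[1.0, 1.0, 0.5],
                      [1.0, 1.0, 1.0],
                      [0.5, 1.0, 1.0]])
        adj = ~np.eye(3, dtype=bool)
        res = spm(corr, adj)
        assert res.edges[(0, 1)]["weight"] == 0.0
        assert res.edges[(0, 1)]["usage"] == 2   # pairs (0,1) and (0,2)
        assert res.edges[(0, 2)]["usage"] == 0

    def test_matches_exhaustive_oracle_on_random_graphs(self, rng):
        for trial in range(30):
            n = int(rng.integers(4, 9))
            values = rng.uniform(0.05, 0.95, size=(n, n))
            values = (values + values.T) / 2
            np.fill_diagonal(values, 1.0)
            adj = rng.uniform(size=(n, n)) < 0.5
            adj = adj | adj.T
            np.fill_diagonal(adj, False)
            corr = _corr(values)
            res = spm(corr, adj)
            oracle = _spm_usage_oracle(values, adj)
            ours = {e: rec["usage"] for e, rec in res.edges.items()}
            assert ours == oracle

    def test_invariant_under_residue_relabelling(self, rng):
        n = 7
        values = rng.uniform(0.1, 0.9, size=(n, n))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        adj = rng.uniform(size=(n, n)) < 0.6
        adj = adj | adj.T
        np.fill_diagonal(adj, False)
        perm = rng.permutation(n)
        res = spm(_corr(values), adj)
        res_p = spm(_corr(values[np.ix_(perm, perm)]), adj[np.ix_(perm, perm)])
        inv = np.argsort(perm)
        for (i, j), rec in res.edges.items():
            pi, pj = inv[i], inv[j]
            key = (pi, pj) if pi < pj else (pj, pi)
            assert res_p.edges[key]["usage"] == rec["usage"]

    def test_disconnected_graph_warns_with_component_count(self, caplog):
        corr = _corr(np.eye(4) * 0.0 + np.eye(4))
        adj = np.zeros((4, 4), dtype=bool)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
        with caplog.at_level("WARNING"):
            res = spm(corr, adj)
        assert res.n_components == 2
        assert any("2 components" in r.message for r in caplog.records)

    def test_node_importance_sums_included_widths(self):
        corr = _corr([[1.0, 0.9, 0.5],
                      [0.9, 1.0, 0.9],
                      [0.5, 0.9, 1.0]])
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
        res = spm(corr, adj, threshold=0.3)
        assert res.node_importance[1] == pytest.approx(2.0)
        assert res.node_importance[0] == pytest.approx(1.0)


class TestTeSpm:
    def test_window_bookkeeping_1200_600_300(self):
        windows = spm_windows(1200.0, 600.0, 300.0)
        assert windows == [(0.0, 600.0), (300.0, 900.0), (600.0, 1200.0)]

    def test_window_longer_than_span_raises(self):
        with pytest.raises(ValueError, match="longer than"):
            spm_windows(500.0, 600.0, 300.0)

    def test_window_equal_to_span_equals_global_spm(self):
        ens = sd.planted_ensemble(sd.PlantedNetworkSpec(seed=2, n_frames=300))
        span = ens.span_ns
        series = te_spm(ens, window_ns=span, stride_ns=span)
        assert len(series) == 1
        corr = correlation_matrix(ens)
        adj = contact_adjacency(ens)
        global_res = spm(corr, adj)
        windowed = series.results[0]
        assert {e: r["usage"] for e, r in windowed.edges.items()} \
            == {e: r["usage"] for e, r in global_res.edges.items()}

    def test_planted_path_switched_on_halfway(self):
        """Planted edges dominate only in windows overlapping the hot half."""
        null_spec = sd.PlantedNetworkSpec(seed=7, n_frames=1000,
                                          rho_path=0.1)
        hot_spec = sd.PlantedNetworkSpec(seed=8, n_frames=1000)
        cold = sd.planted_ensemble(null_spec)
        hot = sd.planted_ensemble(hot_spec)
        frames = np.concatenate([cold.frames, hot.frames])
        ens = sd.TrajectoryEnsemble(
            frames=frames, times=np.arange(2000, dtype=float),
            topology=cold.topology)
        series = te_spm(ens, window_ns=999.0, stride_ns=999.0)
        assert len(series) == 2
        path = hot_spec.planted_path()
        pedges = set(tuple(sorted(e)) for e in zip(path[:-1], path[1:]))
        first = set(series.results[0].top_edges(len(path)))
        second = set(series.results[1].top_edges(len(path)))
        assert pedges <= second
        assert not pedges <= first


class TestSubunitCounts:
    def _result(self, residues, included_pairs):
        res = net.SPMResult(residues=residues, threshold=0.5)
        res.node_importance = np.zeros(len(residues))
        for k, (i, j) in enumerate(included_pairs):
            res.edges[(i, j)] = {"weight": 0.1, "usage": 10, "width": 1.0}
        return res

    def test_counts_per_subunit(self):
        residues = ([("A", str(i)) for i in range(1, 5)]
                    + [("B", str(i)) for i in range(1, 4)])
        # 3 HisF (chain A) + 2 HisH (chain B) nodes carry included edges
        res = self._result(residues, [(0, 1), (1, 2), (4, 5)])
        counts = subunit_counts(res, {"A": "HisF", "B": "HisH"})
        assert counts == {"HisF": 3, "HisH": 2}

    def test_all_in_one_subunit(self):
        residues = [("A", "1"), ("A", "2"), ("B", "1")]
        res = self._result(residues, [(0, 1)])
        counts = subunit_counts(res, {"A": "HisF", "B": "HisH"})
        assert counts == {"HisF": 2, "HisH": 0}

    def test_counts_sum_equals_included_nodes(self, rng):
        ens = sd.planted_ensemble(sd.PlantedNetworkSpec(seed=1, n_frames=400))
        res = spm(correlation_matrix(ens), contact_adjacency(ens))
        counts = subunit_counts(res, ens.topology.subunit_map)
        assert sum(counts.values()) == len(res.included_nodes())

    def test_untagged_chain_raises(self):
        res = self._result([("A", "1"), ("C", "2")], [(0, 1)])
        with pytest.raises(ValueError, match="subunit"):
            subunit_counts(res, {"A": "HisF"})


def test_graph_export_round_trip(tmp_path):
    ens = sd.planted_ensemble(sd.PlantedNetworkSpec(seed=4, n_frames=300))
    res = spm(correlation_matrix(ens), contact_adjacency(ens))
    gml = tmp_path / "spm.graphml"
    csv = tmp_path / "spm.csv"
    net.write_graphml(res, gml)
    net.write_edgelist_csv(res, csv)
    back = nx.read_graphml(gml)
    assert back.number_of_edges() == len(res.edges)
    import pandas as pd

    frame = pd.read_csv(csv)
    assert len(frame) == len(res.edges)
    assert set(frame.columns) >= {"residue_i", "residue_j", "weight",
                                  "usage", "width", "included"}
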