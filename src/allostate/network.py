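"""Dynamic cross-correlation networks and the shortest path map (SPM).

The SPM highlights allosteric communication pathways in a protein: every
Cα–Cα contact (mean distance below a cutoff) becomes a graph edge weighted
by -log|C_ij|, where C_ij is the normalized dot-product correlation of the
residues' displacement vectors around the superposed mean structure.
Highly correlated contacts are "short"; the shortest paths between all
residue pairs therefore concentrate on strongly correlated routes.  Each
edge's usage count across all pairs, normalized to the most-used edge, is
its width; edges above an inclusion threshold constitute the map.

The time-evolution variant (te-SPM) recomputes the map in overlapping time
windows (e.g. a 600 ns window advanced by 300 ns) to follow how the
communication network reorganizes along an activation trajectory.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .trajio import StructureModel, TrajectoryEnsemble

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "SPMResult",
    "TeSPMSeries",
    "correlation_matrix",
    "contact_adjacency",
    "spm",
    "te_spm",
    "subunit_counts",
    "spm_to_networkx",
    "write_graphml",
    "write_edgelist_csv",
    "ca_indices",
]


def ca_indices(model: StructureModel) -> tuple[list[int], list[tuple[str, str]]]:
    """All Cα atom indices with their (chain, resid) residue tags."""
    idx, residues = [], []
    for i, a in enumerate(model.atoms):
        if a.name == "CA":
            idx.append(i)
            residues.append((a.chain, a.resid))
    return idx, residues


@dataclass
class CorrelationMatrix:
    """Residue displacement cross-correlation, values in [-1, 1]."""

    residues: list[tuple[str, str]]          # (chain, resid)
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residues)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.residues)


def _superpose(coords: np.ndarray, tol: float = 1e-6,
               max_iter: int = 50) -> np.ndarray:
    """Iteratively least-squares superpose frames onto their mean structure.

    Kabsch rotations for all frames are computed in one batched SVD.
    """
    coords = coords - coords.mean(axis=1, keepdims=True)
    mean = coords[0].copy()
    for _ in range(max_iter):
        h = np.einsum("kni,nj->kij", coords, mean)
        u, _s, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("kij,kjl->kil",
                                      np.transpose(vt, (0, 2, 1)),
                                      np.transpose(u, (0, 2, 1))))
        corr = np.repeat(np.eye(3)[None], len(coords), axis=0)
        corr[:, 2, 2] = det
        rot = np.einsum("kij,kjl,klm->kim",
                        np.transpose(vt, (0, 2, 1)), corr,
                        np.transpose(u, (0, 2, 1)))
        aligned = np.einsum("kni,kji->knj", coords, rot)
        new_mean = aligned.mean(axis=0)
        shift = float(np.abs(new_mean - mean).max())
        coords = aligned
        mean = new_mean
        if shift < tol:
            break
    return coords


def correlation_matrix(
    traj: TrajectoryEnsemble,
    selection: list[int] | None = None,
    residues: list[tuple[str, str]] | None = None,
    align: bool = True,
    mask_zero_variance: bool = False,
) -> CorrelationMatrix:
    """Pearson dot-product correlation of per-residue displacement vectors.

    Frames are least-squares superposed onto the iteratively refined mean
    structure first (removes rigid-body drift which would otherwise inflate
    correlations), then C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²><|Δr_j|²>)
    with Δr the displacement from the mean position.

    A residue with zero displacement variance has no defined correlation:
    this raises unless ``mask_zero_variance``, in which case its row and
    column are NaN.
    """
    if traj.n_frames < 10:
        raise ValueError("need at least 10 frames for a correlation matrix")
    if selection is None:
        selection, auto_res = ca_indices(traj.topology)
        residues = residues or auto_res
    if residues is None:
        residues = [(traj.topology.atoms[i].chain, traj.topology.atoms[i].resid)
                    for i in selection]
    if len(selection) < 2:
        raise ValueError("need at least 2 residues")
    coords = traj.frames[:, selection, :]
    if align:
        coords = _superpose(coords)
    delta = coords - coords.mean(axis=0)
    cov = np.einsum("kid,kjd->ij", delta, delta) / len(delta)
    var = np.diag(cov).copy()
    zero = var <= 1e-14
    if zero.any() and not mask_zero_variance:
        bad = [residues[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero-variance residues {bad}; pass "
                         "mask_zero_variance=True to mask them")
    var[zero] = 1.0
    c = cov / np.sqrt(np.outer(var, var))
    c[zero, :] = np.nan
    c[:, zero] = np.nan
    np.fill_diagonal(c, np.where(zero, np.nan, 1.0))
    c = np.clip(c, -1.0, 1.0, out=c)
    return CorrelationMatrix(residues=list(residues), values=c)


def contact_adjacency(
    traj: TrajectoryEnsemble,
    selection: list[int] | None = None,
    cutoff: float = 6.0,
) -> np.ndarray:
    """Boolean adjacency: mean Cα–Cα distance over frames below cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if selection is None:
        selection, _ = ca_indices(traj.topology)
    coords = traj.frames[:, selection, :]
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    mean_d = np.linalg.norm(diff, axis=-1).mean(axis=0)
    adj = mean_d < cutoff
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class SPMResult:
    """The shortest path map: per-edge usage widths and node importances."""

    residues: list[tuple[str, str]]
    edges: dict[tuple[int, int], dict] = field(default_factory=dict)
    # edge record keys: weight, usage, width
    threshold: float = 0.3
    node_importance: np.ndarray = None
    n_components: int = 1
    degenerate_pairs: int = 0        # pairs with equal-weight alternate paths

    def included_edges(self) -> list[tuple[int, int]]:
        return [e for e, rec in self.edges.items()
                if rec["width"] >= self.threshold]

    def included_nodes(self) -> set[int]:
        nodes: set[int] = set()
        for i, j in self.included_edges():
            nodes.update((i, j))
        return nodes

    def top_edges(self, k: int) -> list[tuple[int, int]]:
        """The k widest edges (deterministic index tie-break)."""
        ranked = sorted(self.edges.items(),
                        key=lambda kv: (-kv[1]["width"], kv[0]))
        return [e for e, _ in ranked[:k]]


def _dijkstra_tree(n: int, adj_list: list[list[tuple[int, float]]],
                   source: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Shortest-path tree with deterministic lowest-index-predecessor ties.

    Returns (dist, predecessor, n_degenerate) where n_degenerate counts
    nodes reachable by an equal-cost path through a different predecessor.
    """
    dist = np.full(n, np.inf)
    pred = np.full(n, -1, dtype=int)
    dist[source] = 0.0
    done = np.zeros(n, dtype=bool)
    n_degenerate = 0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if done[u] or d > dist[u] + 1e-15:
            continue
        done[u] = True
        if u != source:
            # predecessor fixed at finalization: lowest-index already-
            # finalized neighbour on a shortest path.  Because the
            # predecessor finalized earlier, the tree cannot cycle even
            # through zero-weight (|C| = 1) edges.
            cands = [v for v, w in adj_list[u]
                     if done[v] and abs(dist[v] + w - d) <= 1e-12]
            pred[u] = min(cands)
            if len(cands) > 1:
                n_degenerate += 1
        for v, w in adj_list[u]:
            nd = d + w
            if nd < dist[v] - 1e-15:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist, pred, n_degenerate


def spm(corr: CorrelationMatrix, adjacency: np.ndarray,
        threshold: float = 0.3) -> SPMResult:
    """Build the shortest path map from correlations and contacts.

    Edge weight d_ij = -log|C_ij| (|C| clamped to [1e-12, 1]) on contact
    edges.  For every residue pair the Dijkstra shortest path is walked and
    each traversed edge's usage incremented; widths are usages normalized
    to the maximum.  Node importance is the sum of incident included-edge
    widths.  Pairs in different connected components contribute nothing
    (a warning reports the component count).
    """
    n = corr.n
    adjacency = np.asarray(adjacency, dtype=bool)
    if adjacency.shape != (n, n):
        raise ValueError("adjacency shape does not match correlation matrix")

    absc = np.abs(corr.values)
    absc = np.clip(np.nan_to_num(absc, nan=0.0), 1e-12, 1.0)
    weights = -np.log(absc)

    edges: dict[tuple[int, int], dict] = {}
    adj_list: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if adjacency[i, j] or adjacency[j, i]:
                w = float(weights[i, j])
                edges[(i, j)] = {"weight": w, "usage": 0, "width": 0.0}
                adj_list[i].append((j, w))
                adj_list[j].append((i, w))

    degenerate_pairs = 0
    unreachable = False
    for s in range(n):
        dist, pred, n_deg = _dijkstra_tree(n, adj_list, s)
        degenerate_pairs += n_deg
        for t in range(s + 1, n):
            if not np.isfinite(dist[t]):
                unreachable = True
                continue
            v = t
            while v != s:
                u = int(pred[v])
                key = (u, v) if u < v else (v, u)
                edges[key]["usage"] += 1
                v = u
    if unreachable:
        comp = _component_count(n, adj_list)
        log.warning("contact graph is disconnected (%d components); "
                    "pairs without a path contribute nothing", comp)
        n_components = comp
    else:
        n_components = 1

    max_usage = max((rec["usage"] for rec in edges.values()), default=0)
    if max_usage > 0:
        for rec in edges.values():
            rec["width"] = rec["usage"] / max_usage
    importance = np.zeros(n)
    for (i, j), rec in edges.items():
        if rec["width"] >= threshold:
            importance[i] += rec["width"]
            importance[j] += rec["width"]
    return SPMResult(residues=list(corr.residues), edges=edges,
                     threshold=threshold, node_importance=importance,
                     n_components=n_components,
                     degenerate_pairs=degenerate_pairs)


def _component_count(n: int, adj_list) -> int:
    seen = np.zeros(n, dtype=bool)
    comps = 0
    for s in range(n):
        if seen[s]:
            continue
        comps += 1
        stack = [s]
        seen[s] = True
        while stack:
            u = stack.pop()
            for v, _w in adj_list[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
    return comps


@dataclass
class TeSPMSeries:
    """One SPM per sliding time window, with per-window subunit counts."""

    windows: list[tuple[float, float]]       # (start ns, end ns)
    results: list[SPMResult]
    counts: list[dict[str, int]]

    def __len__(self) -> int:
        return len(self.windows)


def spm_windows(span_ns: float, window_ns: float,
                stride_ns: float) -> list[tuple[float, float]]:
    """Window bookkeeping: [k·stride, k·stride + window] while end <= span."""
    if stride_ns <= 0:
        raise ValueError("stride must be positive")
    if window_ns > span_ns:
        raise ValueError(
            f"window ({window_ns} ns) longer than trajectory span "
            f"({span_ns} ns)")
    windows = []
    k = 0
    while True:
        start = k * stride_ns
        end = start + window_ns
        if end > span_ns + 1e-9:
            break
        windows.append((start, end))
        k += 1
    return windows


def te_spm(
    traj: TrajectoryEnsemble,
    window_ns: float,
    stride_ns: float,
    selection: list[int] | None = None,
    cutoff: float = 6.0,
    threshold: float = 0.3,
    subunit_map: dict[str, str] | None = None,
) -> TeSPMSeries:
    """Time-evolution SPM over sliding windows of the trajectory.

    Each window [k·stride, k·stride + window] (frames strictly inside the
    span, boundaries included) gets its own correlation matrix, contact
    adjacency and SPM.  A 1200 ns trajectory at window 600 / stride 300
    yields the three windows [0, 600], [300, 900], [600, 1200].
    """
    t0 = float(traj.times[0])
    windows = spm_windows(traj.span_ns, window_ns, stride_ns)
    if selection is None:
        selection, _ = ca_indices(traj.topology)
    sub_map = subunit_map or traj.topology.subunit_map
    results, counts = [], []
    for start, end in windows:
        sub = traj.slice_time(t0 + start, t0 + end)
        corr = correlation_matrix(sub, selection=selection)
        adj = contact_adjacency(sub, selection=selection, cutoff=cutoff)
        res = spm(corr, adj, threshold=threshold)
        results.append(res)
        counts.append(subunit_counts(res, sub_map))
    return TeSPMSeries(windows=windows, results=results, counts=counts)


def subunit_counts(result: SPMResult,
                   subunit_map: dict[str, str]) -> dict[str, int]:
    """Number of residues with at least one included edge, per subunit."""
    counts: dict[str, int] = {label: 0 for label in set(subunit_map.values())}
    for i in result.included_nodes():
        chain, _resid = result.residues[i]
        if chain not in subunit_map:
            raise ValueError(f"residue chain {chain!r} has no subunit tag")
        counts[subunit_map[chain]] = counts.get(subunit_map[chain], 0) + 1
    return counts


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def spm_to_networkx(result: SPMResult):
    """The SPM as an undirected networkx graph (all contact edges kept)."""
    import networkx as nx

    g = nx.Graph()
    for i, (chain, resid) in enumerate(result.residues):
        g.add_node(i, chain=chain, resid=resid,
                   importance=float(result.node_importance[i]))
    for (i, j), rec in result.edges.items():
        g.add_edge(i, j, weight=rec["weight"], usage=rec["usage"],
                   width=rec["width"],
                   included=bool(rec["width"] >= result.threshold))
    return g


def write_graphml(result: SPMResult, path) -> None:
    import networkx as nx

    nx.write_graphml(spm_to_networkx(result), str(path))


def write_edgelist_csv(result: SPMResult, path) -> None:
    import pandas as pd

    rows = []
    for (i, j), rec in sorted(result.edges.items()):
        ci, ri = result.residues[i]
        cj, rj = result.residues[j]
        rows.append({
            "residue_i": f"{ci}:{ri}", "residue_j": f"{cj}:{rj}",
            "weight": rec["weight"], "usage": rec["usage"],
            "width": rec["width"],
            "included": rec["width"] >= result.threshold,
        })
    pd.DataFrame(rows).to_csv(path, index=False)
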