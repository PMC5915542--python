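"""Directed graph measures on time-varying networks.

Only the measures the analysis uses: weighted out-degree, directed weighted
local efficiency (Rubinov-Sporns form), hub ranking, and the onset of an
edge's significance.  Shortest-path distances are reciprocals of the
significance-masked weights, the standard convention for flow-like weights;
unreachable pairs contribute nothing (infinite distance).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

from .adtf import TimeVaryingNetwork


def out_degree(net: TimeVaryingNetwork, node: str, t_ms: float) -> float:
    """Sum of a node's significant outgoing weights at one timepoint.

    With entry (i, j) meaning flow j -> i, node j's out-degree is the sum of
    column j over significant off-diagonal entries.
    """
    if node not in net.node_labels:
        raise KeyError(f"unknown node {node!r}")
    j = net.node_labels.index(node)
    W = net.masked(net.time_index(t_ms))
    return float(W[:, j].sum())


def out_degree_series(net: TimeVaryingNetwork) -> pd.DataFrame:
    """Out-degree of every node at every timepoint (long format)."""
    W = np.where(net.sig_mask, net.weights, 0.0)
    deg = W.sum(axis=1)  # column sums -> (T, n)
    t, nd = np.meshgrid(net.times, np.arange(net.n_nodes), indexing="ij")
    return pd.DataFrame({
        "time_ms": t.ravel(),
        "node": np.asarray(net.node_labels)[nd.ravel()],
        "out_degree": deg.ravel(),
    })


def _local_efficiency_matrix(W: np.ndarray) -> np.ndarray:
    """Per-node directed weighted local efficiency for one adjacency.

    ``W[i, j]`` is flow j -> i.  For node i with neighborhood N_i (nodes
    linked to i in either direction), the value is

        E_i = (1/2) * sum_{j != m in N_i} (W_ij + W_ji)(W_im + W_mi)
              (1/d_jm + 1/d_mj) / [ (k_out + k_in)(k_out + k_in - 1)
                                    - 2 sum_j W_ij W_ji ]

    with d the directed shortest-path length inside N_i on reciprocal-weight
    distances.  Nodes with fewer than two neighbors (or a non-positive
    denominator) score 0.
    """
    n = W.shape[0]
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    eff = np.zeros(n)
    k_out = W.sum(axis=0)  # column sums: flows leaving each node
    k_in = W.sum(axis=1)   # row sums: flows entering each node
    for i in range(n):
        nbrs = np.where((W[i, :] + W[:, i]) > 0)[0]
        nbrs = nbrs[nbrs != i]
        if len(nbrs) < 2:
            continue
        k = k_out[i] + k_in[i]
        den = k * (k - 1) - 2 * float(W[i, :] @ W[:, i])
        if den <= 0:
            continue
        # directed distances within the neighborhood subgraph:
        # edge u -> v has length 1 / W[v, u]
        flow = W[np.ix_(nbrs, nbrs)]            # flow[a, b] = b -> a
        with np.errstate(divide="ignore"):
            dist = np.where(flow.T > 0, 1.0 / flow.T, np.inf)
        d = shortest_path(dist, method="D")      # d[a, b] = a -> b
        conn = W[i, nbrs] + W[nbrs, i]           # (W_ij + W_ji) per neighbor
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        pair = conn[:, None] * conn[None, :] * (inv_d + inv_d.T)
        np.fill_diagonal(pair, 0.0)
        eff[i] = 0.5 * pair.sum() / den
    return eff


def local_efficiency(net: TimeVaryingNetwork, t_ms: float
                     ) -> tuple[dict[str, float], float]:
    """Per-node directed local efficiency and the network mean at one time."""
    if net.n_nodes < 3:
        raise ValueError("local efficiency needs at least 3 nodes")
    W = net.masked(net.time_index(t_ms))
    eff = _local_efficiency_matrix(W)
    per_node = dict(zip(net.node_labels, eff.tolist()))
    return per_node, float(eff.mean())


def hubs(net: TimeVaryingNetwork, t_window: tuple[float, float]
         ) -> list[tuple[str, float]]:
    """Nodes ranked by time-averaged out-degree over a window (ms).

    Deterministic: ties break alphabetically.
    """
    t0, t1 = t_window
    sel = (net.times >= t0) & (net.times <= t1)
    if not sel.any():
        raise ValueError(f"window [{t0}, {t1}] ms contains no network "
                         "timepoints")
    W = np.where(net.sig_mask[sel], net.weights[sel], 0.0)
    deg = W.sum(axis=1).mean(axis=0)  # time-mean column sums
    order = sorted(zip(net.node_labels, deg.tolist()),
                   key=lambda kv: (-kv[1], kv[0]))
    return order


def onset_delay(net: TimeVaryingNetwork, edge: tuple[str, str],
                t_window: tuple[float, float]) -> float | None:
    """First time (ms) at which edge source -> target is significant.

    Returns None if the edge never reaches significance in the window.
    """
    src, tgt = edge
    for node in (src, tgt):
        if node not in net.node_labels:
            raise KeyError(f"unknown node {node!r}")
    j = net.node_labels.index(src)
    i = net.node_labels.index(tgt)
    sel = np.where((net.times >= t_window[0]) & (net.times <= t_window[1]))[0]
    for t in sel:
        if net.sig_mask[t, i, j]:
            return float(net.times[t])
    return None


def metrics_table(net: TimeVaryingNetwork) -> pd.DataFrame:
    """Out-degree and local efficiency for every node/timepoint (TSV-ready)."""
    rows = []
    for t in net.times:
        deg = {n: out_degree(net, n, t) for n in net.node_labels}
        eff, _ = local_efficiency(net, t)
        for n in net.node_labels:
            rows.append((t, n, "out_degree", deg[n]))
            rows.append((t, n, "local_efficiency", eff[n]))
    return pd.DataFrame(rows, columns=["time_ms", "node", "metric", "value"])
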