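"""Weighted nodal graph metrics of the tool-use network with sparsity-AUC.

The 10-node tool-use subnetwork (TE, AIP, LIP, VIP, PMv, PMd, pre-SMA plus
the three MT+ seeds) is analyzed as a weighted undirected graph.  The total
connection strength is first normalized to 1 for cross-species
comparability, the network is thresholded at sparsities 0.05..0.5 (step
0.05) keeping edge weights (no binarization), and four nodal metrics are
computed at each sparsity:

* ``Dc``  -- degree centrality as node strength (sum of incident weights);
* ``Cp``  -- weighted clustering coefficient, geometric-mean triangle form
  on weights rescaled by the network maximum;
* ``Eg``  -- nodal efficiency, mean inverse shortest-path length to all
  other nodes on edge lengths ``1/w`` (unreachable pairs contribute 0);
* ``Eloc`` -- local efficiency, the global efficiency of the subgraph
  induced by the node's neighbors with the node itself removed.

Each metric's curve over the sparsity sweep is summarized by its
trapezoidal area under the curve (AUC), the threshold-free statistic used
for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

TOOL_USE_NODES = (
    "TE", "AIP", "LIP", "VIP", "PMv", "PMd", "pre-SMA", "MST", "MT", "FST",
)
DEFAULT_SPARSITIES = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
METRICS = ("Cp", "Dc", "Eloc", "Eg")


@dataclass
class WeightedNetwork:
    """Symmetric nonnegative weighted graph with labeled nodes, no self-loops."""

    weights: np.ndarray
    labels: tuple[str, ...] = TOOL_USE_NODES

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.labels = tuple(self.labels)
        n = len(self.labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights shape must match number of labels")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("network must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index(self, node: str) -> int:
        try:
            return self.labels.index(node)
        except ValueError:
            raise KeyError(f"unknown node: {node}") from None


def normalize_total_strength(net: WeightedNetwork) -> WeightedNetwork:
    """Rescale so the unique undirected edge weights sum to 1 (idempotent)."""
    total = np.triu(net.weights, k=1).sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero network")
    return WeightedNetwork(net.weights / total, net.labels)


def threshold_by_sparsity(net: WeightedNetwork, s: float) -> WeightedNetwork:
    """Keep the ``ceil(s * n(n-1)/2)`` strongest edges; weights are preserved.

    Ties at the cut are broken deterministically: weight descending, then
    lexicographic on the (label_a, label_b) pair.
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    n = net.n_nodes
    k = ceil(s * n * (n - 1) / 2)
    iu, ju = np.triu_indices(n, k=1)
    edges = sorted(
        zip(iu, ju),
        key=lambda e: (-net.weights[e[0], e[1]], net.labels[e[0]], net.labels[e[1]]),
    )
    out = np.zeros_like(net.weights)
    for i, j in edges[:k]:
        out[i, j] = out[j, i] = net.weights[i, j]
    return WeightedNetwork(out, net.labels)


def _lengths(weights: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, np.inf)
    np.fill_diagonal(lengths, 0.0)
    return lengths


def _global_efficiency_matrix(weights: np.ndarray) -> np.ndarray:
    """Per-node efficiency: mean of 1/d to every other node (0 if unreachable)."""
    n = weights.shape[0]
    if n < 2:
        return np.zeros(n)
    d = dijkstra(_lengths(weights), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_metrics(net: WeightedNetwork) -> pd.DataFrame:
    """All four nodal metrics of one (already thresholded) network.

    Returns a DataFrame indexed by node label with columns Cp, Dc, Eloc, Eg.
    """
    w = net.weights
    n = net.n_nodes
    adj = w > 0
    deg = adj.sum(axis=1)  # binary degree

    dc = w.sum(axis=1)

    # clustering on weights rescaled by the network-wide maximum
    wmax = w.max()
    cp = np.zeros(n)
    if wmax > 0:
        cbrt = np.cbrt(w / wmax)
        tri = np.diag(cbrt @ cbrt @ cbrt)  # ordered neighbor pairs, x2 per triangle
        denom = deg * (deg - 1)
        cp = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)

    eg = _global_efficiency_matrix(w)

    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc[i] = _global_efficiency_matrix(sub).mean()

    return pd.DataFrame(
        {"Cp": cp, "Dc": dc, "Eloc": eloc, "Eg": eg}, index=list(net.labels)
    )


def nodal_degree_centrality(net: WeightedNetwork, node: str) -> float:
    """Weighted degree centrality (node strength) of one node."""
    return float(net.weights[net.index(node)].sum())


def nodal_degree_binary(net: WeightedNetwork, node: str) -> int:
    """Binary degree (number of suprathreshold connections) of one node."""
    return int((net.weights[net.index(node)] > 0).sum())


def nodal_clustering(net: WeightedNetwork, node: str) -> float:
    net.index(node)
    return float(nodal_metrics(net).loc[node, "Cp"])


def nodal_efficiency(net: WeightedNetwork, node: str) -> float:
    net.index(node)
    return float(nodal_metrics(net).loc[node, "Eg"])


def nodal_local_efficiency(net: WeightedNetwork, node: str) -> float:
    net.index(node)
    return float(nodal_metrics(net).loc[node, "Eloc"])


def sparsity_sweep(
    net: WeightedNetwork,
    sparsities: Sequence[float] = DEFAULT_SPARSITIES,
) -> pd.DataFrame:
    """Nodal metrics at every sparsity; tidy (node, metric, sparsity, value)."""
    if len(sparsities) == 0 or list(sparsities) != sorted(sparsities):
        raise ValueError("sparsities must be a nonempty ascending sequence")
    frames = []
    for s in sparsities:
        m = nodal_metrics(threshold_by_sparsity(net, s))
        tidy = (
            m.rename_axis("node")
            .reset_index()
            .melt(id_vars="node", var_name="metric", value_name="value")
        )
        tidy["sparsity"] = s
        frames.append(tidy)
    return pd.concat(frames, ignore_index=True)[
        ["node", "metric", "sparsity", "value"]
    ]


def metric_auc(
    values: Sequence[float],
    sparsities: Sequence[float] = DEFAULT_SPARSITIES,
) -> float:
    """Trapezoidal area under one metric's curve over the full sweep.

    Requires a value at every threshold of the sweep (default 0.05..0.5,
    step 0.05); a constant ``c`` integrates to ``0.45 c`` on the default
    sweep.
    """
    values = np.asarray(values, dtype=float)
    sp = np.asarray(sparsities, dtype=float)
    if values.shape != sp.shape:
        raise ValueError(
            f"need one value per threshold ({sp.size}), got {values.size}"
        )
    if not np.allclose(np.round(sp, 10), sp) or np.any(np.diff(sp) <= 0):
        raise ValueError("sparsities must be strictly ascending")
    return float(np.trapezoid(values, sp))


def auc_table(
    net: WeightedNetwork,
    sparsities: Sequence[float] = DEFAULT_SPARSITIES,
) -> pd.DataFrame:
    """Per-node AUC of each metric over the sparsity sweep."""
    sweep = sparsity_sweep(net, sparsities)
    out = {}
    for (node, metric), grp in sweep.groupby(["node", "metric"], sort=False):
        grp = grp.sort_values("sparsity")
        out.setdefault(node, {})[metric] = metric_auc(
            grp["value"].to_numpy(), grp["sparsity"].to_numpy()
        )
    table = pd.DataFrame.from_dict(out, orient="index")
    return table.loc[list(net.labels), list(METRICS)]
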