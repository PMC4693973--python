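"""Residue coevolution networks: communities, layout, linkers, paths.

Nodes are reference residue numbers sized by cumulative MI score; edges carry
the coevolution z-score. Communities come from greedy modularity
maximization; the two-dimensional layout is classical scaling of the
shortest-path metric refined by stress majorization. Linker residues — those
with edges into foreign communities — are the candidate mediators of
long-range (allosteric) communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class ResidueNetwork:
    """Undirected residue graph with node scores, partition and layout."""

    graph: nx.Graph
    node_scores: dict[int, float]
    partition: dict[int, int] | None = None
    modularity: float | None = None
    layout: dict[int, tuple[float, float]] | None = None
    stress_history: np.ndarray | None = field(default=None)

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        )


def build_network(
    edges: list[tuple[int, int, float]],
    node_scores: dict[int, float],
) -> ResidueNetwork:
    """Assemble the residue network from a coevolution edge list.

    Isolated scored residues are retained as singleton nodes. Duplicate edges
    with conflicting weights are an error; self-loops are rejected.
    """
    G = nx.Graph()
    G.add_nodes_from(node_scores)
    for u, v, w in edges:
        if u == v:
            raise ValueError(f"self-loop on residue {u}")
        if u not in node_scores or v not in node_scores:
            raise ValueError(f"edge ({u}, {v}) references unscored residue")
        if G.has_edge(u, v) and G[u][v]["weight"] != w:
            raise ValueError(f"conflicting duplicate edge ({u}, {v})")
        G.add_edge(u, v, weight=float(w))
    return ResidueNetwork(G, dict(node_scores))


def communities(
    net: ResidueNetwork, resolution: float = 1.0, seed: int = 0
) -> tuple[dict[int, int], float]:
    """Greedy (CNM) modularity maximization on the weighted graph.

    Returns (partition, Q). The algorithm is deterministic; ``seed`` is
    accepted for interface stability. An edgeless graph yields singleton
    communities with Q = 0. Community ids are contiguous from 0, ordered by
    smallest member.
    """
    G = net.graph
    if G.number_of_edges() == 0:
        part = {n: i for i, n in enumerate(sorted(G.nodes))}
        net.partition, net.modularity = part, 0.0
        return part, 0.0
    comms = nx.community.greedy_modularity_communities(
        G, weight="weight", resolution=resolution
    )
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    part = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(
        G, [set(c) for c in comms], weight="weight", resolution=resolution
    )
    net.partition, net.modularity = part, float(q)
    return part, float(q)


def modularity_of(net: ResidueNetwork, partition: dict[int, int]) -> float:
    """Weighted modularity Q of an arbitrary stated partition."""
    groups: dict[int, set] = {}
    for n, c in partition.items():
        groups.setdefault(c, set()).add(n)
    return float(
        nx.community.modularity(net.graph, list(groups.values()), weight="weight")
    )


def _classical_mds(D: np.ndarray) -> np.ndarray:
    """Classical (Torgerson) scaling of a distance matrix to 2-D."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(-vals)[:2]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))
    if coords.shape[1] < 2:  # pragma: no cover - eigh always returns n columns
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords


def _stress(X: np.ndarray, D: np.ndarray) -> float:
    diff = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(D.shape[0], 1)
    return float(((diff[iu] - D[iu]) ** 2).sum())


def _majorize(X: np.ndarray, D: np.ndarray, n_iter: int) -> tuple[np.ndarray, list[float]]:
    """SMACOF stress majorization (uniform weights); monotone stress descent."""
    n = X.shape[0]
    history = [_stress(X, D)]
    for _ in range(n_iter):
        diff = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(diff > 0, D / diff, 0.0)
        np.fill_diagonal(ratio, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
        history.append(_stress(X, D))
        if history[-2] - history[-1] < 1e-12:
            break
    return X, history


def layout(
    net: ResidueNetwork, n_iter: int = 100, seed: int = 0
) -> dict[int, tuple[float, float]]:
    """Two-step node placement: classical scaling then stress majorization.

    Connected components are laid out separately from their shortest-path
    (hop) metric and packed on a grid. Deterministic; ``seed`` kept for
    interface stability. The per-iteration stress history of the largest
    component is stored on the network.
    """
    G = net.graph
    pos: dict[int, tuple[float, float]] = {}
    offset_x = 0.0
    best_history: list[float] = [0.0]
    for comp in sorted(nx.connected_components(G), key=lambda c: (-len(c), min(c))):
        nodes = sorted(comp)
        if len(nodes) == 1:
            pos[nodes[0]] = (offset_x, 0.0)
            offset_x += 2.0
            continue
        sub = G.subgraph(nodes)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        D = np.array([[lengths[u][v] for v in nodes] for u in nodes], dtype=float)
        X = _classical_mds(D)
        X, history = _majorize(X, D, n_iter)
        if len(history) > len(best_history):
            best_history = history
        span = X[:, 0].max() - X[:, 0].min()
        X[:, 0] += offset_x - X[:, 0].min()
        offset_x += span + 2.0
        for u, xy in zip(nodes, X):
            pos[u] = (float(xy[0]), float(xy[1]))
    net.layout = pos
    net.stress_history = np.asarray(best_history)
    return pos


def linkers(
    net: ResidueNetwork, partition: dict[int, int] | None = None
) -> list[tuple[int, int, float]]:
    """Residues with edges into foreign communities.

    Returns (residue, n_foreign_communities, node_score) tuples for every
    node touching >= 1 community other than its own, ranked by
    (count, node_score) descending with residue-number ties ascending.
    """
    part = partition if partition is not None else net.partition
    if part is None:
        raise ValueError("communities must be computed first")
    out = []
    for n in net.graph.nodes:
        foreign = {part[v] for v in net.graph.neighbors(n) if part[v] != part[n]}
        if foreign:
            out.append((n, len(foreign), net.node_scores.get(n, 0.0)))
    out.sort(key=lambda t: (-t[1], -t[2], t[0]))
    return out


def optimal_paths(
    net: ResidueNetwork,
    source: int,
    target: int,
    k: int = 1,
    length_mode: str = "inverse",
) -> list[tuple[list[int], float]]:
    """k shortest communication paths between two residues.

    Edge length is 1/z by default ("inverse"; stronger coevolution = shorter)
    or -ln(z/z_max) ("log"). Yen's algorithm on Dijkstra distances; returns
    [] for a disconnected pair.
    """
    G = net.graph
    if source not in G or target not in G:
        raise ValueError("source/target residue not in network")
    if G.number_of_edges() == 0:
        return []
    zmax = max(d["weight"] for _, _, d in G.edges(data=True))
    H = G.copy()
    for u, v, d in H.edges(data=True):
        if length_mode == "inverse":
            d["length"] = 1.0 / d["weight"]
        elif length_mode == "log":
            d["length"] = -np.log(d["weight"] / zmax) + 1e-12
        else:
            raise ValueError(f"unknown length_mode: {length_mode!r}")
    if not nx.has_path(H, source, target):
        return []
    out = []
    gen = nx.shortest_simple_paths(H, source, target, weight="length")
    for _, path in zip(range(k), gen):
        length = sum(
            H[u][v]["length"] for u, v in zip(path, path[1:])
        )
        out.append((path, float(length)))
    return out


def plot_network(net: ResidueNetwork, path, important: set[int] | None = None):
    """Render the node-size-by-score, color-by-community picture as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if net.layout is None:
        layout(net)
    if net.partition is None:
        communities(net)
    pos = net.layout
    part = net.partition
    fig, ax = plt.subplots(figsize=(8, 8))
    scores = np.array([net.node_scores.get(n, 0.0) for n in net.graph.nodes])
    smax = scores.max() if scores.size and scores.max() > 0 else 1.0
    sizes = 40 + 260 * scores / smax
    colors = [part[n] for n in net.graph.nodes]
    for u, v in net.graph.edges:
        strong = important and u in important and v in important
        ax.plot(
            [pos[u][0], pos[v][0]],
            [pos[u][1], pos[v][1]],
            color="0.25" if strong else "0.8",
            lw=1.5 if strong else 0.6,
            zorder=1,
        )
    xs = [pos[n][0] for n in net.graph.nodes]
    ys = [pos[n][1] for n in net.graph.nodes]
    ax.scatter(xs, ys, s=sizes, c=colors, cmap="tab10", zorder=2)
    if important:
        for n in important:
            if n in pos:
                ax.annotate(str(n), pos[n], fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, format="svg")
    plt.close(fig)
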