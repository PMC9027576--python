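"""Per-pen aggression networks and node-level social network traits.

Fight and bully records within a pen are combined into one undirected,
unweighted graph (an edge exists if the dyad interacted at least once in
either direction; frequency, duration and initiator are deliberately
ignored).  Seven traits describe each animal's position in its pen network:

- degree centrality (raw partner count and the count / (n-1) normalisation),
- betweenness centrality (pair-normalised shortest-path load),
- closeness centrality (inverse mean geodesic distance, with the
  reachable-set rescaling for disconnected graphs; isolates get 0),
- eigenvector centrality (leading eigenvector of the adjacency matrix on
  the largest connected component),
- local clustering coefficient (0 for animals with fewer than 2 partners),
- clique membership (member of at least one maximum clique), and
- categorical betweenness (top population quartile = 'high').

The continuous centralities are bounded in [0, 1] under these
normalisations; standard graph algorithms are delegated to networkx.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class NetworkDataError(ValueError):
    """An interaction record refers to an animal outside its pen."""


class DegenerateNetworkError(ValueError):
    """Graph too small for the requested statistic."""


@dataclass
class InteractionRecord:
    """One observed aggressive interaction inside a pen."""

    pen_id: int
    initiator_id: int
    receiver_id: int
    kind: str = "fight"  # "fight" | "bully"
    duration: float | None = None


@dataclass
class PenNetwork:
    """Undirected unweighted aggression graph of one pen.

    ``nodes`` lists every pen member (isolates included) in a stable order;
    ``adjacency`` is symmetric boolean with zero diagonal.
    """

    pen_id: int
    nodes: list[int]
    adjacency: np.ndarray
    graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.array_equal(a, a.T) or a.diagonal().any():
            raise ValueError("adjacency must be symmetric with zero diagonal")
        self.adjacency = a
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        idx = np.argwhere(np.triu(a, 1))
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in idx)
        self.graph = g

    @property
    def n(self) -> int:
        return len(self.nodes)


def build_pen_network(
    records: Iterable[InteractionRecord], pen_members: Sequence[int], pen_id: int | None = None
) -> PenNetwork:
    """Combine fight and bully records into the pen's undirected graph.

    Raises :class:`NetworkDataError` if any record mentions an animal not in
    ``pen_members``.  Animals with no interactions remain as isolates.
    """
    members = list(pen_members)
    pos = {a: k for k, a in enumerate(members)}
    n = len(members)
    adj = np.zeros((n, n), dtype=bool)
    pid = pen_id
    for rec in records:
        if pid is None:
            pid = rec.pen_id
        bad = [a for a in (rec.initiator_id, rec.receiver_id) if a not in pos]
        if bad:
            raise NetworkDataError(
                f"pen {rec.pen_id}: interaction references non-members {bad}"
            )
        if rec.initiator_id == rec.receiver_id:
            raise NetworkDataError(
                f"pen {rec.pen_id}: self-interaction for animal {rec.initiator_id}"
            )
        i, j = pos[rec.initiator_id], pos[rec.receiver_id]
        adj[i, j] = adj[j, i] = True
    return PenNetwork(pid if pid is not None else -1, members, adj)


def degree_centrality(net: PenNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Raw degree and the degree / (n-1) normalisation, in node order."""
    if net.n < 2:
        raise DegenerateNetworkError("degree centrality needs at least 2 nodes")
    raw = net.adjacency.sum(axis=1).astype(float)
    return raw, raw / (net.n - 1)


def betweenness_centrality(net: PenNetwork) -> np.ndarray:
    """Pair-normalised betweenness: share of geodesics through each node.

    Normalised by (n-1)(n-2)/2, the number of unordered pairs excluding the
    focal node, so a path's middle node scores 1 on a 3-node path.
    """
    if net.n < 3:
        raise DegenerateNetworkError("betweenness needs at least 3 nodes")
    bc = nx.betweenness_centrality(net.graph, normalized=True)
    return np.array([bc[v] for v in net.nodes])


def closeness_centrality(net: PenNetwork) -> np.ndarray:
    """Closeness with the Wasserman–Faust reachable-set rescaling.

    For node v with r reachable nodes at total geodesic distance s:
    ``(r / s) * (r / (n-1))``; isolates score 0.  On a connected graph this
    is the usual (n-1)/s.
    """
    if net.n < 2:
        raise DegenerateNetworkError("closeness needs at least 2 nodes")
    cc = nx.closeness_centrality(net.graph, wf_improved=True)
    return np.array([cc[v] for v in net.nodes])


def eigenvector_centrality(net: PenNetwork, scaling: str = "max") -> np.ndarray:
    """Leading-eigenvector centrality on the largest connected component.

    Entries are non-negative; nodes outside the largest component get 0.
    ``scaling="max"`` rescales so the largest entry is 1 (the default);
    ``scaling="l2"`` leaves the unit-L2-norm eigenvector.  An edgeless
    graph yields all zeros with a warning.  Among equally large components
    the one containing the smallest node id is used.
    """
    if scaling not in ("max", "l2"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if net.graph.number_of_edges() == 0:
        warnings.warn(
            f"pen {net.pen_id}: edgeless network, eigenvector centrality all zero",
            stacklevel=2,
        )
        return np.zeros(net.n)
    comps = sorted(
        nx.connected_components(net.graph), key=lambda c: (-len(c), min(net.nodes.index(v) for v in c))
    )
    comp = sorted(comps[0], key=net.nodes.index)
    cidx = [net.nodes.index(v) for v in comp]
    sub = net.adjacency[np.ix_(cidx, cidx)].astype(float)
    w, v = np.linalg.eigh(sub)
    lead = np.abs(v[:, np.argmax(w)])
    out = np.zeros(net.n)
    out[cidx] = lead
    if scaling == "max":
        out /= out.max()
    return out


def clustering_coefficient(net: PenNetwork) -> np.ndarray:
    """Local transitivity: 2 * triangles(i) / (k_i (k_i - 1)); 0 if k_i < 2."""
    cl = nx.clustering(net.graph)
    return np.array([cl[v] for v in net.nodes])


def clique_membership(net: PenNetwork) -> tuple[np.ndarray, int]:
    """Indicator of membership in at least one maximum clique, plus its size.

    Pens are small (n <= 30 enforced) so exact enumeration via networkx's
    maximal-clique generator is used.  An edgeless graph degenerates to
    maximum-clique size 1 with every animal a 'member'; a warning flags it.
    """
    if net.n > 30:
        raise DegenerateNetworkError("exact clique enumeration limited to n <= 30")
    cliques = list(nx.find_cliques(net.graph))
    size = max(len(c) for c in cliques) if cliques else 1
    members: set[int] = set()
    for c in cliques:
        if len(c) == size:
            members.update(c)
    if size <= 1:
        warnings.warn(
            f"pen {net.pen_id}: no edges, clique membership degenerate", stacklevel=2
        )
        members = set(net.nodes)
    flag = np.array([1 if v in members else 0 for v in net.nodes])
    return flag, size


def categorize_betweenness(values: np.ndarray, quartile: float = 0.75) -> np.ndarray:
    """Split betweenness into 'high' (top quartile, coded 1) vs 'low' (0).

    The cut is the population-wide 75th percentile; ties at the cut are all
    'high'.  With all values equal the whole population is 'high' and a
    degenerate-split warning is raised.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for a quartile split")
    cut = np.quantile(values, quartile)
    high = (values >= cut).astype(int)
    if high.all():
        warnings.warn("degenerate betweenness split: all values at or above the cut",
                      stacklevel=2)
    return high


#: canonical column order for the per-animal trait table
SNA_COLUMNS = [
    "sna_degree_raw",
    "sna_degree",
    "sna_betweenness",
    "sna_closeness",
    "sna_eigenvector",
    "sna_clustering",
    "sna_clique_member",
]


def compute_sna_traits(
    networks: Iterable[PenNetwork], eigenvector_scaling: str = "max"
) -> pd.DataFrame:
    """All seven traits for every animal across pens.

    Returns one row per animal with raw/normalised centralities on the
    observed scale (transformation to the modelled scale is a separate,
    explicit step) and the population-wide categorical betweenness.
    """
    rows = []
    for net in networks:
        raw, norm = degree_centrality(net)
        btw = betweenness_centrality(net)
        clo = closeness_centrality(net)
        eig = eigenvector_centrality(net, scaling=eigenvector_scaling)
        clu = clustering_coefficient(net)
        clq, clq_size = clique_membership(net)
        for k, animal in enumerate(net.nodes):
            rows.append(
                {
                    "animal": animal,
                    "pen": net.pen_id,
                    "sna_degree_raw": raw[k],
                    "sna_degree": norm[k],
                    "sna_betweenness": btw[k],
                    "sna_closeness": clo[k],
                    "sna_eigenvector": eig[k],
                    "sna_clustering": clu[k],
                    "sna_clique_member": int(clq[k]),
                    "pen_max_clique_size": clq_size,
                }
            )
    table = pd.DataFrame(rows)
    table["sna_betweenness_cat"] = categorize_betweenness(
        table["sna_betweenness"].to_numpy()
    )
    return table
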