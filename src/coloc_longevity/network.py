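"""Co-location networks over Hi-C bins.

Nodes are global bin IDs; an edge joins two bins whose contact frequency
strictly exceeds the applicable top-tail threshold (per-chromosome intra or
genome-wide inter).  The *original* network's nodes are the bins harboring
at least one genome-wide-significant SNP (isolated nodes are retained); the
*extended* network additionally contains every bin that interacts strongly
with at least one original node, tagged ``"added"``.

Communities are detected with Louvain modularity optimization on edge
weights; the resolution parameter (default 0.1) trades community count
against size.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .contacts import ContactMatrix, ThresholdSet
from .layout import GenomeLayout

__all__ = [
    "ColocationNetwork",
    "CommunityPartition",
    "build_original_network",
    "extend_network",
    "node_degree",
    "connected_components",
    "detect_communities",
    "ego_subnetwork",
    "shared_nodes",
    "write_network_tsv",
    "read_network_tsv",
]


@dataclass
class ColocationNetwork:
    """A weighted undirected graph over genome bins.

    ``graph`` is a :class:`networkx.Graph` whose nodes are 1-based global
    bin IDs with an ``origin`` attribute (``"original"`` or ``"added"``)
    and whose edges carry the contact frequency as ``weight``.
    """

    graph: nx.Graph
    layout: GenomeLayout
    dataset: str = ""

    @property
    def nodes(self) -> set[int]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def origin(self, node: int) -> str:
        return self.graph.nodes[node]["origin"]

    def original_nodes(self) -> set[int]:
        return {n for n, d in self.graph.nodes(data=True) if d["origin"] == "original"}

    def added_nodes(self) -> set[int]:
        return {n for n, d in self.graph.nodes(data=True) if d["origin"] == "added"}


def _strong_edges_among(
    bins: np.ndarray, contacts: ContactMatrix, thresholds: ThresholdSet
) -> list[tuple[int, int, float]]:
    """All (i, j, f) with i < j in ``bins`` and f above the applicable cut."""
    layout = contacts.layout
    idx = np.asarray(sorted(bins), dtype=int) - 1
    sub = contacts.matrix[np.ix_(idx, idx)].tocoo()
    pool = layout.pooled_index_array()
    chrom = layout.bin_chrom_array()
    edges = []
    for r, c, f in zip(sub.row, sub.col, sub.data):
        if r >= c or f <= 0:
            continue
        gi, gj = idx[r], idx[c]
        if pool[gi] == pool[gj] and (thresholds.cross_arm == "intra" or chrom[gi] == chrom[gj]):
            tau = thresholds.intra[layout.pooled_names[pool[gi]]]
        else:
            tau = thresholds.inter
        if f > tau:
            edges.append((int(gi) + 1, int(gj) + 1, float(f)))
    return edges


def build_original_network(
    sig_bins: set[int],
    contacts: ContactMatrix,
    thresholds: ThresholdSet,
    dataset: str = "",
) -> ColocationNetwork:
    """Network whose nodes are the significant bins, edges the strong contacts.

    Every significant bin becomes a node even if isolated; an edge joins two
    nodes iff their contact frequency strictly exceeds the applicable
    threshold.
    """
    layout = contacts.layout
    for b in sig_bins:
        if not 1 <= b <= layout.n_bins:
            raise ValueError(f"significant bin {b} outside layout with {layout.n_bins} bins")
    g = nx.Graph()
    g.add_nodes_from(sorted(sig_bins), origin="original")
    if sig_bins:
        g.add_weighted_edges_from(
            _strong_edges_among(np.asarray(sorted(sig_bins)), contacts, thresholds)
        )
    return ColocationNetwork(graph=g, layout=layout, dataset=dataset)


def extend_network(
    net: ColocationNetwork,
    contacts: ContactMatrix,
    thresholds: ThresholdSet,
    star_extension: bool = False,
) -> ColocationNetwork:
    """Add every outside bin that interacts strongly with an original node.

    New nodes are tagged ``"added"``; original tags are preserved.  By
    default the edge set is *all* strong pairs among the final node set
    (including added-added pairs); with ``star_extension=True`` only
    added-to-original edges are created for the added nodes, the strict
    "interacts with the original nodes" reading.

    Extension is a single round: bins recruited by added nodes are not
    themselves added.
    """
    layout = contacts.layout
    orig = sorted(net.nodes)
    if not orig:
        g = nx.Graph()
        return ColocationNetwork(graph=g, layout=layout, dataset=net.dataset)
    idx = np.asarray(orig, dtype=int) - 1
    cols = contacts.matrix[:, idx].tocoo()  # all contacts with original nodes
    pool = layout.pooled_index_array()
    chrom = layout.bin_chrom_array()
    added: set[int] = set()
    star_edges: list[tuple[int, int, float]] = []
    for r, c, f in zip(cols.row, cols.col, cols.data):
        gj = idx[c]  # original node, 0-based
        if r == gj or f <= 0:
            continue
        if pool[r] == pool[gj] and (thresholds.cross_arm == "intra" or chrom[r] == chrom[gj]):
            tau = thresholds.intra[layout.pooled_names[pool[r]]]
        else:
            tau = thresholds.inter
        if f > tau:
            b = int(r) + 1
            if b not in net.nodes:
                added.add(b)
                star_edges.append((b, int(gj) + 1, float(f)))

    g = nx.Graph()
    g.add_nodes_from(orig)
    nx.set_node_attributes(g, {n: net.origin(n) for n in orig}, "origin")
    g.add_nodes_from(sorted(added), origin="added")
    if star_extension:
        g.add_weighted_edges_from(
            (u, v, w) for u, v, w in net.graph.edges(data="weight")
        )
        g.add_weighted_edges_from(star_edges)
    else:
        all_bins = np.asarray(sorted(set(orig) | added), dtype=int)
        g.add_weighted_edges_from(_strong_edges_among(all_bins, contacts, thresholds))
    return ColocationNetwork(graph=g, layout=layout, dataset=net.dataset)


def node_degree(net: ColocationNetwork) -> dict[int, int]:
    """Unweighted degree of every node (number of connections)."""
    return dict(net.graph.degree())


def connected_components(net: ColocationNetwork) -> list[set[int]]:
    """Connected components, largest first (ties by smallest member bin)."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


@dataclass
class CommunityPartition:
    """A node -> community assignment from Louvain modularity optimization."""

    membership: dict[int, int]
    resolution: float
    seed: int
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[int]]:
        out: dict[int, set[int]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def detect_communities(
    net: ColocationNetwork, resolution: float = 0.1, seed: int = 0
) -> CommunityPartition:
    """Louvain communities on edge weights at the given resolution.

    Deterministic for a fixed seed.  Community IDs are renumbered 0..k-1 in
    order of each community's smallest member bin.
    """
    if net.n_nodes == 0:
        raise ValueError("cannot detect communities in an empty network")
    comms = nx.community.louvain_communities(
        net.graph, weight="weight", resolution=resolution, seed=seed
    )
    comms = sorted((set(c) for c in comms), key=min)
    membership = {node: cid for cid, comm in enumerate(comms) for node in comm}
    mod = nx.community.modularity(
        net.graph, comms, weight="weight", resolution=resolution
    )
    return CommunityPartition(
        membership=membership, resolution=resolution, seed=seed, modularity=float(mod)
    )


def ego_subnetwork(net: ColocationNetwork, node: int) -> ColocationNetwork:
    """The subnetwork centered on a node: it, its neighbors, all edges among them."""
    if node not in net.graph:
        raise KeyError(f"node {node} not in network")
    members = {node} | set(net.graph.neighbors(node))
    sub = net.graph.subgraph(members).copy()
    return ColocationNetwork(graph=sub, layout=net.layout, dataset=net.dataset)


def shared_nodes(
    net_a: ColocationNetwork, net_b: ColocationNetwork
) -> tuple[set[int], float]:
    """Common bins of two networks and the genomic span they cover, in Mb."""
    if net_a.layout.bin_size != net_b.layout.bin_size:
        raise ValueError("networks have different resolutions")
    common = net_a.nodes & net_b.nodes
    span_mb = len(common) * net_a.layout.bin_size / 1e6
    return common, span_mb


def write_network_tsv(net: ColocationNetwork, path) -> None:
    """Weighted edge list plus isolated nodes, with origin tags.

    Isolated nodes are written as rows with empty ``bin_j``.
    """
    rows = []
    for u, v, w in sorted(net.graph.edges(data="weight")):
        rows.append((u, v, w, net.origin(u), net.origin(v)))
    for n in sorted(net.nodes):
        if net.graph.degree(n) == 0:
            rows.append((n, "", "", net.origin(n), ""))
    pd.DataFrame(
        rows, columns=["bin_i", "bin_j", "weight", "origin_i", "origin_j"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_network_tsv(path, layout: GenomeLayout, dataset: str = "") -> ColocationNetwork:
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples():
        u = int(row.bin_i)
        g.add_node(u, origin=row.origin_i)
        if pd.notna(row.bin_j) and str(row.bin_j) != "":
            v = int(float(row.bin_j))
            g.add_node(v, origin=row.origin_j)
            g.add_edge(u, v, weight=float(row.weight))
    return ColocationNetwork(graph=g, layout=layout, dataset=dataset)
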