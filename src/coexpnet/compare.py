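"""Cross-network comparison: overlaps, conserved/unique edges, components.

Edge identity in every comparison is the unordered gene pair only;
weights are ignored.  Gene-mode comparisons use the endpoint genes of the
(size-matched, top-k) networks, not the full transcriptome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import Network, Pair


@dataclass
class OverlapMatrix:
    """Pairwise shared-element counts and Jaccard indices.

    ``counts[i, j]`` is the number of shared elements (edges or genes)
    between networks i and j; the diagonal holds each network's own
    element count.  ``jaccard[i, j] = counts / (n_i + n_j - counts)``.
    """

    labels: list[str]
    counts: np.ndarray = field(repr=False)
    jaccard: np.ndarray = field(repr=False)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)

    def jaccard_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.jaccard, index=self.labels, columns=self.labels)


@dataclass
class ComponentSummary:
    """Connected-component statistics of an edge-induced graph."""

    n_components: int
    lcc_genes: int
    lcc_membership: set[str]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "lcc_genes": self.lcc_genes,
            "lcc_membership": sorted(self.lcc_membership),
        }


def pairwise_overlap(networks: list[Network], mode: str = "edges") -> OverlapMatrix:
    """Shared-edge or shared-gene counts for every pair of networks."""
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to compare")
    labels = [n.name for n in networks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate network names: {labels}")
    if mode == "edges":
        sets: list[set] = [n.pairs for n in networks]
    elif mode == "genes":
        sets = [n.genes for n in networks]
    else:
        raise ValueError(f"mode must be 'edges' or 'genes', got {mode!r}")
    k = len(sets)
    counts = np.zeros((k, k), dtype=int)
    jaccard = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            inter = len(sets[i] & sets[j])
            union = len(sets[i]) + len(sets[j]) - inter
            counts[i, j] = counts[j, i] = inter
            jaccard[i, j] = jaccard[j, i] = inter / union if union else 1.0
    return OverlapMatrix(labels, counts, jaccard)


def conserved_edges(networks: list[Network], name: str = "conserved") -> Network:
    """Edges present in *every* input network.

    The retained weight for a conserved pair is the minimum of its
    weights across inputs (the weakest observation of the interaction).
    """
    if not networks:
        raise ValueError("need at least 1 network")
    common: set[Pair] = set.intersection(*(n.pairs for n in networks))
    out = Network(name)
    for pair in common:
        out.edges[pair] = min(n.edges[pair] for n in networks)
    return out


def unique_edges(target: Network, others: list[Network], name: str | None = None) -> Network:
    """Edges of ``target`` present in no other network."""
    if any(o is target for o in others):
        raise ValueError("target network must not appear among the others")
    seen: set[Pair] = set().union(*(o.pairs for o in others)) if others else set()
    out = Network(name if name is not None else f"{target.name}_unique")
    for pair, w in target.edges.items():
        if pair not in seen:
            out.edges[pair] = w
    return out


def _lcc_int(edges_a: np.ndarray, edges_b: np.ndarray, n_nodes: int) -> tuple[int, np.ndarray]:
    """Union-find over integer-labelled edges.

    Returns (largest component size over touched nodes, root array).
    Nodes not touched by any edge are their own roots and do not count.
    """
    parent = np.arange(n_nodes, dtype=np.intp)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    for a, b in zip(edges_a.tolist(), edges_b.tolist()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots = np.fromiter((find(i) for i in range(n_nodes)), dtype=np.intp, count=n_nodes)
    touched = np.zeros(n_nodes, dtype=bool)
    touched[edges_a] = True
    touched[edges_b] = True
    if not touched.any():
        return 0, roots
    sizes = np.bincount(roots[touched], minlength=n_nodes)
    return int(sizes.max()), roots


def components(network: Network) -> ComponentSummary:
    """Connected components of the edge-induced undirected graph.

    Every gene is an edge endpoint by construction, so there are no
    isolated nodes; an empty network has zero components.
    """
    if len(network) == 0:
        return ComponentSummary(0, 0, set())
    genes = sorted(network.genes)
    index = {g: i for i, g in enumerate(genes)}
    ea = np.fromiter((index[a] for a, _ in network.edges), dtype=np.intp, count=len(network))
    eb = np.fromiter((index[b] for _, b in network.edges), dtype=np.intp, count=len(network))
    lcc, roots = _lcc_int(ea, eb, len(genes))
    root_ids, counts = np.unique(roots, return_counts=True)
    biggest = root_ids[np.argmax(counts)]
    membership = {genes[i] for i in range(len(genes)) if roots[i] == biggest}
    return ComponentSummary(int(len(root_ids)), lcc, membership)
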