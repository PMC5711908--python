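"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined in increasing order of pairwise mutational distance;
links longer than the parsimony connection limit (the largest number of
steps for which the probability that the connection is free of superimposed
changes is at least ``alpha``, conventionally 95%) are refused, which can
split the network into disconnected subnetworks.  Multi-step links are
materialised with inferred (unsampled) intermediate nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .seqio import HaplotypeSet, InputError


def pairwise_difference_matrix(hset: HaplotypeSet) -> np.ndarray:
    """Hamming distances between haplotype representative sequences.

    Sites where either sequence is missing (N) are excluded pairwise; gaps
    are compared literally (a shared indel state is a similarity, masked
    stutter never reaches this point).
    """
    seqs = [np.array(list(seq), dtype="U1") for _, seq, _ in hset.haplotypes]
    k = len(seqs)
    d = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            both = (seqs[i] != "N") & (seqs[j] != "N")
            d[i, j] = d[j, i] = int(np.sum(seqs[i][both] != seqs[j][both]))
    return d


def parsimony_probability(j: int, L: int) -> float:
    """Probability that two haplotypes j observed differences apart over L
    sites are separated by exactly j mutations (no superimposed changes).

    Uses a Jukes–Cantor superimposition model with the plug-in per-site
    divergence q = j/L: per-site mutation count is Poisson with mean
    lambda = -3/4 log(1 - 4q/3); a difference is parsimonious when it is the
    product of a single mutation, an identity when the site experienced none.
    """
    if j == 0:
        return 1.0
    q = j / L
    if q >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * q / 3.0)
    p_diff = 0.75 * (1.0 - math.exp(-4.0 * lam / 3.0))
    p_same = 0.25 + 0.75 * math.exp(-4.0 * lam / 3.0)
    p1_given_diff = lam * math.exp(-lam) / p_diff
    p0_given_same = math.exp(-lam) / p_same
    return p1_given_diff**j * p0_given_same ** (L - j)


def connection_limit(L: int, alpha: float = 0.95, max_steps: int | None = None) -> int:
    """Largest step count j with parsimony probability >= alpha."""
    if L < 1:
        raise InputError("alignment length must be >= 1")
    if max_steps is None:
        max_steps = L
    j = 0
    while j < max_steps and parsimony_probability(j + 1, L) >= alpha:
        j += 1
    return j


@dataclass
class NetworkGraph:
    """Haplotype network with inferred intermediates.

    ``graph`` nodes carry attributes ``kind`` ('observed' | 'inferred') and,
    for observed nodes, ``frequency`` (number of member samples).  All edges
    are single mutational steps after intermediate insertion.
    """

    graph: nx.Graph
    j95: int

    @property
    def observed_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def inferred_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "inferred"]

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for u, v in self.graph.edges():
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "steps": 1,
                    "inferred": self.graph.nodes[u]["kind"] == "inferred"
                    or self.graph.nodes[v]["kind"] == "inferred",
                }
            )
        return pd.DataFrame(rows, columns=["source", "target", "steps", "inferred"])


def build_network(hset: HaplotypeSet, dmat: np.ndarray, j95: int) -> NetworkGraph:
    """Join haplotypes in increasing distance order under the connection limit.

    Candidate links are sorted by (distance, -combined frequency,
    lexicographic id pair); a link is added when its ends are not yet in the
    same component and its length does not exceed ``j95``.  A link between
    already-connected haplotypes is retained as a reticulation only when it
    is strictly shorter than the existing path between them; equal-length
    alternatives are redundant and dropped.  A k-step link inserts k-1
    inferred nodes.
    """
    ids = hset.ids
    freq = {hid: len(m) for hid, _, m in hset.haplotypes}
    g = nx.Graph()
    for hid in ids:
        g.add_node(hid, kind="observed", frequency=freq[hid])

    candidates = []
    k = len(ids)
    for i in range(k):
        for j in range(i + 1, k):
            d = int(dmat[i, j])
            a, b = sorted((ids[i], ids[j]))
            candidates.append((d, -(freq[a] + freq[b]), a, b))
    candidates.sort()

    # provisional backbone over observed haplotypes, step-weighted edges
    backbone = nx.Graph()
    backbone.add_nodes_from(ids)

    added: list[tuple[str, str, int]] = []
    for d, _negf, a, b in candidates:
        if d == 0 or d > j95:
            continue
        if nx.has_path(backbone, a, b):
            # already connected: keep the link as a reticulation only when it
            # is strictly more parsimonious than the existing shortest path
            # (equal-length alternatives are redundant and dropped)
            span = nx.shortest_path_length(backbone, a, b, weight="weight")
            if d < span:
                added.append((a, b, d))
                backbone.add_edge(a, b, weight=d)
            continue
        added.append((a, b, d))
        backbone.add_edge(a, b, weight=d)

    # materialize multi-step links with inferred intermediates
    inferred_counter = 0
    for a, b, d in added:
        prev = a
        for s in range(1, d):
            inferred_counter += 1
            node = f"i{inferred_counter}"
            g.add_node(node, kind="inferred", frequency=0)
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, b)
    return NetworkGraph(graph=g, j95=j95)


def network_from_haplotypes(
    hset: HaplotypeSet, L: int, alpha: float = 0.95
) -> NetworkGraph:
    """Convenience: distance matrix + connection limit + network in one call."""
    dmat = pairwise_difference_matrix(hset)
    j95 = connection_limit(L, alpha=alpha)
    return build_network(hset, dmat, j95)


def minimum_spanning_network(hset: HaplotypeSet, dmat: np.ndarray) -> NetworkGraph:
    """Fallback: network at an infinite connection limit (MST backbone)."""
    return build_network(hset, dmat, j95=int(dmat.max()) if dmat.size else 0)
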