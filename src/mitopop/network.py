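"""Statistical-parsimony haplotype networks with a probability connection limit.

Haplotypes are joined at increasing mutational step distance, inserting
anonymous intermediate nodes for multi-step links, but only while a
connection of that many steps retains at least the requested probability
(default 95%) of being free of homoplasy.  The probability of parsimony for
a j-step connection over L sites is computed as the cumulative product of
per-step homoplasy-avoidance probabilities

    P_j = prod_{i=1..j} (1 - i / (2 L)),

i.e. the i-th connecting mutation must avoid the i sites already involved
in the path, each counted with probability 1/2 of striking the same lineage
of the two-lineage path.  The connection limit is the largest j with
P_j >= confidence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .seqio import HaplotypeTable

__all__ = ["ParsimonyNetwork", "connection_limit", "parsimony_probability",
           "build_network"]


@dataclass
class ParsimonyNetwork:
    graph: nx.Graph
    limit: int
    subnetworks: list[list[str]] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["count"] > 0]

    def edge_list(self):
        return [(u, v, d["steps"]) for u, v, d in self.graph.edges(data=True)]


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a j-step connection over L sites is homoplasy-free."""
    if j < 0:
        raise ValueError("steps must be non-negative")
    steps = np.arange(1, j + 1, dtype=float)
    factors = 1.0 - steps / (2.0 * L)
    if (factors <= 0).any():
        return 0.0
    return float(np.exp(np.log(factors).sum()))


def connection_limit(L: int, confidence: float = 0.95) -> int:
    """Maximum number of connection steps justified at the given confidence.

    Largest j such that the cumulative parsimony probability P_j for
    haplotypes j steps apart reaches ``confidence``.
    """
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    j = 0
    while parsimony_probability(j + 1, L) >= confidence:
        j += 1
    return j


def _hamming_ignore_gaps(s: str, t: str) -> int:
    return sum(
        1 for x, y in zip(s, t)
        if x != y and x not in "N-" and y not in "N-"
    )


def build_network(
    t: HaplotypeTable,
    limit: int | None = None,
    L: int | None = None,
    confidence: float = 0.95,
    keep_reticulations: bool = False,
    max_reticulations: int = 10,
) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony network over a haplotype table.

    Pairs of components are joined at increasing step distance d = 1..limit,
    inserting d-1 anonymous intermediate nodes ("missing haplotypes", count
    0).  When several equal-length connections compete, the pair whose
    connection point carries the higher haplotype frequency wins, then label
    order.  By default the output is the frequency-resolved tree; setting
    ``keep_reticulations`` retains alternative equal-length connections as
    extra edges up to ``max_reticulations``.
    """
    if t.n_haplotypes == 0:
        raise ValueError("empty haplotype table")
    if limit is None:
        if L is None:
            L = len(next(iter(t.hap_seqs.values())))
        limit = connection_limit(L, confidence)
    haps = list(t.hap_seqs)
    freq = t.counts.sum(axis=1).to_dict()
    g = nx.Graph()
    for h in haps:
        g.add_node(h, count=int(freq[h]),
                   demes=t.counts.loc[h][t.counts.loc[h] > 0].to_dict())
    dist = {
        (a, b): _hamming_ignore_gaps(t.hap_seqs[a], t.hap_seqs[b])
        for a, b in itertools.combinations(haps, 2)
    }
    comp = {h: h for h in haps}  # union-find

    def find(x):
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    n_missing = 0
    n_reticulations = 0
    for d in range(1, limit + 1):
        at_d = [pair for pair, dd in dist.items() if dd == d]
        at_d.sort(
            key=lambda p: (
                -max(freq[p[0]], freq[p[1]]),
                -min(freq[p[0]], freq[p[1]]),
                p,
            )
        )
        for a, b in at_d:
            ra, rb = find(a), find(b)
            if ra == rb:
                if keep_reticulations and n_reticulations < max_reticulations:
                    try:
                        if nx.shortest_path_length(g, a, b) > d:
                            _link(g, a, b, d, n_missing)
                            n_missing += d - 1
                            n_reticulations += 1
                    except nx.NetworkXNoPath:
                        pass
                continue
            _link(g, a, b, d, n_missing)
            n_missing += d - 1
            comp[ra] = rb
    comps = [sorted(c) for c in nx.connected_components(g)]
    observed_comps = [
        [h for h in c if g.nodes[h]["count"] > 0] for c in comps
    ]
    subnetworks = sorted(
        (c for c in observed_comps if len(c) > 1), key=lambda c: c[0]
    )
    unplaced = sorted(
        itertools.chain.from_iterable(
            c for c in observed_comps if len(c) == 1
        )
    )
    return ParsimonyNetwork(graph=g, limit=limit, subnetworks=subnetworks,
                            unplaced=unplaced)


def _link(g: nx.Graph, a: str, b: str, d: int, n_missing: int) -> None:
    prev = a
    for k in range(d - 1):
        mid = f"m{n_missing + k + 1}"
        g.add_node(mid, count=0, demes={})
        g.add_edge(prev, mid, steps=1)
        prev = mid
    g.add_edge(prev, b, steps=1)


def write_edge_list(net: ParsimonyNetwork, path) -> None:
    """Edge list TSV with node attributes (haplotype, count, deme mix)."""
    import pandas as pd

    rows = [
        {
            "node_a": u,
            "node_b": v,
            "count_a": net.graph.nodes[u]["count"],
            "count_b": net.graph.nodes[v]["count"],
        }
        for u, v in net.graph.edges()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
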