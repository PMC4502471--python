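"""Probability-weighted centrality and global network topology.

Centrality is computed on the network thresholded at a working
probability cutoff (default 0.1, the adopted minimum for retained PPIs):

* **wDEG** — the sum of the probabilities of the edges incident to a
  protein.
* **wBET** — weighted betweenness: each retained edge carries traversal
  cost 1/P_in, and a protein's score is, over all unordered pairs
  (s, t), the fraction of minimum-cost s-t paths passing through it.

Statistical significance is assessed against Erdős–Rényi G(n, m) random
networks with the same node and edge counts, whose edges carry a random
permutation of the observed probability multiset. The empirical p-value
for a protein compares its observed score with the maximum per-node
score of each replicate (an add-one estimator, so p >= 1/(n_random+1)),
followed by Benjamini-Hochberg FDR per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, fdr_adjust
from .core import ProbabilisticNetwork

DEFAULT_CUTOFF = 0.1


def _weighted_graph(pnet: ProbabilisticNetwork, cutoff: float) -> nx.Graph:
    """Thresholded graph with pin weights and 1/pin traversal costs."""
    g = nx.Graph()
    g.add_nodes_from(pnet.protein_ids)
    ii, jj = np.nonzero(np.triu(pnet.pin, 1) >= cutoff)
    for i, j in zip(ii, jj):
        p = float(pnet.pin[i, j])
        g.add_edge(pnet.protein_ids[i], pnet.protein_ids[j],
                   pin=p, cost=1.0 / p)
    return g


# ---------------------------------------------------------------------------
# Per-protein centralities
# ---------------------------------------------------------------------------

def weighted_degree(pnet: ProbabilisticNetwork, i: str | None = None,
                    cutoff: float = DEFAULT_CUTOFF):
    """wDEG: sum of incident edge probabilities at the working cutoff.

    With ``i`` returns one protein's score; otherwise a dict for all.
    """
    W = np.where(pnet.pin >= cutoff, pnet.pin, 0.0)
    sums = W.sum(axis=1)
    if i is not None:
        return float(sums[pnet.index(i)])
    return {p: float(sums[k]) for k, p in enumerate(pnet.protein_ids)}


def weighted_betweenness(pnet: ProbabilisticNetwork, i: str | None = None,
                         cutoff: float = DEFAULT_CUTOFF):
    """wBET: minimum-cost-path betweenness with edge cost 1/P_in.

    Unnormalized: each unordered pair (s, t) contributes the fraction of
    co-minimal paths through the protein; unreachable pairs contribute 0.
    """
    if i is not None:
        pnet.index(i)  # raises on unknown protein
    g = _weighted_graph(pnet, cutoff)
    bc = nx.betweenness_centrality(g, normalized=False, weight="cost")
    if i is not None:
        return float(bc[i])
    return {p: float(v) for p, v in bc.items()}


# ---------------------------------------------------------------------------
# Global metrics
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    """Whole-network summary at one probability cutoff."""

    density: float
    centralization: float
    aspl: float | None          # mean minimum 1/P_in cost over reachable pairs
    reachable_fraction: float
    modularity: float | None = None

    def as_dict(self) -> dict:
        return {"density": self.density, "modularity": self.modularity,
                "centralization": self.centralization, "aspl": self.aspl,
                "reachable_fraction": self.reachable_fraction}


def global_metrics(pnet: ProbabilisticNetwork,
                   cutoff: float = DEFAULT_CUTOFF,
                   assign: ClusterAssignment | None = None) -> GlobalMetrics:
    """Density, Newman modularity, Freeman centralization, and weighted ASPL.

    Density is |E| / C(n, 2) at the cutoff. Modularity (unweighted, over
    the cluster assignment) is reported only when an assignment is given
    and the thresholded network has edges. ASPL averages the minimum
    1/P_in path cost over reachable pairs, with the reachable fraction
    reported alongside; it is None when no pair is reachable.
    """
    g = _weighted_graph(pnet, cutoff)
    n = g.number_of_nodes()
    m = g.number_of_edges()
    possible = n * (n - 1) / 2
    density = m / possible if possible else 0.0

    modularity = None
    if assign is not None and m > 0:
        communities = [members & set(g.nodes)
                       for members in assign.clusters().values()]
        communities = [c for c in communities if c]
        unassigned = set(g.nodes) - set().union(*communities) if communities else set(g.nodes)
        communities.extend({x} for x in sorted(unassigned))
        modularity = float(nx.community.modularity(g, communities))

    degrees = np.array([d for _, d in g.degree()], dtype=float)
    if n > 2:
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0

    total = 0.0
    reachable = 0
    for s, lengths in nx.all_pairs_dijkstra_path_length(g, weight="cost"):
        for t, cost in lengths.items():
            if t != s:
                total += cost
                reachable += 1
    reachable //= 2  # each unordered pair visited twice
    total /= 2.0
    aspl = (total / reachable) if reachable else None
    reachable_fraction = reachable / possible if possible else 0.0
    return GlobalMetrics(density=density, centralization=centralization,
                         aspl=aspl, reachable_fraction=reachable_fraction,
                         modularity=modularity)


# ---------------------------------------------------------------------------
# Empirical significance
# ---------------------------------------------------------------------------

def centrality_significance(pnet: ProbabilisticNetwork,
                            cutoff: float = DEFAULT_CUTOFF,
                            n_random: int = 1000,
                            seed: int | None = None) -> pd.DataFrame:
    """Empirical wDEG / wBET significance against Erdős–Rényi nulls.

    Each of ``n_random`` replicates is a G(n, m) graph with the same
    node and edge counts as the thresholded network, edge probabilities
    assigned by permuting the observed multiset. A protein's empirical
    p-value is the add-one fraction of replicates whose maximum per-node
    score reaches its observed score; q-values are BH-adjusted per
    metric and q_min = min(q_wdeg, q_wbet).
    """
    if n_random < 100:
        raise ValueError(f"n_random must be >= 100, got {n_random}")
    ids = pnet.protein_ids
    n = len(ids)
    g = _weighted_graph(pnet, cutoff)
    m = g.number_of_edges()
    if m > n * (n - 1) // 2:
        raise ValueError("infeasible G(n, m): more edges than pairs")
    weights = np.array([d["pin"] for _, _, d in g.edges(data=True)])

    obs_wdeg = np.array([weighted_degree(pnet, p, cutoff) for p in ids])
    bc = nx.betweenness_centrality(g, normalized=False, weight="cost")
    obs_wbet = np.array([bc[p] for p in ids])

    rng = np.random.default_rng(seed)
    max_wdeg = np.empty(n_random)
    max_wbet = np.empty(n_random)
    for r in range(n_random):
        gr = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        perm = rng.permutation(weights)
        assert gr.number_of_edges() == m
        for (u, v), w in zip(gr.edges, perm):
            gr.edges[u, v]["pin"] = float(w)
            gr.edges[u, v]["cost"] = 1.0 / float(w)
        wdeg_r = np.zeros(n)
        for u, v, d in gr.edges(data=True):
            wdeg_r[u] += d["pin"]
            wdeg_r[v] += d["pin"]
        bc_r = nx.betweenness_centrality(gr, normalized=False, weight="cost")
        max_wdeg[r] = wdeg_r.max() if n else 0.0
        max_wbet[r] = max(bc_r.values()) if bc_r else 0.0

    p_wdeg = (1 + (max_wdeg[None, :] >= obs_wdeg[:, None]).sum(axis=1)) / (1 + n_random)
    p_wbet = (1 + (max_wbet[None, :] >= obs_wbet[:, None]).sum(axis=1)) / (1 + n_random)
    q_wdeg = fdr_adjust(p_wdeg)
    q_wbet = fdr_adjust(p_wbet)
    return pd.DataFrame({
        "protein_id": ids,
        "wdeg": obs_wdeg, "wbet": obs_wbet,
        "p_wdeg": p_wdeg, "p_wbet": p_wbet,
        "q_wdeg": q_wdeg, "q_wbet": q_wbet,
        "q_min": np.minimum(q_wdeg, q_wbet),
    })
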