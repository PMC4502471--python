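"""Functional clusters (FCs), enrichment tests, and cluster connectivity.

Proteins are clustered by the similarity of their binding-probability
profiles: the distance between two proteins is 1 minus the Pearson
correlation of their P_in rows (self-probabilities excluded), and the
distance matrix is agglomerated with average linkage (UPGMA). Cluster x
functional-term enrichment uses the one-sided upper-tail hypergeometric
test with Benjamini-Hochberg FDR across all tests jointly. Cluster-
cluster connectivity C_IJ is the probability mass between two clusters
normalized by the total mass connecting either cluster to the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact as _scipy_fisher_exact
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import ProbabilisticNetwork

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cluster assignment
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """protein_id -> cluster_id (1..k) plus the merge history."""

    mapping: dict[str, int]
    k: int
    linkage_tree: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        labels = sorted(set(self.mapping.values()))
        if labels and labels != list(range(1, len(labels) + 1)):
            raise ValueError(f"cluster ids must be contiguous 1..k, got {labels}")

    def members(self, cluster_id: int) -> set[str]:
        return {p for p, c in self.mapping.items() if c == cluster_id}

    def clusters(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for p, c in self.mapping.items():
            out.setdefault(c, set()).add(p)
        return out

    def to_tsv(self, path) -> None:
        pd.DataFrame({"protein_id": list(self.mapping),
                      "cluster_id": list(self.mapping.values())}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
        mapping = dict(zip(df["protein_id"], df["cluster_id"].astype(int)))
        return cls(mapping, k=len(set(mapping.values())))


# ---------------------------------------------------------------------------
# Distances and hierarchical clustering
# ---------------------------------------------------------------------------

def profile_distance_matrix(pnet: ProbabilisticNetwork) -> np.ndarray:
    """Binding-profile distance d(i, j) = 1 - Pearson(row_i, row_j).

    Entries i and j are excluded from both rows before correlating: the
    diagonal self-probabilities are structural zeros, and the mutual
    entries would otherwise leak the pair's own score into its
    similarity. Pairs where either reduced profile is constant get
    distance 1 (logged once).
    """
    pin = pnet.pin
    n = pnet.n
    if n < 3:
        raise ValueError("profile distances need at least 3 proteins")
    dist = np.zeros((n, n))
    n_constant = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = np.ones(n, dtype=bool)
            mask[[i, j]] = False
            x = pin[i, mask]
            y = pin[j, mask]
            sx = x.std()
            sy = y.std()
            if sx == 0 or sy == 0:
                d = 1.0
                n_constant += 1
            else:
                r = float(np.dot(x - x.mean(), y - y.mean()) / (len(x) * sx * sy))
                d = 1.0 - max(-1.0, min(1.0, r))
            dist[i, j] = dist[j, i] = d
    if n_constant:
        logger.info("profile_distance_matrix: %d pair(s) with a constant profile "
                    "set to distance 1", n_constant)
    return dist


def hierarchical_clusters(dist: np.ndarray, k: int,
                          ids: list[str] | None = None) -> ClusterAssignment:
    """Average-linkage (UPGMA) agglomeration cut to exactly k clusters.

    Deterministic: scipy breaks distance ties by the smaller index.
    Cluster ids are relabeled contiguously (1..k) in order of first
    appearance along the input ordering.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must lie in [2, {n}], got {k}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return ClusterAssignment(dict(zip(ids, labels)), k=len(relabel), linkage_tree=tree)


def cluster_pnet(pnet: ProbabilisticNetwork, k: int) -> ClusterAssignment:
    """Cluster a probabilistic network's binding profiles into k FCs."""
    return hierarchical_clusters(profile_distance_matrix(pnet), k,
                                 ids=pnet.protein_ids)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentQuery:
    """Counts for one cluster x term test.

    N: proteins in the network; B: proteins with the term; n: proteins
    in the cluster; b: proteins in both.
    """

    N: int
    B: int
    n: int
    b: int

    def __post_init__(self) -> None:
        if not (0 <= self.b <= min(self.n, self.B) and self.n <= self.N
                and self.B <= self.N and self.n >= 0 and self.B >= 0):
            raise ValueError(f"inconsistent enrichment counts {self}")


def hypergeometric_enrichment(q: EnrichmentQuery) -> float:
    """One-sided upper-tail hypergeometric p-value (overlap >= b)."""
    return float(hypergeom.sf(q.b - 1, q.N, q.B, q.n))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    return float(_scipy_fisher_exact(table, alternative="two-sided")[1])


def enrich_clusters(assign: ClusterAssignment,
                    term_map: dict[str, set[str]],
                    q_max: float | None = None) -> pd.DataFrame:
    """Cluster x term hypergeometric enrichment with joint BH adjustment.

    The universe N is the set of assigned proteins; term memberships are
    intersected with it. With ``q_max`` (the display rule is q < 0.1)
    only rows below the threshold are returned.
    """
    universe = set(assign.mapping)
    N = len(universe)
    rows = []
    for cid, members in sorted(assign.clusters().items()):
        for term, annotated in sorted(term_map.items()):
            ann = annotated & universe
            q = EnrichmentQuery(N=N, B=len(ann), n=len(members),
                                b=len(ann & members))
            rows.append({"cluster_id": cid, "term_id": term, "b": q.b,
                         "n": q.n, "B": q.B, "N": q.N,
                         "p_value": hypergeometric_enrichment(q)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["q_value"] = fdr_adjust(df["p_value"])
    if q_max is not None:
        df = df[df["q_value"] < q_max].reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Cluster-cluster connectivity
# ---------------------------------------------------------------------------

def cluster_connectivity(pnet: ProbabilisticNetwork,
                         assign: ClusterAssignment,
                         I: int, J: int) -> float:
    """Normalized probability mass connecting clusters I and J.

    C_IJ = sum_{i in I, j in J} P_ij /
           [sum_{i in I, n in N} P_in + sum_{j in J, n in N} P_jn
            - sum_{i in I, j in J} P_ij]

    The cross mass appears in both row sums, so C_IJ lies in [0, 1] and
    is symmetric. A zero denominator (no probability mass touching
    either cluster) is defined as C_IJ = 0.
    """
    if I == J:
        raise ValueError("cluster connectivity is defined for distinct clusters")
    members_i = [pnet.index(p) for p in assign.members(I)]
    members_j = [pnet.index(p) for p in assign.members(J)]
    if not members_i or not members_j:
        raise ValueError(f"empty cluster in pair ({I}, {J})")
    cross = float(pnet.pin[np.ix_(members_i, members_j)].sum())
    total_i = float(pnet.pin[members_i, :].sum())
    total_j = float(pnet.pin[members_j, :].sum())
    denom = total_i + total_j - cross
    if denom == 0:
        return 0.0
    return cross / denom


def cluster_connectivity_table(pnet: ProbabilisticNetwork,
                               assign: ClusterAssignment) -> pd.DataFrame:
    """C_IJ for every unordered pair of clusters."""
    cids = sorted(assign.clusters())
    rows = []
    for a in range(len(cids)):
        for b in range(a + 1, len(cids)):
            rows.append({"cluster_i": cids[a], "cluster_j": cids[b],
                         "c_ij": cluster_connectivity(pnet, assign,
                                                      cids[a], cids[b])})
    return pd.DataFrame(rows)
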