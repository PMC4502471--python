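"""Bayesian posterior probability of direct interaction (P_in).

For every protein pair the model collects two pieces of evidence:

* **Transitivity T** — the Jaccard ratio of shared vs. exclusive
  third-party interaction partners in an evidence PPI network. A direct
  edge between the pair contributes nothing by itself, so predictions do
  not simply echo the input network.
* **Co-expression C** — the Pearson correlation of the two genes'
  expression profiles; pairs without usable profiles are treated as
  missing and scored from T alone.

Conditional likelihoods P(T|e) and P(C|e) are binned histograms fitted
on the edges of a trusted network (e = 1) versus a degree-preserving
decoy rewiring of it (e = 0), with Laplace smoothing. The posterior is
Bayes' rule under conditional independence of T and C given e:

    P_in = pi * P(T|1) P(C|1) / [pi * P(T|1) P(C|1) + (1-pi) * P(T|0) P(C|0)]
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import ExpressionMatrix, InteractionNetwork, ProbabilisticNetwork, ProteinCatalog

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairEvidence:
    """Transitivity and co-expression evidence for one unordered pair."""

    a: str
    b: str
    t: float
    c: float | None  # None = missing

    def __post_init__(self) -> None:
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"T must lie in [0, 1], got {self.t}")
        if self.c is not None and not -1.0 <= self.c <= 1.0:
            raise ValueError(f"C must lie in [-1, 1], got {self.c}")


def compute_transitivity(net: InteractionNetwork, a: str, b: str) -> float:
    """Shared / (shared + exclusive) third-party partners of a and b.

    With S = N(a) ∩ N(b) \\ {a, b} and X the exclusive third-party
    partners, returns |S| / (|S| + |X|), i.e. the Jaccard index of the
    two neighborhoods after removing the pair itself. Returns 0 when
    both reduced neighborhoods are empty.
    """
    if a == b:
        raise ValueError("transitivity is undefined for a pair with itself")
    for x in (a, b):
        if not net.has_node(x):
            raise KeyError(f"unknown protein {x!r}")
    na = net.neighbors(a) - {a, b}
    nb = net.neighbors(b) - {a, b}
    union = na | nb
    if not union:
        return 0.0
    return len(na & nb) / len(union)


def compute_coexpression(expr: ExpressionMatrix, a: str, b: str) -> float | None:
    """Pearson correlation of two expression profiles, or None if missing.

    Missing means: either gene absent from the matrix, or either profile
    has zero variance (correlation undefined).
    """
    if a not in expr or b not in expr:
        return None
    x = expr.profile(a)
    y = expr.profile(b)
    if np.std(x) == 0 or np.std(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against floating point spill just outside [-1, 1]
    return max(-1.0, min(1.0, r))


# ---------------------------------------------------------------------------
# Decoy network
# ---------------------------------------------------------------------------

def make_decoy_network(net: InteractionNetwork, seed: int | None = None) -> InteractionNetwork:
    """Degree-preserving rewiring via double-edge swaps (the e = 0 class).

    Attempts 10x|E| swaps: two edges (a, b) and (c, d) are replaced by
    (a, d) and (c, b) whenever that creates neither a self-loop nor a
    duplicate edge. The node set and the degree sequence are identical
    to the input; the result is a pure function of (net, seed). If no
    swap is possible (e.g. a star) the input is returned unchanged with
    a warning.
    """
    if net.n_edges < 2:
        raise ValueError("decoy rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    edges = net.edge_list()
    edge_set = set(map(frozenset, edges))
    m = len(edges)
    n_swapped = 0
    for _ in range(10 * m):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.integers(0, 2):
            a, b = b, a
        # propose a-d, c-b
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = tuple(sorted((a, d)))
        edges[j] = tuple(sorted((c, b)))
        n_swapped += 1
    if n_swapped == 0:
        warnings.warn("no double-edge swap was possible; decoy equals input network")
        return net.copy()
    return InteractionNetwork(nodes=net.nodes, edges=edges)


# ---------------------------------------------------------------------------
# Conditional model
# ---------------------------------------------------------------------------

@dataclass
class ConditionalModel:
    """Binned likelihoods P(T|e), P(C|e) for e in {0, 1} plus the class prior.

    ``lik_t`` and ``lik_c`` have shape (2, n_bins); row index is the
    class e. Each row sums to 1. ``c_enabled`` is False when no usable
    co-expression was available at fit time, in which case the C channel
    is ignored at scoring time.
    """

    t_edges: np.ndarray
    c_edges: np.ndarray
    lik_t: np.ndarray
    lik_c: np.ndarray
    prior: float
    smoothing: float
    c_enabled: bool = True

    def __post_init__(self) -> None:
        self.t_edges = np.asarray(self.t_edges, dtype=float)
        self.c_edges = np.asarray(self.c_edges, dtype=float)
        self.lik_t = np.asarray(self.lik_t, dtype=float)
        self.lik_c = np.asarray(self.lik_c, dtype=float)
        if not 0.0 < self.prior < 1.0:
            raise ValueError(f"prior must lie in (0, 1), got {self.prior}")
        for name, lik in (("lik_t", self.lik_t), ("lik_c", self.lik_c)):
            if np.any(np.abs(lik.sum(axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if np.any(lik <= 0):
                raise ValueError(f"{name} has empty bin mass; use smoothing > 0")

    @staticmethod
    def _bin_index(x, edges) -> np.ndarray:
        idx = np.searchsorted(edges, np.asarray(x, dtype=float), side="right") - 1
        return np.clip(idx, 0, len(edges) - 2)

    def t_likelihood(self, t, e: int) -> np.ndarray:
        return self.lik_t[e][self._bin_index(t, self.t_edges)]

    def c_likelihood(self, c, e: int) -> np.ndarray:
        return self.lik_c[e][self._bin_index(c, self.c_edges)]

    # -- serialization (audit trail for the CLI) --------------------------
    def to_json(self, path) -> None:
        payload = {
            "t_edges": self.t_edges.tolist(),
            "c_edges": self.c_edges.tolist(),
            "lik_t": self.lik_t.tolist(),
            "lik_c": self.lik_c.tolist(),
            "prior": self.prior,
            "smoothing": self.smoothing,
            "c_enabled": self.c_enabled,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConditionalModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(**payload)


def _smoothed_hist(values: np.ndarray, edges: np.ndarray, smoothing: float) -> np.ndarray:
    counts, _ = np.histogram(values, bins=edges)
    counts = counts.astype(float) + smoothing
    total = counts.sum()
    if total == 0:
        raise ValueError("cannot normalize an all-zero histogram; use smoothing > 0")
    return counts / total


def fit_conditional_models(true_net: InteractionNetwork,
                           expr: ExpressionMatrix | None,
                           t_bins: int = 20,
                           c_bins: int = 40,
                           smoothing: float = 1.0,
                           prior: float | str = "auto",
                           seed: int | None = None) -> ConditionalModel:
    """Fit P(T|e) and P(C|e) on a trusted network vs. its decoy.

    The e = 1 sample is every edge of ``true_net``; the e = 0 sample is
    every edge of a degree-preserving decoy. Transitivity is evaluated
    on ``true_net`` for both samples, so the two classes are compared at
    matched degrees. Pairs with missing co-expression are excluded from
    the C histograms only. ``prior="auto"`` uses the training edge
    density |E| / C(n, 2).
    """
    if true_net.n_edges == 0:
        raise ValueError("cannot fit conditional models on an empty network")
    t_edges = np.linspace(0.0, 1.0, t_bins + 1)
    c_edges = np.linspace(-1.0, 1.0, c_bins + 1)

    decoy = make_decoy_network(true_net, seed=seed)
    samples = {1: true_net.edge_list(), 0: decoy.edge_list()}

    lik_t = np.empty((2, t_bins))
    lik_c = np.empty((2, c_bins))
    c_enabled = True
    c_values: dict[int, np.ndarray] = {}
    for e, pairs in samples.items():
        t_vals = np.array([compute_transitivity(true_net, a, b) for a, b in pairs])
        lik_t[e] = _smoothed_hist(t_vals, t_edges, smoothing)
        if expr is not None:
            cv = [compute_coexpression(expr, a, b) for a, b in pairs]
            c_values[e] = np.array([c for c in cv if c is not None])
        else:
            c_values[e] = np.array([])
    if any(len(c_values[e]) == 0 for e in (0, 1)):
        c_enabled = False
        logger.warning("no usable co-expression in one or both classes; "
                       "C channel disabled (T-only model)")
        lik_c[:] = 1.0 / c_bins
    else:
        for e in (0, 1):
            lik_c[e] = _smoothed_hist(c_values[e], c_edges, smoothing)

    if prior == "auto":
        n = true_net.n_nodes
        pi = true_net.n_edges / (n * (n - 1) / 2)
    else:
        pi = float(prior)
    if not 0.0 < pi < 1.0:
        raise ValueError(f"prior must lie in (0, 1), got {pi}")
    return ConditionalModel(t_edges, c_edges, lik_t, lik_c, pi, smoothing,
                            c_enabled=c_enabled)


# ---------------------------------------------------------------------------
# Posterior
# ---------------------------------------------------------------------------

def _posterior(t, c, c_missing, model: ConditionalModel):
    """Vectorized Bayes posterior; ``c_missing`` marks T-only pairs."""
    num = model.prior * model.t_likelihood(t, 1)
    den = (1.0 - model.prior) * model.t_likelihood(t, 0)
    if model.c_enabled:
        c_filled = np.where(c_missing, 0.0, np.asarray(c, dtype=float))
        f1 = np.where(c_missing, 1.0, model.c_likelihood(c_filled, 1))
        f0 = np.where(c_missing, 1.0, model.c_likelihood(c_filled, 0))
        num = num * f1
        den = den * f0
    return num / (num + den)


def posterior_pin(ev: PairEvidence, model: ConditionalModel) -> float:
    """P_in for one pair; a missing C falls back to T-only evidence."""
    missing = ev.c is None or not model.c_enabled
    return float(_posterior(np.asarray([ev.t]),
                            np.asarray([0.0 if ev.c is None else ev.c]),
                            np.asarray([missing]), model)[0])


def score_pair(net: InteractionNetwork, expr: ExpressionMatrix | None,
               model: ConditionalModel, a: str, b: str) -> float:
    """Convenience: evidence extraction plus posterior for one pair."""
    t = compute_transitivity(net, a, b)
    c = compute_coexpression(expr, a, b) if expr is not None else None
    return posterior_pin(PairEvidence(a, b, t, c), model)


# ---------------------------------------------------------------------------
# All-pairs scoring
# ---------------------------------------------------------------------------

def _transitivity_matrix(net: InteractionNetwork, ids: list[str]) -> np.ndarray:
    """All-pairs transitivity for ``ids``, using every evidence-network node
    (catalog or not) as a potential third party."""
    order = list(ids) + sorted(net.nodes - set(ids))
    g = net.to_networkx()
    g.add_nodes_from(order)
    A = nx.to_numpy_array(g, nodelist=order, dtype=float)
    k = len(ids)
    deg = A.sum(axis=1)
    shared = (A @ A)[:k, :k]  # common third-party partners (no self-edges)
    Ak = A[:k, :k]
    di = deg[:k, None] - Ak
    dj = deg[None, :k] - Ak
    union = di + dj - shared
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(union > 0, shared / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(T, 0.0)
    return T


def _coexpression_matrix(expr: ExpressionMatrix | None, ids: list[str]):
    """All-pairs Pearson correlation; returns (C, missing mask)."""
    k = len(ids)
    C = np.zeros((k, k))
    missing = np.ones((k, k), dtype=bool)
    if expr is None:
        return C, missing
    present = [i for i, g in enumerate(ids) if g in expr]
    if not present:
        return C, missing
    X = np.vstack([expr.profile(ids[i]) for i in present])
    sd = X.std(axis=1)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - X[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
    R = (Z @ Z.T) / X.shape[1]
    np.clip(R, -1.0, 1.0, out=R)
    pos = np.array(present)
    usable = np.array(ok)
    sub_missing = ~(usable[:, None] & usable[None, :])
    C[np.ix_(pos, pos)] = np.where(sub_missing, 0.0, R)
    missing[np.ix_(pos, pos)] = sub_missing
    return C, missing


def build_ps_network(catalog: ProteinCatalog | list[str],
                     evidence_net: InteractionNetwork,
                     expr: ExpressionMatrix | None,
                     model: ConditionalModel) -> ProbabilisticNetwork:
    """Score P_in for every unordered pair of catalog proteins.

    Proteins absent from the evidence network have empty neighborhoods
    (T = 0); pairs without co-expression are scored from T alone. The
    result is an exactly symmetric matrix with a zero diagonal holding
    n(n-1)/2 informative scores.
    """
    ids = catalog.ids if isinstance(catalog, ProteinCatalog) else list(catalog)
    if len(ids) < 2:
        raise ValueError("catalog must contain at least 2 proteins")
    T = _transitivity_matrix(evidence_net, ids)
    C, missing = _coexpression_matrix(expr, ids)
    P = _posterior(T, C, missing, model)
    P = np.triu(P, 1)
    P = P + P.T
    return ProbabilisticNetwork(ids, P)
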