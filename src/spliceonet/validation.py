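"""Cross-validation of probabilistic vs. deterministic PPI prediction.

Positives are the direct edges of a test network; negatives are protein
pairs in different connected components of it (shortest path length
diverges, so neither a direct nor an indirect interaction is expected).
Reachable non-adjacent pairs belong to neither set and are excluded
from scoring. Predictions are compared through sensitivity, specificity
and Matthews' correlation coefficient:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 (flagged) when any marginal in the denominator
vanishes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import InteractionNetwork, ProbabilisticNetwork

Pair = frozenset


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class ValidationReport:
    """Confusion counts and derived metrics at one decision threshold."""

    threshold: float | None
    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    mcc: float
    mcc_degenerate: bool = False
    unknown_pairs: int = 0  # pairs with a protein the predictor never saw


def matthews_cc(c: ConfusionCounts) -> tuple[float, bool]:
    """MCC from the printed formula; degenerate tables give (0, True)."""
    tp, tn, fp, fn = c.TP, c.TN, c.FP, c.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0, True
    return (tp * tn - fp * fn) / math.sqrt(denom), False


def build_pos_neg_sets(test_net: InteractionNetwork) -> tuple[set, set]:
    """Positive pairs (direct edges) and negative pairs (cross-component).

    Negative pairs are unreachable from each other (path length diverges);
    reachable non-adjacent pairs are deliberately in neither set.
    """
    if test_net.n_nodes == 0:
        raise ValueError("empty test network")
    positives = set(test_net.edges)
    g = test_net.to_networkx()
    comps = [sorted(c) for c in nx.connected_components(g)]
    negatives: set = set()
    for a in range(len(comps)):
        for b in range(a + 1, len(comps)):
            for u in comps[a]:
                for v in comps[b]:
                    negatives.add(Pair((u, v)))
    if not negatives:
        warnings.warn("test network is a single connected component; "
                      "negative set is empty")
    return positives, negatives


def _predictor(pred, threshold):
    if isinstance(pred, ProbabilisticNetwork):
        if threshold is None:
            raise ValueError("a probabilistic predictor requires a threshold")

        def predict(pair):
            a, b = tuple(pair)
            if a not in pred or b not in pred:
                return False, True
            return pred.get(a, b) >= threshold, False
    else:
        def predict(pair):
            a, b = tuple(pair)
            known = pred.has_node(a) and pred.has_node(b)
            return (known and pred.has_edge(a, b)), not known
    return predict


def evaluate_predictions(pred, positives: set, negatives: set,
                         threshold: float | None = None) -> ValidationReport:
    """Score a predictor against positive/negative pair sets.

    A :class:`ProbabilisticNetwork` predicts "interacts" iff
    P_in >= threshold; an :class:`InteractionNetwork` predicts exactly
    its edges. Pairs containing a protein unknown to the predictor are
    scored as negative predictions and counted in ``unknown_pairs``.
    """
    positives = {Pair(p) for p in positives}
    negatives = {Pair(p) for p in negatives}
    if not positives or not negatives:
        raise ValueError("positive and negative sets must both be nonempty")
    if positives & negatives:
        raise ValueError("positive and negative sets overlap")
    predict = _predictor(pred, threshold)
    tp = fn = fp = tn = unknown = 0
    for pair in positives:
        hit, unk = predict(pair)
        unknown += unk
        tp += hit
        fn += not hit
    for pair in negatives:
        hit, unk = predict(pair)
        unknown += unk
        fp += hit
        tn += not hit
    counts = ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    mcc, degenerate = matthews_cc(counts)
    return ValidationReport(threshold=threshold, counts=counts,
                            sensitivity=sens, specificity=spec, mcc=mcc,
                            mcc_degenerate=degenerate, unknown_pairs=unknown)


def holdout_training_network(train_net: InteractionNetwork,
                             test_net: InteractionNetwork) -> InteractionNetwork:
    """Training network with every test edge removed (node set unchanged).

    Direct test PPIs are withheld so that only neighboring PPIs remain
    as evidence for probabilistic prediction.
    """
    shared = train_net.edges & test_net.edges
    kept = [tuple(sorted(e)) for e in train_net.edges - shared]
    return InteractionNetwork(nodes=train_net.nodes, edges=kept)


def residual_comparison(pnet_with: ProbabilisticNetwork,
                        pnet_without: ProbabilisticNetwork,
                        eps: float = 0.1) -> tuple[float, int]:
    """Per-pair |P_with - P_without| residual summary.

    Returns (fraction of pairs with residual < eps, count of pairs with
    residual >= eps). At eps = 0 the fraction counts exact equality and
    the count covers strictly nonzero residuals.
    """
    if pnet_with.protein_ids != pnet_without.protein_ids:
        raise ValueError("protein orderings differ")
    iu = np.triu_indices(pnet_with.n, k=1)
    res = np.abs(pnet_with.pin - pnet_without.pin)[iu]
    if eps == 0:
        return float(np.mean(res == 0)), int(np.sum(res > 0))
    return float(np.mean(res < eps)), int(np.sum(res >= eps))
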