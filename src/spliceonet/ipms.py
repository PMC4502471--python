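"""IP-MS peptide-count scoring and overlay on the probabilistic network.

Per-protein enrichment of an inducible-bait immunoprecipitation is
scored from unique peptide counts as

    logE = log2(P_dox+ / (P_dox- + 1))

where the pseudo-count in the denominator accommodates proteins below
detection without induction. A ligand is *enriched* when logE is
strictly greater than 1, which simultaneously guarantees a two-fold
ratio and at least three supporting peptides when the uninduced count
is zero. Replicates are pooled by summing peptide counts before
scoring. Ligands are then partitioned into nuclease-resistant (nucR:
enriched with nuclease, i.e. RNA-independent), nuclease-sensitive
(nucS: enriched only without nuclease, i.e. RNA-bridged) and undetected
classes, and compared against the probabilistic network through P_in
distributions, bait path proximity, per-cluster regression, and an
all-member protein-complex screen.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu

from .clustering import ClusterAssignment
from .core import ProbabilisticNetwork
from .topology import _weighted_graph

logger = logging.getLogger(__name__)

CONDITIONS = ("nuclease", "no_nuclease")
LOGE_CUTOFF = 1.0  # strict: enriched iff logE > 1


# ---------------------------------------------------------------------------
# logE scoring
# ---------------------------------------------------------------------------

def compute_logE(p_plus: int, p_minus: int) -> float:
    """log2(P_dox+ / (P_dox- + 1)); zero induced counts give -inf."""
    if p_plus < 0 or p_minus < 0:
        raise ValueError("peptide counts must be non-negative")
    if p_plus == 0:
        return float("-inf")
    return math.log2(p_plus / (p_minus + 1))


def is_enriched(p_plus: int, p_minus: int) -> bool:
    """Strict logE > 1 rule (guarantees >=3 peptides at p_minus = 0)."""
    return compute_logE(p_plus, p_minus) > LOGE_CUTOFF


@dataclass(frozen=True)
class IpmsRecord:
    """One bait-ligand observation in one condition (replicates pooled)."""

    bait: str
    ligand: str
    condition: str
    p_dox_plus: int
    p_dox_minus: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.p_dox_plus < 0 or self.p_dox_minus < 0:
            raise ValueError("peptide counts must be non-negative")

    @property
    def logE(self) -> float:
        return compute_logE(self.p_dox_plus, self.p_dox_minus)

    @property
    def enriched(self) -> bool:
        return self.logE > LOGE_CUTOFF


@dataclass
class LigandSet:
    """Exhaustive, disjoint partition of the catalog around one bait."""

    bait: str
    nucR: set[str] = field(default_factory=set)
    nucS: set[str] = field(default_factory=set)
    undetected: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.nucR & self.nucS:
            raise ValueError("nucR and nucS overlap")
        for group in (self.nucR, self.nucS, self.undetected):
            if self.bait in group:
                raise ValueError("bait cannot be its own ligand")

    @property
    def ligands(self) -> set[str]:
        return self.nucR | self.nucS


def select_enriched(records: pd.DataFrame, catalog_ids) -> LigandSet:
    """Partition catalog proteins into nucR / nucS / undetected for one bait.

    ``records`` columns: bait, ligand, condition, replicate, p_dox_plus,
    p_dox_minus. Replicate counts are summed per (ligand, condition)
    before scoring. A ligand is nucR when enriched under nuclease
    treatment (regardless of the no-nuclease outcome) and nucS when
    enriched only without nuclease. Rows listing the bait as its own
    ligand are removed with a warning.
    """
    baits = set(records["bait"].astype(str))
    if len(baits) != 1:
        raise ValueError(f"expected a single bait, got {sorted(baits)}")
    bait = baits.pop()
    catalog_ids = set(map(str, catalog_ids))
    df = records.copy()
    df["ligand"] = df["ligand"].astype(str)
    self_rows = df["ligand"] == bait
    if self_rows.any():
        warnings.warn(f"removed {int(self_rows.sum())} row(s) listing bait "
                      f"{bait!r} as its own ligand")
        df = df[~self_rows]
    pooled = df.groupby(["ligand", "condition"], as_index=False)[
        ["p_dox_plus", "p_dox_minus"]].sum()
    enriched: dict[str, set[str]] = {c: set() for c in CONDITIONS}
    for _, row in pooled.iterrows():
        if row["condition"] not in CONDITIONS:
            raise ValueError(f"unknown condition {row['condition']!r}")
        if is_enriched(int(row["p_dox_plus"]), int(row["p_dox_minus"])):
            enriched[row["condition"]].add(row["ligand"])
    nucR = enriched["nuclease"]
    nucS = enriched["no_nuclease"] - nucR
    undetected = catalog_ids - nucR - nucS - {bait}
    return LigandSet(bait=bait, nucR=nucR, nucS=nucS, undetected=undetected)


# ---------------------------------------------------------------------------
# Overlay statistics
# ---------------------------------------------------------------------------

def _group_pins(pnet: ProbabilisticNetwork, bait: str, group) -> np.ndarray:
    return np.array([pnet.get(bait, p) for p in sorted(group) if p in pnet])


def pin_distribution_overlay(pnet: ProbabilisticNetwork, bait: str,
                             ligset: LigandSet,
                             bins=None) -> dict:
    """Per-interval P_in proportions of nucR / nucS / undetected proteins.

    Each group's histogram over the P_in intervals is normalized by the
    group's size (proportions sum to 1). Bait-ligand P_in values of each
    ligand group are compared with the undetected group by a two-sided
    Mann-Whitney U test; empty groups are skipped and flagged.
    """
    if bait not in pnet:
        raise KeyError(f"bait {bait!r} not in network")
    if bins is None:
        bins = np.linspace(0.0, 1.0, 11)
    bins = np.asarray(bins, dtype=float)
    values = {"nucR": _group_pins(pnet, bait, ligset.nucR),
              "nucS": _group_pins(pnet, bait, ligset.nucS),
              "undetected": _group_pins(pnet, bait, ligset.undetected)}
    proportions = {}
    for name, vals in values.items():
        counts, _ = np.histogram(np.clip(vals, bins[0], bins[-1]), bins=bins)
        proportions[name] = counts / len(vals) if len(vals) else counts.astype(float)
    table = pd.DataFrame(proportions, index=pd.IntervalIndex.from_breaks(bins))
    p_values: dict[str, float | None] = {}
    skipped = []
    for name in ("nucR", "nucS"):
        if len(values[name]) == 0 or len(values["undetected"]) == 0:
            p_values[name] = None
            skipped.append(name)
        else:
            p_values[name] = float(mannwhitneyu(
                values[name], values["undetected"],
                alternative="two-sided").pvalue)
    return {"proportions": table, "p_values": p_values,
            "group_values": values, "skipped": skipped}


def bait_proximity(pnet: ProbabilisticNetwork, bait: str, ligset: LigandSet,
                   cutoff: float = 0.1) -> dict:
    """Minimum-cost (1/P_in) path lengths from the bait to each group.

    Returns per-group path lengths, means, unreachable counts, and
    two-sided Mann-Whitney p-values of each ligand group vs. the
    undetected proteins.
    """
    if bait not in pnet:
        raise KeyError(f"bait {bait!r} not in network")
    g = _weighted_graph(pnet, cutoff)
    if g.degree(bait) == 0:
        raise ValueError(f"bait {bait!r} is isolated at cutoff {cutoff}")
    lengths = nx.single_source_dijkstra_path_length(g, bait, weight="cost")
    out: dict = {"lengths": {}, "means": {}, "unreachable": {}, "p_values": {}}
    for name, group in (("nucR", ligset.nucR), ("nucS", ligset.nucS),
                        ("undetected", ligset.undetected)):
        vals = [lengths[p] for p in sorted(group) if p in lengths and p != bait]
        out["lengths"][name] = np.array(vals)
        out["means"][name] = float(np.mean(vals)) if vals else None
        out["unreachable"][name] = sum(1 for p in group if p not in lengths)
    und = out["lengths"]["undetected"]
    for name in ("nucR", "nucS"):
        vals = out["lengths"][name]
        if len(vals) == 0 or len(und) == 0:
            out["p_values"][name] = None
        else:
            out["p_values"][name] = float(mannwhitneyu(
                vals, und, alternative="two-sided").pvalue)
    return out


@dataclass
class FcRegression:
    """OLS fit of observed vs. expected per-cluster ligand proportions."""

    r_squared: float
    slope: float
    intercept: float
    points: pd.DataFrame


def fc_regression(pnet: ProbabilisticNetwork, assign: ClusterAssignment,
                  ligset: LigandSet, cutoff: float = 0.1) -> FcRegression:
    """Regress observed IP-MS ligand proportions on network expectations.

    Expected: per functional cluster, the proportion of catalog proteins
    with bait P_in >= cutoff. Observed: per cluster, the proportion of
    IP-MS ligands (nucR plus nucS). Both series sum to 1 over clusters;
    the fit is ordinary least squares and R^2 is reported. Invariant to
    cluster relabeling.
    """
    bait = ligset.bait
    if bait not in pnet:
        raise KeyError(f"bait {bait!r} not in network")
    clusters = assign.clusters()
    expected_counts = {}
    observed_counts = {}
    for cid, members in clusters.items():
        members = members - {bait}
        expected_counts[cid] = sum(1 for p in members
                                   if p in pnet and pnet.get(bait, p) >= cutoff)
        observed_counts[cid] = len(members & ligset.ligands)
    tot_exp = sum(expected_counts.values())
    tot_obs = sum(observed_counts.values())
    if tot_exp == 0 or tot_obs == 0:
        raise ValueError("no expected or observed interactions at this cutoff")
    rows = [{"cluster_id": cid,
             "expected": expected_counts[cid] / tot_exp,
             "observed": observed_counts[cid] / tot_obs}
            for cid in sorted(clusters)]
    points = pd.DataFrame(rows)
    informative = points[(points["expected"] > 0) | (points["observed"] > 0)]
    if len(informative) < 3:
        raise ValueError("need at least 3 clusters with data for a regression")
    fit = linregress(points["expected"], points["observed"])
    return FcRegression(r_squared=float(fit.rvalue ** 2),
                        slope=float(fit.slope),
                        intercept=float(fit.intercept), points=points)


def complex_screen(complexes: dict[str, set[str]],
                   pnet: ProbabilisticNetwork, bait: str,
                   cutoff: float = 0.1) -> pd.DataFrame:
    """Rank protein complexes by bait P_in coverage of their members.

    For each complex: member count (members present in the network,
    excluding the bait itself), the count passing P_in(bait, member) >=
    cutoff, min/max member P_in, and a full-coverage flag when every
    member passes. Sorted by coverage fraction, then member count.
    """
    if bait not in pnet:
        raise KeyError(f"bait {bait!r} not in network")
    rows = []
    for name, members in complexes.items():
        present = sorted(m for m in members if m in pnet and m != bait)
        pins = np.array([pnet.get(bait, m) for m in present])
        n_pass = int((pins >= cutoff).sum()) if len(pins) else 0
        rows.append({
            "complex_id": name,
            "n_members": len(present),
            "n_pass": n_pass,
            "min_pin": float(pins.min()) if len(pins) else float("nan"),
            "max_pin": float(pins.max()) if len(pins) else float("nan"),
            "coverage": n_pass / len(present) if present else 0.0,
            "full_coverage": bool(present) and n_pass == len(present),
        })
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["coverage", "n_members"],
                            ascending=[False, False]).reset_index(drop=True)
    return df
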