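"""Seeded synthetic benchmarks with planted structure.

The generator emulates the data the toolkit consumes from real studies:

* a **true interactome** drawn from a planted-partition model (dense
  within functional modules, sparse across), standing in for the
  curated PPI databases;
* an **expression matrix** whose genes load on per-module latent
  factors, so co-module pairs are co-expressed, standing in for a
  microarray compendium;
* an **observed network** obtained by degrading the truth with false
  negatives (undersampling) and false positives (spurious PPIs), as in
  yeast two-hybrid surveys;
* **IP-MS peptide-count tables** for a bait whose planted ligands are
  drawn preferentially from high-probability partners, with
  overdispersed (negative-binomial) counts; nuclease-condition ligands
  come from direct partners and no-nuclease ligands additionally from
  two-hop partners, mimicking RNA bridging.

Every output is a pure function of (spec, seed): generators derive
independent streams from the spec seed with fixed salts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, InteractionNetwork, ProbabilisticNetwork, Protein, ProteinCatalog

# stream salts: independent RNG substreams per generator
_SALT_NET, _SALT_EXPR, _SALT_DEGRADE, _SALT_IPMS = 101, 202, 303, 404


@dataclass
class BenchmarkSpec:
    """Study conditions for one synthetic benchmark.

    Defaults define a 120-protein, 6-module interactome with intra- and
    inter-module edge probabilities 0.35 / 0.02, 30 expression samples,
    15 % false-positive and false-negative degradation of the observed
    network, and an IP-MS experiment with 8x peptide enrichment of true
    ligands over a baseline of ~2 unique peptides.
    """

    n_proteins: int = 120
    n_modules: int = 6
    p_intra: float = 0.35
    p_inter: float = 0.02
    n_samples: int = 30
    coexpr_effect: float = 1.0
    noise_sd: float = 0.5
    fp_rate: float = 0.15
    fn_rate: float = 0.15
    bait_id: str | None = None  # default: first protein
    n_ligands: int = 12
    n_ligands_2hop: int = 6
    ligand_enrichment: float = 8.0
    baseline_mean: float = 2.0
    dispersion: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_inter", "fp_rate", "fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.n_modules < 1 or self.n_proteins < self.n_modules:
            raise ValueError("need n_proteins >= n_modules >= 1")

    def protein_ids(self) -> list[str]:
        width = len(str(self.n_proteins))
        return [f"P{i:0{width}d}" for i in range(1, self.n_proteins + 1)]

    @property
    def bait(self) -> str:
        return self.bait_id if self.bait_id is not None else self.protein_ids()[0]


def _rng(spec_seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng([int(spec_seed), salt])


def module_labels(spec: BenchmarkSpec) -> dict[str, int]:
    """Planted module of each protein (modules 1..n_modules, contiguous blocks)."""
    ids = spec.protein_ids()
    return {p: (i * spec.n_modules) // spec.n_proteins + 1
            for i, p in enumerate(ids)}


def generate_catalog(spec: BenchmarkSpec) -> ProteinCatalog:
    """Catalog whose functional terms mirror the planted modules."""
    labels = module_labels(spec)
    return ProteinCatalog(
        Protein(protein_id=p, functional_terms=frozenset({f"module_{m}"}))
        for p, m in labels.items())


def generate_true_interactome(spec: BenchmarkSpec
                              ) -> tuple[InteractionNetwork, dict[str, int]]:
    """Planted-partition graph: P(edge) = p_intra within a module, p_inter across."""
    ids = spec.protein_ids()
    labels = module_labels(spec)
    rng = _rng(spec.seed, _SALT_NET)
    net = InteractionNetwork(nodes=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            p = spec.p_intra if labels[ids[i]] == labels[ids[j]] else spec.p_inter
            if rng.random() < p:
                net.add_edge(ids[i], ids[j])
    return net, labels


def generate_expression(true_net: InteractionNetwork,
                        labels: dict[str, int],
                        spec: BenchmarkSpec) -> ExpressionMatrix:
    """Module-factor expression: gene = effect * module factor + noise.

    Co-module pairs share a latent factor and therefore correlate with
    expected r = effect^2 / (effect^2 + noise_sd^2); cross-module pairs
    are uncorrelated in expectation.
    """
    ids = spec.protein_ids()
    rng = _rng(spec.seed, _SALT_EXPR)
    factors = {m: rng.normal(size=spec.n_samples)
               for m in sorted(set(labels.values()))}
    values = np.vstack([
        spec.coexpr_effect * factors[labels[p]]
        + rng.normal(scale=spec.noise_sd, size=spec.n_samples)
        for p in ids])
    samples = [f"S{k:02d}" for k in range(1, spec.n_samples + 1)]
    return ExpressionMatrix(ids, samples, values)


def degrade_interactome(true_net: InteractionNetwork, fp_rate: float,
                        fn_rate: float, seed: int) -> InteractionNetwork:
    """Observed network: drop each true edge w.p. fn_rate, add each
    non-edge w.p. fp_rate (seeded, node set preserved)."""
    for name, v in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    rng = _rng(seed, _SALT_DEGRADE)
    ids = sorted(true_net.nodes)
    out = InteractionNetwork(nodes=ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if true_net.has_edge(a, b):
                if rng.random() >= fn_rate:
                    out.add_edge(a, b)
            elif rng.random() < fp_rate:
                out.add_edge(a, b)
    return out


def true_pin_network(true_net: InteractionNetwork,
                     hit_probability: float = 0.9) -> ProbabilisticNetwork:
    """Idealized probabilistic network of the ground truth.

    True edges carry ``hit_probability``, everything else 0. IP-MS
    ligands are planted from this network — co-purification reflects
    real physical binding, not the analyst's estimate of it — and then
    overlaid on the estimated network.
    """
    ids = sorted(true_net.nodes)
    idx = {p: i for i, p in enumerate(ids)}
    pin = np.zeros((len(ids), len(ids)))
    for a, b in true_net.edge_list():
        pin[idx[a], idx[b]] = pin[idx[b], idx[a]] = hit_probability
    return ProbabilisticNetwork(ids, pin)


def _negbin(rng: np.random.Generator, mean: float, dispersion: float,
            size: int) -> np.ndarray:
    """Negative binomial draws in (mean, dispersion) parameterization;
    variance = mean + mean^2 / dispersion."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def generate_ipms_counts(pnet: ProbabilisticNetwork, bait: str,
                         spec: BenchmarkSpec,
                         cutoff: float = 0.1,
                         n_replicates: int = 2
                         ) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Synthetic IP-MS count table plus ground-truth ligand labels.

    True nuclease-condition ligands are sampled (without replacement,
    probability proportional to P_in(bait, .)) from the bait's direct
    partners at ``cutoff``; the no-nuclease condition additionally
    recruits two-hop partners (RNA-bridged). True ligands draw induced
    counts with mean ligand_enrichment * baseline_mean; everything else
    is symmetric baseline noise. Counts are overdispersed negative
    binomials; two replicates by default.
    """
    if bait not in pnet:
        raise KeyError(f"bait {bait!r} not in network")
    rng = _rng(spec.seed, _SALT_IPMS)
    bi = pnet.index(bait)
    ids = pnet.protein_ids
    pins = pnet.pin[bi]
    direct = [p for p in ids if p != bait and pnet.get(bait, p) >= cutoff]

    def sample_weighted(pool: list[str], k: int) -> set[str]:
        if not pool or k <= 0:
            return set()
        w = np.array([max(pins[pnet.index(p)], 1e-12) for p in pool])
        k = min(k, len(pool))
        chosen = rng.choice(len(pool), size=k, replace=False, p=w / w.sum())
        return {pool[i] for i in chosen}

    nuc_r_true = sample_weighted(direct, spec.n_ligands)
    # two-hop partners: neighbors-of-neighbors at the cutoff, minus direct
    two_hop: set[str] = set()
    for d in direct:
        two_hop.update(p for p in ids
                       if p not in (bait, d) and pnet.get(d, p) >= cutoff)
    two_hop -= set(direct)
    nuc_s_true = sample_weighted(sorted(two_hop - nuc_r_true), spec.n_ligands_2hop)

    truth = {"nucR": nuc_r_true, "nucS": nuc_s_true}
    ligands_by_condition = {"nuclease": nuc_r_true,
                            "no_nuclease": nuc_r_true | nuc_s_true}
    base = spec.baseline_mean
    hot = spec.ligand_enrichment * base
    rows = []
    for protein in ids:
        if protein == bait:
            continue
        for condition in ("nuclease", "no_nuclease"):
            is_ligand = protein in ligands_by_condition[condition]
            mean_plus = hot if is_ligand else base
            plus = _negbin(rng, mean_plus, spec.dispersion, n_replicates)
            minus = _negbin(rng, base, spec.dispersion, n_replicates)
            for rep in range(1, n_replicates + 1):
                rows.append({"bait": bait, "ligand": protein,
                             "condition": condition, "replicate": rep,
                             "p_dox_plus": int(plus[rep - 1]),
                             "p_dox_minus": int(minus[rep - 1])})
    return pd.DataFrame(rows), truth


# survey qualities for the cross-validation benchmark: the test survey is a
# sparse two-hybrid-like screen (heavy undersampling, few spurious hits);
# the training survey emulates a curated interaction database (nearly
# complete, low false-positive rate)
TEST_SURVEY = {"fp_rate": 0.002, "fn_rate": 0.7}
TRAIN_SURVEY = {"fp_rate": 0.01, "fn_rate": 0.15}


def generate_validation_surveys(spec: BenchmarkSpec
                                ) -> tuple[InteractionNetwork, InteractionNetwork]:
    """(train, test) networks for the cross-validation benchmark.

    The test set is a sparse survey of the benchmark truth; the training
    set is a curated-quality survey of an *independent realization* of
    the same module structure, emulating two experimental campaigns that
    sample the same biology but rarely the same individual PPIs.
    """
    import dataclasses as _dc

    true_net, _ = generate_true_interactome(spec)
    test = degrade_interactome(true_net, seed=spec.seed + 500, **TEST_SURVEY)
    spec2 = _dc.replace(spec, seed=spec.seed + 1000)
    truth2, _ = generate_true_interactome(spec2)
    train = degrade_interactome(truth2, seed=spec.seed + 1000, **TRAIN_SURVEY)
    return train, test


@dataclass
class Benchmark:
    """All artifacts of one synthetic study."""

    spec: BenchmarkSpec
    catalog: ProteinCatalog
    true_net: InteractionNetwork
    labels: dict[str, int]
    expr: ExpressionMatrix
    observed_net: InteractionNetwork


def generate_benchmark(spec: BenchmarkSpec) -> Benchmark:
    """Generate catalog, truth, expression and the degraded observed network."""
    true_net, labels = generate_true_interactome(spec)
    expr = generate_expression(true_net, labels, spec)
    observed = degrade_interactome(true_net, spec.fp_rate, spec.fn_rate,
                                   seed=spec.seed)
    return Benchmark(spec=spec, catalog=generate_catalog(spec),
                     true_net=true_net, labels=labels, expr=expr,
                     observed_net=observed)
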