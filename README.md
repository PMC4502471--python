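# spliceonet

Probabilistic reconstruction and analysis of spliceosomal protein–protein
interaction (PPI) networks.

The spliceosome assembles and disassembles PPIs continuously, so splicing
factors — SR proteins, hnRNPs, snRNP and LSm components — form many
transient interactions that yeast two-hybrid surveys undersample. Rather
than treating a PPI as a deterministic observation, `spliceonet` scores
every protein pair with a posterior probability of direct interaction,
**P_in**, and analyzes the resulting probabilistic network: functional
clustering, enrichment, probability-weighted centrality, cross-validation
against held-out interaction data, and overlay of immunoprecipitation /
mass-spectrometry (IP-MS) experiments. It is aimed at computational
biologists studying interactomes of large molecular machines.

## The model

For a pair (i, j), two pieces of evidence are collected:

* **Transitivity** `T` — the ratio of shared to shared-plus-exclusive
  third-party interaction partners of i and j in an evidence PPI network
  (a Jaccard index over neighborhoods, with the pair itself excluded, so
  a direct i–j edge contributes nothing by itself);
* **Co-expression** `C` — the Pearson correlation of the two genes'
  expression profiles, treated as missing when a profile is absent or
  constant.

Conditional likelihoods `P(T | e)` and `P(C | e)` are binned histograms
fitted on the edges of a trusted network (`e = 1`) versus a
degree-preserving decoy rewiring of it (`e = 0`), with Laplace
smoothing. Treating T and C as conditionally independent given `e`,
Bayes' rule gives

```
            π · P(T|1) · P(C|1)
P_in = ─────────────────────────────────────────────
        π · P(T|1) · P(C|1) + (1−π) · P(T|0) · P(C|0)
```

with prior `π` defaulting to the training edge density. Downstream:

* **Functional clusters (FCs)**: UPGMA clustering of the P_in matrix
  under the distance `1 − Pearson(binding profiles)`, with upper-tail
  hypergeometric cluster × term enrichment (Benjamini–Hochberg FDR) and
  cluster–cluster connectivity `C_IJ`;
* **Topology**: probability-weighted degree (`wDEG = Σ_j P_ij`) and
  betweenness (`wBET`, minimum-cost paths with edge cost `1/P_in`),
  with empirical significance against 1,000 Erdős–Rényi G(n, m)
  replicates carrying a permutation of the observed probabilities;
* **Cross-validation**: sensitivity, specificity and Matthews'
  correlation coefficient of thresholded P_in predictions versus a
  deterministic edge-overlap baseline, on positives (test-network
  edges) and negatives (pairs in different test components);
* **IP-MS overlay**: per-protein enrichment
  `logE = log2(P_dox+ / (P_dox− + 1))` with the strict `logE > 1` rule,
  nuclease-resistant (nucR) vs. nuclease-sensitive (nucS) ligand
  classification, P_in distribution and bait-proximity comparisons,
  per-cluster regression, and an all-member protein-complex screen.

A seeded synthetic-data module generates every input the toolkit
consumes — a planted-partition interactome, module-factor expression, a
degraded observed network, and overdispersed IP-MS peptide counts — so
the whole pipeline is testable without downloads.

## Worked example

```python
import numpy as np
import spliceonet as sn
from sklearn.metrics import roc_auc_score, adjusted_rand_score

spec = sn.BenchmarkSpec(seed=7)          # 120 proteins, 6 modules
bench = sn.generate_benchmark(spec)      # truth, expression, observed net
model = sn.fit_conditional_models(bench.observed_net, bench.expr, seed=7)
pnet = sn.build_ps_network(bench.catalog, bench.observed_net, bench.expr, model)

print(pnet.n * (pnet.n - 1) // 2)        # 7140 scored pairs
print(round(model.prior, 4))             # 0.1968 (training edge density)
print(round(pnet.get("P001", "P002"), 3))  # 0.297, a same-module pair

iu = np.triu_indices(pnet.n, 1)
truth = np.array([bench.true_net.has_edge(pnet.protein_ids[i], pnet.protein_ids[j])
                  for i, j in zip(*iu)])
print(round(roc_auc_score(truth, pnet.pin[iu]), 3))   # 0.831

assign = sn.cluster_pnet(pnet, k=6)
print(adjusted_rand_score([bench.labels[p] for p in pnet.protein_ids],
                          [assign.mapping[p] for p in pnet.protein_ids]))  # 1.0
```

Ranking pairs by P_in separates the planted true interactome from
non-interacting pairs with AUROC 0.83 even though 15 % of true edges
were dropped and spurious edges added, and clustering the binding
profiles recovers the six planted modules exactly (adjusted Rand
index 1.0).

The same workflow is available from the shell:

```bash
spliceonet simulate --seed 7 --out-dir bench/
spliceonet build-net --ppi bench/ppis_observed.tsv --expr bench/expr.tsv \
    --catalog bench/catalog.tsv --seed 7 --out pnet.tsv
spliceonet cluster --pnet pnet.tsv --k 6 --out clusters.tsv
spliceonet topology --pnet pnet.tsv --cutoff 0.1 --n-random 1000 --seed 7 \
    --clusters clusters.tsv --out centrality.tsv
```

Every subcommand accepts `--config config.yaml` for defaults and writes
a JSON run manifest beside its outputs.

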