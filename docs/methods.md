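# Methods

## The interaction-probability model

`spliceonet` scores every unordered pair of catalog proteins with the
posterior probability `P_in` that the pair forms a direct PPI, given two
observable quantities:

* **Transitivity (T).** For proteins a and b with neighborhoods N(a),
  N(b) in an evidence PPI network, let S = N(a) ∩ N(b) \ {a, b} be the
  shared third-party partners and X the exclusive ones. We define
  T = |S| / (|S| + |X|), the Jaccard index of the reduced neighborhoods,
  with T = 0 when both are empty. The pair itself is excluded on both
  sides, so the presence or absence of a direct a–b edge does not enter
  T(a, b); predictions therefore do not simply echo the input network,
  and removing a single direct edge perturbs other pairs only through
  their third-party neighborhoods. "Shared versus exclusive partners"
  admits several normalizations; the Jaccard ratio is the canonical one
  and is bounded in [0, 1] regardless of degree.
* **Co-expression (C).** The Pearson correlation of the two genes'
  expression profiles across samples (≥ 3 samples required). C is
  *missing* — not zero — when either gene is absent from the matrix or
  has a constant profile. Pairs with missing C are scored from T alone:
  in realistic catalogs many more pairs exist than co-expression
  profiles, so a fallback is mandatory rather than optional.

**Likelihoods.** T and C are treated as conditionally independent given
the class e ∈ {0, 1} (interacting or not). Both likelihoods are binned
histograms: 20 equal-width bins for T on [0, 1] and 40 for C on [−1, 1],
each with a Laplace pseudocount (default 1 per bin) and renormalized.
Histograms keep the model free of density-estimation hyperparameters,
and the pseudocount guarantees every bin has positive mass, so P_in is
never exactly 0 or 1. The e = 1 sample is the edge set of the trusted
evidence network; the e = 0 sample is the edge set of a
**degree-preserving decoy** produced by double-edge swaps (10×|E|
attempted swaps, seeded). A degree-preserving rewire, rather than a
uniform shuffle, compares the two classes at matched degrees — otherwise
the e = 0 class would be dominated by low-degree pairs and T would look
artificially informative. T is evaluated on the *original* network for
both samples. Networks admitting no swap (e.g. a star) are returned
unchanged with a warning.

**Prior.** π = P(e = 1) defaults to the training edge density
|E| / C(n, 2) ("auto") and is configurable; there is no canonical value
for it, and the edge density is the empirical base rate of the evidence.

**Posterior.** Bayes' rule under conditional independence:
P_in = πL / (πL + (1 − π)), where L is the product of the T and C
likelihood ratios (the C factor is omitted for pairs with missing C, and
globally when the fit found no usable co-expression in either class —
flagged on the model). P_in is monotone in L at fixed π.

## Downstream analyses

**Functional clusters.** The distance between proteins i and j is
1 − Pearson(row_i, row_j) of their P_in binding profiles, with entries i
and j removed from both rows: the diagonal is a structural zero and the
mutual entry would leak the pair's own score into its similarity.
Constant profiles get distance 1 (logged). Clustering is average-linkage
(UPGMA) agglomeration cut to exactly k clusters (default 10; scipy's
deterministic smaller-index tie-break), relabeled contiguously.

**Enrichment.** Cluster × term over-representation uses the upper-tail
hypergeometric probability P(overlap ≥ b) — the printed mass function
alone is a point probability, and over-representation requires the tail
including the observed overlap. All cluster × term tests form one family
for Benjamini–Hochberg adjustment; the conventional display rule is
q < 0.1. The two-group partition test is the two-sided Fisher exact
test (the conservative default when directionality is not prespecified).

**Cluster connectivity.** C_IJ is the P_in mass between clusters I and J
normalized by the total mass touching either cluster (the cross mass
counted once); the numerator is a sub-sum of the denominator, so
C_IJ ∈ [0, 1] and C_IJ = C_JI. A zero denominator defines C_IJ = 0.

**Weighted centrality.** Scores are computed on the network thresholded
at a working cutoff (default P_in ≥ 0.1, the adopted minimum for
retained PPIs; on the dense untresholded matrix betweenness degenerates,
as nearly every pair is "adjacent"). wDEG is the incident-probability
sum. wBET uses edge traversal cost 1/P_in — high-probability edges are
cheap — and counts, per unordered pair (s, t), the fraction of
minimum-cost paths through the protein; unreachable pairs contribute 0.

**Empirical significance.** Each of n_random (default 1,000) replicates
is an Erdős–Rényi G(n, m) graph with the observed node and edge counts,
its edges carrying a random permutation of the observed probability
multiset, so the null preserves size and weight mass but randomizes
placement. A protein's empirical p-value is the add-one fraction of
replicates whose *maximum* per-node score reaches the observed score
(for wDEG and wBET separately). Comparing against the replicate maximum
is deliberately conservative — it asks whether any node of a random
network could look as central — and keeps the estimator's floor at
1/(n_random + 1). q-values are BH-adjusted per metric; q_min is the
smaller of the two and ranks hub candidates.

**Global metrics.** Density |E|/C(n, 2); Newman modularity of the
unweighted thresholded graph over a given cluster assignment (absent
when no assignment or no edges); Freeman degree centralization; average
shortest-path length as the mean minimum 1/P_in cost over reachable
pairs, with the reachable fraction reported alongside.

**Cross-validation.** Positives are the direct edges of a test network;
negatives are pairs in *different connected components* (path length
diverges), the strictest available notion of a non-interacting pair;
reachable non-adjacent pairs are in neither set. The probabilistic
predictor is trained on the training network with every test edge
removed (holdout) and thresholded at P_in ≥ t; the deterministic
baseline predicts an interaction exactly when the edge exists in the
full training network — the overlap between surveys, which is what a
direct-observation approach can assert. MCC of a table with a zero
marginal is reported as 0 and flagged. Proteins unknown to a predictor
are scored as negative predictions and counted.

**IP-MS scoring.** Per protein and condition, replicate unique-peptide
counts are pooled by summation, then
logE = log2(P_dox+ / (P_dox− + 1)); the pseudocount accommodates
proteins undetected without induction, and P_dox+ = 0 maps to −∞ (never
enriched). Enrichment is *strict* logE > 1: the non-strict reading would
admit two peptides over zero (log2(2/1) = 1), while the strict rule
guarantees both a two-fold ratio and at least three peptides when the
uninduced count is zero. Ligands enriched under nuclease treatment are
nucR (RNA-independent) regardless of the no-nuclease outcome; ligands
enriched only without nuclease are nucS (RNA-bridged); everything else
in the catalog is undetected — an exhaustive, disjoint partition.
Group comparisons (P_in distributions, bait path lengths) use the
two-sided Mann–Whitney U test at α = 0.05, a distribution-free choice
suited to the bounded, skewed P_in scale. The per-cluster regression
compares each cluster's share of IP-MS ligands with its share of
predicted partners (P_in ≥ cutoff) by ordinary least squares, reporting
R²; both series are within-series proportions and sum to 1.

## The synthetic benchmark

The generator (`spliceonet.simulate`) produces every input the toolkit
consumes, as a pure function of (spec, seed):

* **True interactome**: a planted-partition graph — 120 proteins in 6
  equal modules, intra-module edge probability 0.35, inter-module 0.02.
  These sizes give module degrees (~7) and a network scale at which the
  full pipeline runs in seconds on one CPU while leaving transitivity
  informative.
* **Expression**: each module has a latent factor over 30 samples; a
  gene is effect × factor + Gaussian noise (effect 1.0, noise SD 0.5),
  so co-module pairs correlate with expected r = effect²/(effect² +
  SD²) = 0.8 — co-expression supports, but does not equal, interaction.
* **Observed network**: each true edge dropped with probability 0.15 and
  each non-edge added with probability 0.15, emulating undersampling and
  spurious hits. Note that at this false-positive rate roughly two
  thirds of observed edges are spurious: the evidence network is
  deliberately hard.
* **IP-MS counts**: ligands are planted from the *ground-truth*
  interactome (represented as an idealized probability network with
  true edges at 0.9) — co-purification reflects real physical binding,
  not the analyst's estimate of it — with nuclease-condition ligands
  sampled from the bait's direct partners (12 by default, probability
  proportional to interaction probability) and no-nuclease ligands
  additionally from two-hop partners (6 by default, emulating RNA
  bridging). Counts are negative binomial in the (mean, dispersion)
  parameterization — MudPIT unique-peptide counts are overdispersed —
  with baseline mean 2 unique peptides, dispersion 5, and an 8× induced
  enrichment for true ligands, typical scales for ion-trap IP-MS of an
  inducible tagged bait. Two replicates per condition.
* **Cross-validation surveys**: the test set is a sparse two-hybrid-like
  survey of the truth (70 % false negatives, 0.2 % false positives);
  the training set is a curated-database-like survey (15 % / 1 %) of an
  *independent realization* of the same module structure. Two campaigns
  sampling the same biology rarely report the same individual PPI, which
  is exactly the regime in which probabilistic prediction pays off; with
  a shared realization the deterministic overlap baseline would
  trivially inherit most test edges and the comparison would be
  uninformative.

What the benchmark does *not* emulate: scale-free degree structure,
study bias in database coverage, sequence- or abundance-dependent MS
detectability, and microarray normalization artifacts. Passing tests
demonstrate that the implementation recovers planted structure under
controlled noise, not that the defaults match any particular organism's
interactome.

## Numerical and degenerate-input conventions

* Probability matrices are validated as exactly symmetric with a zero
  diagonal (self-interactions are excluded everywhere); scoring fills
  the upper triangle and mirrors it, and text round-trips re-symmetrize.
* Histogram bin lookup clips to the outermost bins, so T = 1 and
  C = ±1 fall in the closing bin.
* Thresholding is inclusive (pin ≥ cutoff) and isolates are kept.
* Empirical p-values use the add-one estimator; they cannot be 0.
* `residual_comparison` reports the fraction of pairs with residual
  < eps and the count ≥ eps; at eps = 0 the fraction counts exact
  equality and the count covers strictly nonzero residuals.
* Protein identifiers are case-sensitive symbols; no alias resolution.

## Problem sizes in the test suite

The suite runs the full benchmark at its default size (120 proteins) for
three seeds, centrality nulls at n_random = 100 on 40-node fixtures (the
floor the API accepts), and enumeration oracles on instances with ≤ 12
population members (hypergeometric/Fisher) or ≤ 8 nodes (betweenness) —
sizes at which exhaustive enumeration is exact and fast. The whole suite
completes in well under a minute on one CPU.

## Known limitations

* The conditional model is a naive-Bayes combination of two evidence
  channels; correlated evidence (e.g. co-expression driven by shared
  complexes already visible in T) inflates confidence.
* Histogram likelihoods are insensitive to structure within a bin;
  very small training networks leave bins dominated by the pseudocount.
* The replicate-maximum null for centrality is conservative; proteins
  short of the hub regime get q ≈ 1 rather than a graded score.
* C_IJ depends on cluster sizes; comparisons are meaningful within one
  clustering, not across clusterings with different k.
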