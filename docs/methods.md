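# Methods

## Statistical model of the integration stage

Each omics layer is a feature × sample matrix for the same subjects,
split into two phenotype groups (labelled high/low; balanced 5+5 by
default).  The per-layer association score is the pooled-variance
two-sample t statistic (high minus low).  Pooled rather than Welch
variance is used because the permutation null relies on exchangeability
of the sample labels, which the pooled statistic respects.

The score is standardised by its permutation standard deviation: all
C(n, n₁) distinct balanced relabelings are enumerated when there are at
most 10,000 (the 5+5 design gives 252), otherwise 10,000 relabelings are
sampled with a fixed seed; the identity labeling is always a member of
the null set.  The exhaustive SD is the full-population value (ddof 0);
the sampled SD uses ddof 1.

Under the null |Z| is treated as half-normal, and the combined score
S_meta = Σₖ|Z_gk| is referred to the tail of a sum of D independent
half-normals.  Four interchangeable nulls are exposed:

* **exact_convolution** (default): numerical convolution of the
  half-normal density on a trapezoid-corrected grid (dx = 1e-4, per-
  component support [0, 9]); absolute accuracy ≈ 1e-9 against
  quadrature; D = 1 uses the closed form 2(1 − Φ(s)).
* **paper_eq2**: the closed form 1 − [2Φ(s/√2) − 1]², valid for D = 2.
  This is *exactly* the convolution tail for two layers: the region
  |z₁| + |z₂| ≤ s is a square that a 45° rotation maps to
  [−s/√2, s/√2]², so its standard-bivariate-normal probability is the
  bracket squared.
* **monte_carlo**: simulation estimate of the same tail.
* **permutation**: the permuted S_meta values of all features with the
  same layer multiplicity are pooled into one empirical null.

**Small-sample caveat.**  With 5+5 samples the standardised score is
t(8)-shaped, which is heavier-tailed than Gaussian; the half-normal
convolution is therefore anti-conservative in the far tail, and with
thousands of features it produces spurious BH discoveries under a
global null.  The permutation null inherits the correct tail (its
p-values are empirically uniform under the null) and is the method the
calibration tests use.  The convolution remains the default because it
is the distributional model the combined score is defined by, it is
smooth (no pooling granularity), and candidate selection downstream is
threshold-based rather than error-rate-critical; analyses that need
calibrated error rates at n = 5+5 should pass
`method="permutation"`.

Probe-level inputs are collapsed to features by keeping the most
significant probe (ties: larger |score|, then lexicographic probe id).
BH adjustment is computed within feature class (genes and miRNAs
separately, as the pipeline integrates them separately).

## Pathway impact

Seed genes are those with integrated p ≤ α (default 0.05); their ΔE is
the difference of group means on the (log2) expression scale, zero for
non-seeds.  Over-representation is the hypergeometric upper tail of the
seed count in the pathway against the measured background.
Perturbation propagates ΔE through the signed topology by solving
PF = (I − B)⁻¹ΔE with B[i,j] = β(j→i)/N_ds(j); the net accumulation
t_A = Σ(PF − ΔE) is referred to a bootstrap null that places the same
number of resampled fold-changes on random pathway genes (median-
centred two-sided p, floor 1/B, default B = 1000–2000).  Pathways whose
(I − B) is singular or near-singular (condition number > 1e12, e.g. an
undamped 2-cycle) are flagged and get P_PERT = 1.  Pathways with fewer
than 3 measured members are skipped (degenerate nulls).  The global
probability is P_G = c − c·ln c with c = P_NDE·P_PERT — the probability
that a product of two independent uniforms falls below c — and all
three columns are BH-adjusted across pathways; a pathway is called
significant when q_G ≤ 0.20 or q_NDE ≤ 0.20.

## Prize-collecting Steiner tree

Candidates are the union of {q ≤ 0.05} and {member of a significant
pathway with p ≤ 0.05}.  Node prizes are −ln p (natural log throughout;
p floored at 1e-16).  Edge costs combine the interaction-database
reliability R₁ with the |Pearson r| of the endpoints' expression
profiles R₂ (clipped at 0.99) multiplicatively, c = 1 − R₁R₂; with a
single channel c = 1 − R₁.

The exact solver enumerates all connected node subsets (bitmask
connectivity + Kruskal MST per subset) up to 15 nodes; the minimum-cost
connected structure on a node set is its MST, so this is a true global
optimum.  Ties are broken by objective, then larger collected prize,
then fewer nodes, then lexicographic node ids — the prize-before-size
order makes the λ = 0 limit return the highest-prize singleton rather
than the empty set, and keeps every result deterministic.  The empty
module (objective 0) is admissible.

The heuristic computes, per connected component, the minimum spanning
tree under the raw costs and under prize-discounted weights
c − λ(b_u + b_v)/2, and strong-prunes each by exact dynamic programming
on the tree (best connected subtree); the best pruned subtree across
components wins.  On trees the heuristic is exact; on 200 random
≤ 12-node graphs it is within 5% of the exact objective in ≥ 95% of
(graph, λ) pairs.  Zero-prize linker nodes one interactome hop from a
candidate may be admitted (Steiner semantics); the pipeline enables
this by default because module genes that narrowly miss the candidate
thresholds then re-enter as connectors.

λ is calibrated by sweeping 0.01–1.00 in steps of 0.01 over simulated
networks matched to the candidate graph in size and density, returning
the smallest λ whose mean planted-essential-node recovery reaches 70%.
The calibration networks mirror the real candidate-graph construction:
two-channel edge costs (reliability strata Beta(5,2)/Beta(2,5),
correlation strata Beta(7,3)/Beta(1.5,4.5)), essential nodes connected
by a high-reliability spanning path, scored essential p-values spanning
10⁻⁶–10⁻¹·⁵, and 10% of essentials unscored (prize 0) to represent
threshold-missed genes.  λ is an instance-specific quantity: it depends
on the prize scale and cost distribution of the data at hand, and no
fixed value is built in.

## miRNA regulation patterns

miRNAs with both expression and methylation data are meta-integrated
(class EM); expression-only miRNAs are tested by the expression t-test
alone (class E); both are selected at p ≤ 0.05, EM taking precedence.
Selected miRNAs are correlated with module-gene expression; pairs with
r ≤ −0.55 enter the reported network, and pairs additionally present in
the supplied miRNA→target map are *target-supported*.  The cutoff is
inclusive (r = −0.55 kept, −0.54 dropped).

Each module gene receives exactly one label:

| pattern | evidence |
|---|---|
| METHYLATION | methylation t-test p ≤ 0.10 **and** expression–methylation r ≤ −0.55 |
| MIRNA | a target-supported anti-correlated selected miRNA |
| CO_REGULATED | both of the above |
| NEIGHBOR_TF | neither, but an interaction neighbour in the module with expression r ≥ +0.55 |
| UNCLASSIFIED | none of the above |

The ±0.55 thresholds mirror the miRNA screening cutoff by symmetry; the
methylation α of 0.10 reflects that methylation evidence is corroborative
(the gene already carries integrated expression evidence).  Neighbour
evidence uses all interactome edges among module genes, not only the
solution tree, since the tree is merely the cheapest connector.
Anti-correlated miRNAs without target support stay in the displayed
network but cannot create MIRNA-pattern evidence.  Strengthening any
evidence never demotes a gene to UNCLASSIFIED (monotonicity, tested).

## Synthetic data generator

The generator emulates the study design the analysis assumes: balanced
two-group samples (default 5+5), 2000 genes, 200 miRNAs.  Expression is
gene-wise independent Gaussian (sd = `noise_sd`) around uniform
baselines; planted differential genes (default 1%) get a group-mean
offset of `effect_size`·`noise_sd` (default d = 3, the regime where a
5+5 t-test has ~96% power at α = 0.05).  Planted genes cycle through
the four regulation patterns; the planted module (default 12 genes, a
connected induced subgraph of the interactome) is pattern-annotated the
same way.

* **Methylation** of pattern-1/4 genes is −a·z(expression) +
  √(1−a²)·noise with a = |`methyl_anticorr`| (default 0.8, matching
  reported gene-level correlations of −0.73…−0.85), which fixes the
  expected Pearson correlation at −a and simultaneously makes
  methylation group-differential.  Pattern-2/3 genes get independent
  null methylation — the four patterns are unrealisable otherwise.
* **Regulator miRNAs** (patterns 2/4) are coupled to their target gene
  the same way plus an opposing group shift of `effect_size`/2, so they
  are both anti-correlated and reliably detectable at p ≤ 0.05.  A
  configurable fraction of miRNAs (default 60%) carries methylation
  data, giving a non-trivial EM/E split.
* **The interactome** is Erdős–Rényi at density 0.005 (mean degree ~10,
  typical of high-confidence interaction networks) with reliabilities
  Beta(2,5); module-internal edges use Beta(5,2) and missing module
  connectivity is repaired with spanning edges from the same stratum.
* **Pathways** get random memberships with signed DAG topologies
  (edges ordered by member index, so propagation is always solvable);
  the first pathway contains the planted module plus half of the
  remaining differential genes — disease-pathway semantics mirroring
  designs where the module genes belong to the significant pathways.
* **Module coherence**: planted module genes share one direction of
  differential expression.  A co-expressed module is what the
  correlation evidence channel and the neighbour/TF pattern presuppose;
  with random directions within the module, pattern 3 would be
  undefined.

What the generator does **not** model: probe-level noise and array
normalisation artefacts, methylation measured as counts or β-values
(it is Gaussian here), correlated gene-gene background noise, hub
structure and degree heterogeneity of real interactomes, and miRNAs
with many simultaneous strong targets.  Passing recovery tests on this
generator therefore demonstrates that the pipeline's inference is
correct under its own model assumptions, not that those assumptions
hold for any particular real dataset.

## Problem sizes and determinism

The recovery benchmarks run 20 independent datasets at the full study
scale (2000 genes, 200 miRNAs, 5+5 samples, 12-gene module); the null
calibration runs 20 global-null datasets of 1000 genes; the solver
cross-checks use 200 random graphs of 6–12 nodes over ten λ values;
Monte-Carlo oracles use 10⁷ draws.  One pipeline run at full scale
takes a few seconds on one CPU.

All randomness flows from a single integer seed through numpy
`SeedSequence` spawning (one child per stage, in a fixed order), so any
stage re-run in isolation with the seed recorded in the run manifest
reproduces its output bit-for-bit.  TSV round-trips preserve float64
exactly (`%.17g` writing, round-trip parsing).

## Known limitations

* The combined-score null assumes independent layers; expression and
  methylation of the same gene are correlated under the alternative
  (by design), which affects power, not null calibration.
* The convolution null is anti-conservative at very small n (see
  above); use the permutation method when calibrated tail areas matter.
* P_PERT's bootstrap places fold-changes on uniformly random pathway
  genes, ignoring degree bias within the pathway graph.
* The exact PCST solver is exponential and hard-capped at 15 nodes;
  above that the heuristic carries no optimality guarantee beyond the
  empirical 5%-of-exact behaviour measured in the tests.
* λ calibration quality depends on how well the simulated networks
  match the real candidate graph; the stand-in described above encodes
  that structure explicitly but remains a model.
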