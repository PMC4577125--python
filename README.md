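# crossomics

Integrative trans-omics analysis for small two-group phenotype contrasts,
modelled on study designs that profile the same subjects on several omics
layers — e.g. gene expression, promoter methylation, and miRNA expression
in high vs low bone-mineral-density (BMD) groups — and ask which genes,
pathways and regulatory circuits separate the phenotypes when no single
layer reaches significance on its own.

The pipeline has four stages:

1. **Meta-integration.** For feature *g* and omics layer *k*, a pooled
   two-sample t statistic *S<sub>gk</sub>* is standardised by its
   permutation standard deviation (all balanced relabelings of the group
   labels), giving *Z<sub>gk</sub>* whose absolute value is half-normal
   under the null.  The combined score
   *S<sub>meta</sub>(g) = Σ<sub>k</sub> |Z<sub>gk</sub>|*
   is referred to the tail of a sum of independent half-normals (for two
   layers this tail has the closed form 1 − [2Φ(s/√2) − 1]²), or to a
   pooled permutation null, and Benjamini–Hochberg adjusted.
2. **Pathway impact.** Seed genes (integrated p ≤ 0.05) feed a signaling
   pathway impact analysis: a hypergeometric over-representation p-value
   *P<sub>NDE</sub>* plus a perturbation p-value *P<sub>PERT</sub>* from
   propagating log fold-changes through the signed directed pathway
   topology, PF = (I − B)⁻¹ΔE, combined as
   *P<sub>G</sub> = c − c·ln c* with *c = P<sub>NDE</sub>·P<sub>PERT</sub>*.
3. **Module discovery.** Candidate genes (FDR ≤ 0.05 or significant-pathway
   members with p ≤ 0.05) are placed on a weighted interactome with node
   prizes *b<sub>i</sub> = −ln p<sub>i</sub>* and edge costs
   *c<sub>e</sub> = 1 − Π<sub>j</sub> R<sub>j</sub>* (interaction
   reliability × expression correlation, naive-Bayes style), and the
   prize-collecting Steiner tree minimising
   *Σ<sub>e∈E′</sub> c<sub>e</sub> − λ Σ<sub>i∈V′</sub> b<sub>i</sub>*
   is solved exactly (≤ 15 nodes) or by an MST strong-pruning heuristic.
   λ is calibrated on simulated networks of matched size until 70% of
   planted essential nodes are recovered.
4. **miRNA regulation.** Phenotype-associated miRNAs are attached to the
   module via Pearson anti-correlation (cutoff −0.55) and a miRNA→target
   map; each module gene is then classified into one of four regulation
   patterns: promoter **methylation**, **miRNA**, **neighbour/TF**, or
   methylation+miRNA **co-regulation**.

Because real subject-level data of this kind is rarely redistributable,
the package ships a synthetic-data generator (`crossomics.simulate`) that
plants all of the structure the analysis looks for — differential genes,
methylation anti-correlation, a connected interactome module, a seeded
pathway, anti-correlated regulator miRNAs — with full ground-truth
annotation, so every stage is testable offline.

## Worked example

```python
from crossomics import SyntheticConfig, generate_dataset
from crossomics.pipeline import run_analysis

ds = generate_dataset(SyntheticConfig(seed=2))     # 2000 genes, 5+5 samples
bundle = run_analysis(ds.expression, ds.methylation, ds.mirna_expression,
                      ds.mirna_methylation, ds.interactome, ds.pathways,
                      ds.target_map, seed=102)

print(bundle.lam)                                   # 0.08  (calibrated)
print(bundle.gene_integration[["s_meta", "p_inte", "q_inte"]].head(3))
print(bundle.module.nodes)
print(bundle.pattern_table["pattern"].value_counts().to_dict())
```

prints (abridged):

```
0.08
         s_meta      p_inte    q_inte
g01349   12.43       ~0        8.0e-07
g01006    9.59       ~0        8.0e-07
g00486    8.57       ~0        2.3e-06
('g00037', 'g00114', 'g00290', 'g00486', 'g00949', 'g01055',
 'g01119', 'g01349', 'g01396', 'g01672', 'g01739')
{'METHYLATION': 4, 'MIRNA': 3, 'CO_REGULATED': 3, 'NEIGHBOR_TF': 1}
```

The calibrated trade-off λ = 0.08 yields an 11-gene module that recovers
11 of the 12 planted module genes (Jaccard 0.92 against the ground truth
in `ds.truth["module_nodes"]`); the top integration hits are planted
differential genes, and the pattern table assigns each module gene its
regulation mechanism.  The same pipeline is scriptable from a shell:

```sh
crossomics simulate --outdir data/ --seed 2
crossomics mirna-net --dataset-dir data/ --seed 102 --outdir results/
```

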