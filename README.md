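# mycorrnet

Dual-transcriptome co-expression network analysis for host–symbiont
systems, built around the arbuscular mycorrhizal (AM) symbiosis: a
host plant (e.g., cassava cultivars) and a fungal symbiont
(*Rhizophagus irregularis* isolates) measured together by dual
RNA-seq on a crossed genotype × genotype design with a mock-inoculated
control.

The package is for researchers who have paired, read-separated count
matrices (one per organism, shared samples) plus sample metadata and
quantitative growth traits, and want to:

1. classify each gene's transcriptional response — host-genotype
   only, conserved mycorrhizal response, conserved symbiont-genotype
   response, or a genotype × genotype (G×G) interaction — via
   per-gene two-way factorial ANOVA on log2-CPM with BH-FDR control;
2. build weighted co-expression modules per organism: soft-power
   adjacency `a_ij = |cor(x_i, x_j)|^β` (β = 12), topological overlap
   `TOM_ij = (L_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`, average-linkage
   clustering of `1 − TOM`, tree cut (minimum module size 50),
   eigengenes (first PCs) and merging at eigengene dissimilarity 0.1;
3. link modules **across kingdoms**: Pearson correlation of host and
   fungal module eigengenes over inoculated samples, edges at
   p < 0.001, and "key genes" — module members in the top 10% of
   |gene significance| toward a correlated partner module with
   kME > 0.8;
4. associate modules with quantitative traits (root colonization,
   dry weights) by the same correlation machinery; and
5. validate the network against a random gene-to-module relabeling
   null.

A synthetic-data module generates the whole study design — paired
negative-binomial count matrices with planted modules, cross-organism
factor links, response classes, nuisance variation, traits and mock
contamination — with known ground truth, so every step of the
pipeline is testable end to end.

## Worked example

```python
import numpy as np, mycorrnet as mn

config = mn.PipelineConfig(seed=1, outdir="results/demo")
res = mn.run_all(config)

print("host modules:", res.partitions["host"].n_modules)
print("symbiont modules:", res.partitions["symbiont"].n_modules)
sig = res.cross_edges[res.cross_edges.significant]
print(sig[["module_host", "module_symbiont", "r", "p"]].round(3).to_string(index=False))
print("key genes:", int(res.key_genes.passes.sum()))
print("permutation null median edges:", np.median(res.permutation["null_counts"]))
print("empirical p:", round(res.permutation["p_empirical"], 4))
```

prints

```
host modules: 2
symbiont modules: 4
module_host module_symbiont     r   p
         M1              M2 0.914 0.0
key genes: 15
permutation null median edges: 0.0
empirical p: 0.0099
```

Reading this: the pipeline simulated the default 45-sample dual
dataset, classified responses, and — following the practice of
building the host network only from symbiosis-responsive genes —
found 2 host and 4 fungal modules. One host–fungus module pair is
significantly co-expressed across inoculated samples (r = 0.914,
far below the p < 0.001 edge threshold); 15 genes qualify as key
genes of that relationship. Randomly relabeling genes to modules 100
times never produces a network (median 0 edges), so the observed
network gets the smallest possible empirical p-value, 1/101 ≈ 0.0099.
All outputs (count matrices, response classes, module tables,
eigengenes, kME, cross-edge table, GraphML network, key genes,
trait associations, permutation null, manifest) are written under
`results/demo/`.

The same pipeline runs from the shell:

```bash
mycorrnet run-all --out results/demo --seed 1
mycorrnet simulate --out data/sim --seed 7
mycorrnet classify --counts data/sim/host_counts.tsv \
    --meta data/sim/metadata.tsv --organism host --out results/de
```

Estimator-style APIs are available for composition with
scikit-learn: `CoexpressionModules` clusters the columns of a
samples × genes matrix (like `FeatureAgglomeration`) and its
`transform` maps samples onto module eigengene scores;
`ResponseClassifier` fits the per-gene factorial model.

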