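# mcnet

Metabolic network coherence (MC) of transcriptomes: derive a per-individual
network-coherence phenotype from expression data contextualized by a
metabolic model, then run the downstream genetic association and trans-eQTL /
cluster decomposition analyses — all exercisable on synthetic data with
planted ground truth.

## What it computes

1. **Gene-centric projection** (`mcnet.network_builder`): a bipartite
   metabolite–reaction model (with reaction→gene associations) is projected
   onto genes — two genes are adjacent iff reactions associated with them
   share a metabolite. The highest-degree "currency" metabolites (default
   top 5%) are removed first.
2. **Salience** (`mcnet.salience`): per gene, expression values in the lower
   q or upper 1−q empirical quantile tail (default q = 0.02, both tails) are
   marked salient; genes are optionally pre-filtered by zero-count fraction
   and log2(x+1)-transformed.
3. **MC score** (`mcnet.coherence`): per sample, the connectivity (fraction
   of non-isolated nodes) of the subnetwork induced by its salient genes is
   z-transformed against a simulated null of equally sized random gene sets
   (default 2000 draws). Includes a currency-fraction × quantile sensitivity
   sweep.
4. **Genetics** (`mcnet.genetics`): dosage-panel QC (call rate, autosomes,
   MAF, minor-homozygote count, HWE), LD r² and pruning, genotype PCA, and
   the Li–Ji eigenvalue-based LD-effective test count.
5. **Association** (`mcnet.association`): per-SNP OLS of MC on minor-allele
   dosage with covariates, conditional scans on a top SNP, rank-based group
   tests, Manhattan/QQ export.
6. **eQTL decomposition** (`mcnet.eqtl_decomposition`): gene × SNP
   Kruskal–Wallis trans-eQTL tests, Bonferroni thresholds, asymmetric-binary
   distances between salience profiles, Ward (ward.D) clustering, and the
   significance-driven sub-cluster decomposition with target-cluster
   selection and a generic hypergeometric enrichment helper.
7. **Synthetic data** (`mcnet.synthetic_data`): coupled model / genotype /
   expression simulation with planted currency hubs, one causal QTL
   modulating coherence, and salient sets planted so that dichotomization is
   an exact round trip.

## CLI

```bash
# simulate a dataset bundle (model TSV, expression TSV, VCF, covariates, truth)
mc simulate --config sim.yaml --out data/ --seed 1

# MC phenotype
mc compute --model data/model.tsv --expression data/expression.tsv \
   --currency-fraction 0.05 --quantile 0.02 --null-draws 2000 --seed 1 \
   --out mc.tsv

# genotype QC and association
mc qc --vcf data/genotypes.vcf --out panel.tsv --report qc_report.tsv
mc gwas --mc mc.tsv --tsv panel.tsv --covar data/covariates.tsv \
   --adjust population,sex --out gwas.tsv

# full pipeline (8 stages, manifest with seeds and checksums)
mc run --config run.yaml
```

A `run.yaml` names an `output_dir`, a master `seed`, either an `inputs`
block (paths to model/expression/vcf/covariates) or a `simulate` block
(simulation parameters), and optional `params` overriding the defaults
(currency_fraction 0.05, quantile 0.02, null_draws 2000, call rate 0.99,
MAF 0.05, minor homozygotes 5, HWE p 0.001, alpha 0.05).

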