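# nspace

Diseases, like words, acquire meaning from the company they keep. `nspace`
builds a continuous vector space of diseases from chronological diagnosis
records — each disease is embedded by learning to predict it from the
diagnoses surrounding it in patient histories — and then uses that space as
a quantitative phenotyping engine: dimensions become traits, patients
become points, groups of nearby diseases become "constellations", and each
dimension can be scanned for genetic associations and used for polygenic
prediction.

## What the package does

1. **Embedding** (`embedding`): a continuous bag-of-words model with
   negative sampling (window 8, 20 dimensions by default) trained on
   date-ordered diagnosis sequences, followed by a PCA rotation so that
   dimension 1 carries the most variance. Query helpers cover cosine
   similarity, nearest neighbors, antipodes (farthest diseases), analogy
   arithmetic and per-dimension disease orderings.
2. **Dimension annotation** (`annotation`): every dimension × category pair
   is tested with the Wilcoxon rank-sum test; effect sizes are
   Hodges–Lehmann pseudo-medians and p-values are Benjamini–Hochberg
   adjusted over the whole family. Each dimension is labeled by its most
   separable category pair, e.g. `respiratory (-) to neoplastic (+)`.
3. **Constellations** (`constellations`): k-SVD dictionary learning with
   sparsity-1 orthogonal matching pursuit groups diseases into K
   constellations by argmax cosine against learned unit atoms, with an
   agglomerative-clustering baseline and a hypergeometric partition-overlap
   test.
4. **Patients as points** (`patient_traits`): an individual's position is
   the diagnosis-count-weighted mean of their disease vectors, turning each
   dimension into a quantitative trait; a covariate-adjusted scan
   associates external phenotype measures with each dimension.
5. **Genetic association** (`association`): MAF/Hardy–Weinberg QC, a
   vectorized per-variant dosage regression per dimension trait
   (equivalent to full OLS, verified against it), genome-wide significance
   at 5×10⁻⁸, greedy lead-locus collapsing (±5,000 bp or dosage r² > 0.1),
   directional replication via one-sided p-values at 5% FDR, genomic
   control, and hypergeometric gene-set enrichment.
6. **Polygenic prediction** (`prediction`): effect-allele-reconciled risk
   scores, logistic and gradient-boosted models evaluated on repeated
   balanced case/control splits, reported as Nagelkerke R² with a
   likelihood-ratio p against a covariates-only null plus test-set
   accuracy, PPV and NPV with empirical confidence intervals.
7. **Synthetic cohorts** (`synthetic`): a category-mixture generator with
   planted genetic effects (Hardy–Weinberg genotypes, latent genetic axes
   loading onto disease-category preferences) used throughout the test
   suite, so every statistical routine is exercised against known ground
   truth.

## Worked example

A published reference embedding reports the 20-dimensional coordinates of
asthma as {1.31, −0.452, −0.938, 0.197, −1.30, −0.426, 2.60, −1.26, 0.994,
−1.15, −0.373, 0.969, 0.781, −0.295, −1.42, −0.897, 0.919, −0.350,
−0.00992, 0.00486}. Ranking dimensions by absolute loading:

```python
>>> import nspace as ns
>>> ns.rank_dimensions_by_loading(ns.ASTHMA_REFERENCE_COORDINATES)[:5]
[7, 15, 1, 5, 8]
```

End to end on a synthetic cohort, from the command line:

```bash
$ nspace simulate --out bundle --seed 3
$ nspace embed --vocabulary bundle/vocabulary.tsv \
      --histories bundle/histories.tsv --out emb.tsv --seed 3
wrote 60 disease vectors to emb.tsv
$ nspace query --embedding emb.tsv --neighbors D001 -k 3
D010    0.9873
D007    0.9821
D004    0.9756
$ nspace query --embedding emb.tsv --antipode D001
D044    -0.5162
...
```

`D010`, `D007` and `D004` share `D001`'s planted disease category; the
antipode `D044` belongs to a category loaded with the opposite sign.

The same pipeline through the Python API (cohort of 5,000 patients, 60
diseases in 6 categories, 100 variants with 10 planted causal effects):

```python
import nspace as ns

cfg = ns.SimulationConfig(seed=1)
vocab, t0 = ns.make_vocabulary(cfg)
geno = ns.simulate_genotypes(cfg)
corpus, truth = ns.simulate_cohort(cfg, (vocab, t0), geno)

E = ns.pca_rotate(ns.train_embeddings(corpus, vocab, seed=1))
winners, table = ns.annotate_all(E, vocab)          # 300 rank-sum tests
D = ns.fit_ksvd(E, K=6, seed=1)                     # recovers categories, ARI = 1.0
traits = ns.corpus_traits(corpus, E)                # 5,000 patients x 20 traits
scan = ns.gwas_scan(ns.qc_filter(geno), traits, None, dimension=1)
print(scan["p"].min())                              # 2.7e-14: planted variant found
```

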