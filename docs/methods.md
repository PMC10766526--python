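# Methods

This note records the statistical and numerical choices in `nspace`,
module by module, including conventions a reimplementation would need.

## Disease embeddings

Each patient's history is the chronological sequence of disease-group
tokens derived from their diagnosis codes (same-day events keep file
order). A continuous bag-of-words model with negative sampling is trained
on these sequences: for each position, the mean of the context vectors
within a symmetric window (default 8) predicts the center disease against
`negative` (default 5) draws from the unigram distribution raised to the
3/4 power. Defaults: 20 dimensions, 10 epochs, linear learning-rate decay
from 0.025 to 10⁻⁴. The trainer is a deterministic numba kernel with an
xorshift64* RNG keyed on the seed, so runs are bit-reproducible; the
negative sampled log-likelihood of the final epoch is stored as
`meta["final_objective"]`.

The trained input vectors are rotated by PCA: rows are centered, the
rotation is the right singular basis, and each component's sign is fixed
so its largest-absolute loading is positive. Rotation is an isometry
(pairwise distances are preserved; this is tested), dimension variances
are non-increasing, and dimension indices are 1-based everywhere in the
API.

Query semantics: cosine similarity errors on zero vectors; `neighbors`
excludes the query token but not duplicates of its vector; the antipode is
the cosine minimizer (`farthest=True`); analogy queries sum the `plus`
vectors, subtract the `minus` vectors and rank the rest of the vocabulary,
excluding the operands. `compare_spaces` correlates pairwise
inter-disease distances between two spaces over the shared vocabulary
(Pearson r plus regression slope/intercept), which is how spaces of
different dimensionality — or retrained replicas — are checked for
concordance.

## Dimension annotation

For each dimension, every unordered pair of disease categories (with at
least two member diseases each) is compared by the Wilcoxon rank-sum test
on the diseases' coordinates along that dimension. The exact null
distribution is used when both groups have ≤ 25 observations and no ties
(verified against full enumeration); otherwise the tie-corrected normal
approximation. The effect size is the Hodges–Lehmann pseudo-median — the
median of the full grid of pairwise differences — oriented so the category
with the smaller median is the negative pole, giving labels of the form
`catA (-) to catB (+)`. Benjamini–Hochberg adjustment runs over the
complete pairs × dimensions family (at 21 categories and 20 dimensions
that is C(21,2) × 20 = 4,200 tests); each dimension's reported winner is
its minimal-raw-p pair. Under simulated null coordinates the procedure is
calibrated: pooled type-I error at 5% does not exceed nominal and
family-wide BH discoveries occur at the expected rarity.

## Disease constellations (k-SVD)

Disease vectors (rows of the rotated embedding) are approximated as
one-sparse combinations of K unit-norm atoms. Sparse coding with
sparsity 1 has a closed form: each vector picks the atom with the largest
absolute inner product, with a signed coefficient. The dictionary update
is atom-wise: the residual restricted to an atom's members is factored by
SVD and the leading right singular vector replaces the atom, with the sign
chosen so the members' coefficients sum positive (the SVD sign is
arbitrary; without this convention atoms can point away from their
cluster and corrupt the cosine assignment). Atoms that lose all members
are re-seeded from the worst-reconstructed vector. Initialization is
farthest-point in absolute cosine; iteration stops when assignments are
stable twice in a row or the error improvement falls below `tol`.
Diseases are assigned to the constellation maximizing plain (signed)
cosine, 1-based, ties to the lowest index.

On exact one-sparse data the algorithm recovers the planted atoms to
numerical precision with zero reconstruction error; on noisy planted
clusters it attains adjusted Rand index ≥ 0.8 against the truth; its final
objective matches or beats an alternating projection (spherical
k-means-style) oracle on the same objective. The baseline partition is
average-linkage agglomerative clustering on 1 − cosine cut at K clusters;
two partitions are compared by greedy largest-overlap matching with
upper-tail hypergeometric p-values.

## Individuals as points

A patient's trait vector is the diagnosis-count-weighted mean of their
disease vectors: with nᵢʷ occurrences of disease w in patient i,
Ē ᵢ = Σ_w nᵢʷ Eʷ / Σ_w nᵢʷ. It is order-invariant, scale-free in the
counts, and confined to the convex hull of the contributing disease
coordinates. Each of the 20 coordinates is treated as a quantitative
trait.

Phenotype association regresses each dimension trait on a min-max
normalized phenotype measure plus covariates (complete cases; collinear
covariates are dropped by a rank test). Height is included as a covariate
only for phenotypes flagged as spirometry-derived. The reported p is the
t-test on the phenotype coefficient; BH runs over the full
phenotype × dimension family.

## Genetic association

Variant QC keeps MAF > 0.01 and Hardy–Weinberg chi-square (1 df, on
rounded hard calls) p > 10⁻⁶. The scan regresses a dimension trait on
effect-allele dosage with covariates. Implementation: trait and dosages
are residualized on the covariate block (Frisch–Waugh), giving per-variant
slope, standard error and t-test with df = n − rank(covariates) − 1 —
algebraically identical to the full joint OLS fit, which the tests verify
to 10⁻⁹. Monomorphic variants yield NaN. Genome-wide significance is
p < 5×10⁻⁸ (strict inequality).

Significant variants are collapsed to lead loci greedily by ascending p
within each dimension: a variant joins an existing lead if it lies within
±5,000 bp on the same chromosome or its dosage r² with the lead exceeds
0.1; otherwise it becomes a new lead. Ties in p break by chromosome and
position so the output is row-order invariant.

Replication is directional: for each discovery association found in the
replication scan, the one-sided p is half the replication two-sided p if
the effect signs agree and one minus that otherwise (so sign-matched and
sign-opposed halves sum to 1); BH at 5% FDR over the tested set defines
replicated associations, and associations absent from the replication scan
are counted separately. Genomic control λ is the median association
chi-square divided by 0.4549 (the null median of χ²₁). Gene-set
enrichment takes the genes mapped from variants passing a suggestive
threshold (default 10⁻⁵) and tests each set by the upper hypergeometric
tail against a user-supplied background, BH-corrected across sets.

## Polygenic prediction

Risk scores are Sᵢ = Σⱼ Xᵢⱼ β̂ⱼ over effect-allele dosages. Weight rows
are reconciled against the genotype matrix: a weight whose effect allele
is the matrix's *other* allele contributes 2 − X; weights matching neither
allele or referencing absent variants are dropped with a logged tally, and
duplicate (variant, tag) weight rows are averaged at parse time. A
"universal" profile holds one score per embedding dimension (tagged
`dim1`…`dim20`), shared across targets.

Model evaluation draws, per repeat, `n_train_per_arm` cases and controls
without replacement, and disjoint test sets of `n_test_per_arm` each
(defaults 5,000/2,500, 100 repeats). Models: logistic regression (GLM) on
the features plus covariates, or a gradient-boosted classifier (500 trees,
depth 3, learning rate 0.05). Fit quality is Nagelkerke R² on the
training set — Cox–Snell R² rescaled by its maximum, against a
covariates-only logistic null — with the likelihood-ratio chi-square p
(df = number of features). For the boosted model the training
log-likelihood is computed from clipped predicted probabilities and
floored at the null's. Test performance is accuracy, PPV and NPV at the
0.5 probability threshold; degenerate prediction margins give NaN with a
warning. Reports carry the mean and empirical 2.5–97.5 percentile
interval over repeats. Constellation targets label a patient with every
constellation their distinct diseases map to; a case is a patient
carrying the target label.

## Synthetic cohorts

The generator is a category-mixture model with planted genetics, designed
once from the forward model (its parameters are not tuned to test
outcomes):

- **Vocabulary**: `n_diseases` split near-evenly into `n_categories`;
  every disease group has one diagnosis code.
- **Genotypes**: per-variant MAF ~ Uniform(0.05, 0.5), hard calls
  Binomial(2, p) — Hardy–Weinberg by construction.
- **Latent axes**: each individual's axis value is a weighted sum of
  standardized causal dosages plus Gaussian noise scaled so the genetic
  share matches the configured per-causal effect size.
- **Diagnoses**: category affinities are softmax(log Dirichlet base +
  `axis_loading` · latent · pattern), where each axis's pattern loads
  categories with centered ±1 signs; history lengths are
  1 + Poisson(mean − 1) and event dates accumulate uniform 7–180 day
  gaps.

Setting `axis_loading=0` severs the genotype→diagnosis pathway entirely,
giving exact null cohorts for calibration tests. With the default loading
the chain attenuates the latent axis into the embedding-derived traits by
a factor of roughly 0.73, so planted-power checks use effect sizes
comfortably above detection thresholds rather than marginal ones. All
stages derive their RNG streams from `(seed, role)` pairs, so vocabulary,
genotypes and cohort are independently reproducible, and fixture bundles
are byte-identical across runs.

## Calibration checks shipped with the package

The acceptance suite (`tests/test_acceptance.py`, reproducible via
`scripts/acceptance.py`) verifies: the reference worked example for
dimension ranking; the 4,200-test annotation family size; equivalence of
the rank-sum, hypergeometric, OLS and risk-score routines with brute-force
oracles at small sizes (10⁻⁹); type-I error 0.05 ± 0.02 and genomic
λ ∈ [0.95, 1.05] on a 20,000 × 500 null cohort; recovery of a planted
variant explaining 0.5% of a trait (non-centrality ≈ 100) at p < 5×10⁻⁸;
constellation recovery at ARI ≥ 0.8 with a within-category cosine margin
≥ 0.1; and a prediction harness that is calibrated under permuted labels
(accuracy 0.5 ± 0.02, R² ≈ 0) while detecting planted signal at
LR p < 10⁻⁶.
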