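# Methods

This note documents the models, numerical choices and limitations of the
`facedna` pipeline in enough detail to reproduce or audit it.

## Synthetic cohorts

The generator is the package's substitute for restricted human cohorts;
its defaults define the study conditions under which the pipeline is
tested.

**Genotypes.** Balding–Nichols structured allele frequencies: per SNP an
ancestral frequency `p ~ U(0.05, 0.5)`; for population `k` with
differentiation `F_k`, a frequency drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`. Study individuals receive Dirichlet
ancestry proportions (concentration 0.5 by default, i.e. noticeably
admixed; a concentration of 0 yields unadmixed one-hot assignments) and
genotypes `Binomial(2, q·P)`. The reference panel is unadmixed and
balanced across populations, so its PCA — the genomic-background space —
is shaped only by the panel, and study individuals are projected into it
(missing dosages imputed to the panel mean; plain centered PCA, no
per-SNP variance scaling). Defaults: 3 populations, `F = 0.15` each,
2,000 SNPs, 600 study individuals, 300 panel individuals, genotype
missingness 0. SNPs are drawn independently (no linkage), with positions
spread over chromosomes at 5–80 kb gaps.

**Covariates.** Sex is ±1 (+1 female, −1 male, balanced); age
`U(18, 70)` years; BMI `N(24.7, 3.5²)` kg·m⁻² clipped to [16, 45];
height/weight are derived so the BMI identity holds.

**Faces.** A bilaterally symmetric half-ellipsoid template with a midline
ridge (250 landmarks by default; first axis sagittal, bilateral pairs
declared in the template rather than inferred, so reflection relabeling
is exact). Each face is

```
template + Σ_f pred_{i,f} · scale_f · field_f + correlated noise + rigid motion
```

Effect fields are kernel-smoothed Gaussian draws on the template
(squared-exponential kernel over inter-landmark distances, bandwidth
0.25 template units), symmetrized, and normalized to unit per-coordinate
RMS; `scale_f` is therefore the RMS landmark displacement per standard
deviation of the predictor. Predictors: sex (±1), z-scored age and BMI,
centered ancestry proportions, standardized causal-SNP dosages. Residual
noise is Gaussian with the same spatial kernel (marginal SD 0.05 per
coordinate by default) — the real residual covariance of faces is
unknown, and this smooth-noise kernel is an explicit stand-in: it makes
the RV-based segmentation non-degenerate, but nothing about the true
spatial covariance of human faces should be read into it. A random
rotation, translation and log-normal scale jitter (SD 0.05) make the
Procrustes step non-trivial.

Default effect scales, as multiples of the noise SD: sex 0.5, ancestry
0.5 per population, age and BMI 0.2, each causal SNP 0.15 (10 causal SNPs
among the 2,000). These were chosen once so that injected effects sit
comfortably above the detection-power-0.9 point of the association scan
at the default sample sizes — dense landmark coverage aggregates small
per-landmark displacements into strong multivariate signal — while
leaving the classifiers imperfect enough that score fusion has work to
do. What passing tests show is therefore that the machinery recovers
known structured signal of realistic relative magnitude; they do not
certify performance on real faces, whose effect sizes, residual
covariance, and landmark registration errors are all outside this model.

## Shape spaces

**GPA.** Configurations are centered, scaled to unit centroid size and
rotated (proper rotations only, batch Kabsch) to the evolving mean, which
is renormalized each iteration; convergence when the mean moves < 1e-10,
max 100 iterations. Aligned shapes satisfy ‖centroid‖ < 1e-9 and unit
centroid size to 1e-9. Collinear (rank < 2) configurations are rejected.

**Symmetrization.** Each configuration is mirrored across the sagittal
plane with left/right labels swapped; originals and reflections are
superimposed jointly while the mean is symmetrized every iteration, which
makes each individual's symmetric component (average of its aligned
original and reflection) *exactly* mirror-symmetric rather than
approximately so. Asymmetry is discarded throughout.

**Segmentation.** The RV coefficient between every landmark pair of the
symmetrized sample gives an affinity matrix; a 2-way spectral cut
(symmetric normalized Laplacian, 2 smallest eigenvectors, row
normalization, k-means with 10 restarts, seeded) splits each segment,
recursively, with the affinity recomputed within each subtree (whether
the original pipeline re-computed per subtree or refined one global
embedding is not documented; per-subtree recomputation is our choice and
lets deeper cuts respond to local covariance). Segments with fewer than 4
landmarks stop splitting and pass their landmarks to their left child so
every level keeps exactly `2^l` slots; depth 5 gives 63 segments. The
child containing the lowest landmark index is always the left child,
making labels deterministic under a fixed seed.

**Per-segment PCA.** Each segment is superimposed afresh — independently
of its position in the face — flattened, and decomposed by SVD. The
retained PC count comes from Horn's parallel analysis: 100 column-wise
permutations, 95th-percentile threshold, retention stops at the first
eigenvalue that fails to beat its permuted counterpart, minimum one PC.
Caveat: per-segment GPA removes 7 similarity degrees of freedom, which
concentrates variance relative to column-permuted data; for segments with
few landmarks this inflates the retained count, so small-segment
retention should be read as conservative (more PCs kept than a flat
scree would suggest). Retained PCs explain a median ≈ 90 % of segment
variance at default conditions. A segment identical across individuals is
flagged (`zero_variance`), retains one PC by convention, and reports an
explained fraction of 0.

**Fit/transform.** The pipeline fits the whole shape model (GPA mean,
tree, per-segment means and bases, retention) on training individuals
only and projects validation/test faces into the frozen spaces, so no
gallery or probe information leaks into the phenotyping.

## Association

With a single feature variate the first canonical correlation equals the
multiple correlation of the feature with the segment's PC scores;
Wilks' Λ = 1 − r² and Rao's F is `(r²/(1−r²)) · (N−c−q−1)/q` with `q`
PCs and `c` covariates, right-tail p-value. Covariates are removed by
residualizing *both* the feature and the scores on them with an intercept
(partial CCA) — the original description says only that confounders were
corrected for; both-sides residualization is our documented choice and is
verified equivalent to pre-residualized CCA. p-values are invariant to
affine rescaling of the feature and orthogonal rotation of the scores.
Saturated tests (r → 1) are floored at the smallest positive double and
flagged.

The multiple-testing threshold is Benjamini–Yekutieli: with `m` tests and
`c(m) = Σ 1/k`, the largest sorted `p_(i) ≤ i·α/(m·c(m))` (α = 0.05).
One pooled threshold is computed per scan family — one over all
(non-SNP feature × segment) tests, one over all (SNP × segment) tests —
mirroring the single per-scan thresholds the method reports; pooling is
configurable.

The GWAS codes dosages additively, skips SNPs with MAF < 0.05 or constant
dosage, and residualizes on sex, z-scored age and BMI, and the first four
continuous genomic PCs. SNPs with missing dosages fall back to a
complete-case test (missingness is ignored during the scan; missing
genotypes only join the homozygous-major class later, at classification).
Significant SNPs are clumped greedily: the most significant unassigned
SNP seeds a locus; unassigned significant SNPs on the same chromosome
within 500 kb of any member *and* with LD r² > 0.5 against the seed join,
transitively; LD is the squared Pearson correlation of dosages
(seed-based rather than any-member-based — the description leaves this
open). The seed is the locus's peak SNP.

## Classifiers, fusion, evaluation

**Binarization.** Age threshold 30 years; BMI at the training-set median;
genomic PCs at 0; sex +1 → class 1. A value exactly at the threshold
falls in the lower class (the boundary convention is otherwise
unspecified). Features that end up single-class are dropped with a
warning. Peak SNPs are oriented so dosage counts the training cohort's
minor allele, then recoded dominant (0→0, 1→1, 2→1) and recessive (0→0,
1→0, 2→1); missing genotypes are assigned to the homozygous-major class.
A feature is deployed when at least one segment reaches the pooled FDRd
threshold; its input segments are those with `p ≤ 1e-3` (configurable;
the re-tested SNP recodings deploy per inheritance model under the same
rule).

**Classifier.** RBF-kernel SVM with class weights inversely proportional
to class frequencies; the kernel scale is the median pairwise-distance
heuristic, `γ = 1/(2·median²)` (the original used a toolbox default;
the median heuristic is our fixed, overridable choice and makes
predictions invariant to duplicated predictor columns). Posteriors come
from sigmoid (Platt-style) calibration fitted by 5-fold cross-validation
within the training set. Linear (logistic) and tree classifiers are
pluggable behind the same interface. Both classes need ≥ 5 training
instances.

**Matching and fusion.** A face's matching score for a feature is the
calibrated posterior of the probe's class (complement for class 0; 0.5
with a warning if the probe profile lacks the feature). The all-vs-all
validation sweep yields `n_val` genuine and `n_val(n_val−1)` imposter
vectors; the fuser is Gaussian naive Bayes with unbiased per-feature
variances floored at 1e-6, scores clipped to [1e-6, 1−1e-6], and priors
either empirical (default — heavily imposter-skewed, which shifts the
score scale but not ROC/CMC ranks) or uniform. Sum/min/max/product rules
are provided as baselines. At least 10 genuine examples are required.

**Evaluation.** Identification: probes rank the gallery by fused score;
ties get mid-ranks; rank-x% rate is the CMC at `ceil(x%·G)`.
Verification: ROC over all thresholds, trapezoidal tie-aware AUC (equal
to pairwise P(genuine > imposter) + ½ P(tie)), EER linearly interpolated
where the false-accept and false-reject fractions cross; a constant score
distribution is flagged degenerate with AUC 0.5. Random scores give
EER = AUC = 0.5 and rank-x% = x%. Metrics are invariant to strictly
monotone transforms of the scores.

**Partitioning.** A seeded shuffle assigns a training fraction (default
0.5, not printed in the original and therefore configurable) and splits
the remainder into three folds (sizes within ±1); each fold serves as
test set once while the other two train the fuser. Training, validation
and test id sets are disjoint by construction and asserted at run time.
All randomness flows from one master seed through named substreams, so
complete runs are bit-identical under the same seed.

## Default problem sizes

The default experiment — 600 individuals (300 training, three folds of
100), 250 landmarks, depth-5 segmentation, 2,000 SNPs with 10 causal,
300 panel individuals, 100 parallel-analysis permutations — was sized so
a complete run takes well under a minute on one CPU while still giving
every stage non-trivial work; the dense 7,000-landmark, multi-million-SNP
scale of real studies is reachable through configuration but is not the
default. Tests use further-reduced cohorts where the property under test
allows it.

## Known limitations

- No linkage disequilibrium between simulated SNPs beyond what population
  structure induces, so clumping on synthetic data mostly yields
  single-SNP loci; no pedigree/relatedness, no sequence-level simulation.
- The smooth residual-noise kernel is a stand-in (see above); facial
  texture, asymmetry and registration error are not modeled.
- Binarization of age/BMI/genomic PCs is deliberately crude (one
  threshold), matching the paradigm rather than maximizing information.
- Genomic-PC features are tested unadjusted; only the GWAS adjusts for
  covariates. Mixed-model/kinship correction and genotype imputation are
  out of scope.
- Parallel-analysis retention interacts with Procrustes degrees of
  freedom on very small segments (see above).
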