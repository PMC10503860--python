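# Methods

## Model

The pipeline treats a subject's cognitive trajectory as the sum of a
normal-aging component and a disease-acceleration component,

    score(t) = baseline + (aging_slope + acceleration) · t + ε,

with ADAS-Cog13 scores clipped to the instrument's 0–85 range and slopes
in points per year (365.25 days; times are stored internally in days from
baseline). The imaging model's job is to estimate the *aging* part of the
slope from structural MRI alone; what it cannot explain — the residual of
the measured slope on the predicted aging slope, after rank-based inverse
normal transformation of both — is the accelerated cognitive decline slope
used as the GWAS phenotype.

### Dual-loss Siamese network

Both volumes of a longitudinal pair pass through one shared embedding
network G_w. Training jointly minimizes

* MSE between the regression head's output on the *first* time point's
  embedding and the actual score there, and
* the contrastive loss L = (1−Y)·D² + Y·max(0, m−D)² on the Euclidean
  embedding distance D, with Y = 1 when |Δscore| exceeds the
  clinically-significant-change threshold.

The MSE term anchors the embedding to the cognitive scale and absorbs
baseline differences between subjects; the contrastive term shapes the
embedding geometry so that pairs with significant cognitive change are
separated by at least the margin m. The model is trained on cognitively
normal subjects only, so the learned score mapping reflects normal aging;
applied to the whole cohort, the difference of the head's predictions over
the pair's time gap, (ŷ(X_j) − ŷ(X_i))/Δt, is the predicted normal-aging
slope. Applying the *shared* head to each image independently is what
makes this well-defined: weight sharing guarantees identical images give
identical predictions and hence a zero slope.

The normalized predicted error (NPE) reported for validation pairs is the
first-time-point score error divided by the pair gap, (ŷ_i − y_i)/Δt,
summarized as mean ± sd. (A slope-error variant could be defined the same
way; the score-error form is the primary metric here.)

### Backbone and training

The network is written directly in numpy with hand-derived, finite-
difference-verified gradients. The backbone is a stack of non-overlapping
(kernel = stride = 2) 3D convolutions with leaky-ReLU activations,
followed by flattening and a dense layer to a fixed-length embedding; a
one-unit dense layer on the embedding is the regression head.
Design notes:

* *Non-overlapping convolutions* make the backward pass an exact
  reshape/matmul, which keeps CPU training fast and the implementation
  small; at the default depth of three layers there is no need for
  residual skips. Depth, widths, embedding size and patch size are all
  configurable (`HyperParams.conv_widths`, `embed_dim`, `patch_k`).
* *Flatten rather than global average pooling*: atrophy-like signal is
  regional, and pooling across the whole volume dilutes an 8³-voxel
  region by the full 32³ volume. Flattening keeps spatial location in the
  embedding.
* *Leaky ReLU (slope 0.01)*: at the learning rates appropriate for a
  small network, plain ReLU units can die irrecoverably; the leak keeps
  them trainable.
* *Target standardization*: regression targets are z-scored with
  training-split statistics and predictions are mapped back to ADAS
  points. Without this, a freshly initialized small network cannot reach
  the 0–85 output scale in few epochs at any reasonable learning rate.
  The logged MSE (and the validation-selection criterion MSE +
  contrastive) is therefore on the standardized scale.

Optimization follows the published protocol: Adam, mini-batches of 4
pairs, 200 epochs and initial learning rate 1e-4 with a step scheduler
multiplying by γ = 0.1 every 10 epochs, train/validation split 70/30 *by
subject* (floor(0.7·n) subjects train; 414 subjects give 289/125), and the
returned checkpoint is the epoch minimizing validation MSE + contrastive
loss. For the desk-scale *mini backbone* used in the tests (widths
8/16/32, embedding 16, 32³ inputs) the schedule is lr = 1e-2 for 30 epochs
with one decay at epoch 16 — a small network trains at learning rates two
orders larger than a 101-layer one, and 30 epochs must suffice on one CPU.
Volumes are min-max scaled to [0, 1] per volume before the network.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| match window | 45 | days | assessment ↔ scan linkage rule |
| pair gap | [6, 24] | months (30.4375 d) | stable-trend window, inclusive |
| min matched visits | 3 | — | "more than two visits" rule |
| change threshold for Y | 4.0 | ADAS points | commonly used clinically meaningful change; applied to \|Δscore\| |
| margin m | 1.0 | embedding units | minimum distance for different-class pairs |
| missingness / MAF / HWE / info | 0.02 / 0.01 / 1e-6 / 0.1 | — | standard variant QC |
| kinship cutoff | 0.0884 | — | second-degree relatives |
| LD pruning | 50 / 5 / 0.2 | variants / variants / r² | sliding-window greedy pruning |
| PCs | 10 | — | stratification adjustment |
| lead-SNP rules | 1e-5 / 0.6 / 0.1 / 250 | p / r² / r² / kb | candidate, clump, re-prune, merge |
| LD window for clumping | 1000 | kb | standard post-GWAS annotation default |

## Synthetic data: what it emulates, what it does not

The generator produces (a) per-subject linear trajectories with jittered
six-monthly visits, separable aging and acceleration components, and
tertile-based diagnoses from the realized accelerations so group contrasts
exist; (b) one volume per visit in which the *aging region's* mean
intensity is a linear function of the aging score component, the disjoint
*disease region* encodes the acceleration component, and the rest is flat
background, all under additive Gaussian noise; (c) Hardy–Weinberg
genotypes (two simulated haplotypes per subject) with optional LD blocks —
within a block each haplotype copies the previous variant's allele with a
configurable probability — and planted causal variants whose per-allele
effects (points/year) sum into the subject's acceleration. A single
integer seed drives three spawned generator streams (trajectories,
volumes, genotypes), so outputs are bit-reproducible.

Defaults are desk-scale but statistically sensible: 150 subjects, 3–6
visits, 32³ volumes (configurable up to 128×160×128), and 2,000 variants.
The panel size matters: at a few hundred variants the robust kinship
estimator's sampling noise (sd ≈ 0.04) crosses the 0.0884 relatedness
cutoff for truly unrelated pairs and genotype PCs align with individual
variants; at 2,000 variants both effects are negligible.

What passing tests therefore show: the pairing rules, losses, optimizer,
slope algebra, QC filters, kinship, pruning, PCs, association and clumping
behave exactly as specified, and the Siamese model can recover a
regionally-encoded linear aging signal from images of held-out subjects.
What they do not show: performance on real MRI — no anatomy, bias fields,
registration error, scanner effects, or nonlinear atrophy patterns are
simulated, and real AD and aging atrophy overlap spatially, which the
disjoint-region phantom deliberately avoids.

## Numerical choices

* Scan matching ties (two equidistant scans) go to the earlier scan.
* Month = 30.4375 days; pair-gap bounds inclusive on both ends.
* Inverse normal transform: Blom offset k = 3/8, average ranks for ties
  (deterministic; a seed-free choice in preference to random tie
  splitting); constant input is rejected as rank-degenerate.
* HWE: exact conditional test, summing probabilities of heterozygote
  counts no more probable than observed (with a 1+1e-12 relative guard
  against floating-point ties), computed in log space.
* Kinship: φ = (N_het,het − 2·N_opp-hom)/(N_het(i) + N_het(j)) over
  variants non-missing in both samples; diagonal fixed at 0.5.
* Relatedness removal is greedy: drop the sample with the most
  over-threshold partners; ties by higher missingness, then
  lexicographically larger id.
* LD pruning removes the later variant of an offending pair within the
  window; removal is permanent as the window slides.
* PCs: per-variant mean imputation of missing calls, standardized
  dosages, SVD; columns are orthonormal, ordered by eigenvalue, sign
  fixed so each column's largest-magnitude entry is positive.
* Association p-values use the finite-sample t distribution (df = n − k);
  rank-deficient per-variant designs are flagged, never silently dropped.
* Clumping is deterministic given the (p, chrom, pos) tie-break ordering
  and therefore invariant to input row order.
* Missing dosages are mean-imputed for PCs and r² only; MAF/HWE counts
  use observed calls; association is complete-case per variant.

## Open design points resolved here

* Whether pair labels Y derive from score change or diagnosis is left
  open by the protocol; score change (|Δ| ≥ 4 points) is used.
* The residualization producing the accelerated slope uses the predicted
  slope alone (no extra covariates); sex, age and PCs enter the GWAS
  models instead.
* PCs are computed after relatedness removal, on the analysis sample.
* Ancestry projection onto an external reference panel is replaced by
  PCs of the study sample itself; `compute_pcs` accepts any genotype set,
  so a reference projection can be wired in externally.
* The normalized-predicted-error ambiguity (score error vs slope error
  divided by time) is resolved in favor of the score-error form.

## Problem sizes

The test suite and `scripts/acceptance.py` run end-to-end on one CPU in
roughly one and two minutes respectively, using 60-subject cohorts with
32³ volumes for model training, 150 subjects × 2,000 variants for the full
pipeline, n = 300–500 with 1,000 variants for GWAS calibration, and ≤ 15
variants for clumping oracles. These sizes are the package's chosen
desk-scale study conditions; every stage accepts larger inputs.

## Known limitations

* The network is CPU-oriented; 101-layer-scale backbones at full
  128×160×128 resolution are configuration-accepted but impractical here.
* Loci spanning more than the 1,000-kb LD window are clumped in pieces.
* The HWE test is the two-sided exact test, not the mid-p variant.
* Kinship uses only the between-family (unrelated-population) estimator.
* GWAS power at the default 150-subject cohort is limited by design: the
  planted causal variant typically reaches suggestive (p ~ 1e-2–1e-4),
  not genome-wide, significance — detecting it at scale requires the
  cohort sizes of the real studies this pipeline models.
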