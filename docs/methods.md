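# Methods

## The model

`pathcor` estimates a *pathway coexpression network* (PCxN): a graph over
pathway gene sets in which an edge states that the expression activity of two
pathways co-varies across samples, beyond what their shared gene annotations
alone would produce, consistently across a heterogeneous collection of
expression experiments.

### Single-sample pathway activity

Let *X* be the *K* × *L* expression matrix of one background (genes ×
samples). Each column is replaced by its within-array ranks,

S_kl = rank of x_kl within column l, from 1 (lowest) to K (highest),

with ties receiving average ranks, so every column sums to K(K+1)/2 exactly.
Ranks put arrays with different dynamic ranges on a common scale and make
every downstream statistic invariant under monotone per-array distortions.
The activity of pathway *G* = {g₁, …, gₙ} in sample *l* is the mean rank of
its measured members,

E_l = (1/n) Σ_{g∈G} S_gl,

computed per experiment over that experiment's samples. Ranks are always
taken over the full gene universe; only the summary is restricted to the
pathway.

### Experiment-level correlation

Within one experiment with *n* samples, the association between two summary
vectors is a Spearman correlation, realized as the Pearson correlation of
the within-experiment ranks of the summaries. The empirical correlation
matrix *R* of the (2 or 3) rank-transformed, standardized summary vectors is
shrunk toward the identity target *T*,

R* = λ\*T + (1 − λ\*)R,  λ\* = Σ_{k≠l} Var(r_kl) / Σ_{k≠l} r_kl², clamped to [0, 1],

with the small-sample variance of each correlation estimated from the
standardized products w_k·w_l (the analytic-shrinkage framework for
correlation matrices). Shrinkage stabilizes estimates in small experiments
and sends near-zero correlations to exactly zero (λ\* = 1 when all r_kl ≈ 0;
the estimator also caps λ\* at 1 when the analytic solution exceeds it).

If the two gene sets are disjoint, PathCor(i, j) = r\*_ij with a two-sided
t-test on n − 2 degrees of freedom, t = r√(n−2)/√(1−r²). If they share
genes, the summary E_{i∩j} of the shared genes is added, the 3 × 3 matrix is
shrunk with a single common λ\*, and the first-order partial correlation

PathCor(i, j) = (r\*_ij − r\*_is r\*_js) / √((1 − r\*_is²)(1 − r\*_js²))

is tested on n − 3 degrees of freedom. Conditioning on the shared-gene
summary removes the association that redundant annotations manufacture out
of their common members.

### Aggregation across experiments

Experiment-level estimates are combined with fixed sample-size weights: the
global correlation is the Hunter–Schmidt weighted mean
r̄ = Σ nᵢrᵢ / Σ nᵢ, and global significance is the Liptak (weighted
Stouffer) combination

Y = Σ nᵢ Φ⁻¹(1 − pᵢ) / √(Σ nᵢ²),  p_c = 1 − Φ(Y),

with Φ the standard normal CDF and per-experiment p-values clamped into
[10⁻¹⁵, 1 − 10⁻¹⁵] before the quantile transform. Combined p-values over
all pathway pairs are adjusted with Benjamini–Hochberg FDR; an edge exists
when q < α (default α = 0.05). Query gene signatures are integrated as
extra nodes with the same estimator, and their p-values enter the *same* BH
universe as the pathway–pathway pairs, so adding a signature can only raise
(never lower) existing q-values.

### Annotation overlap

Separately from coexpression, annotation overlap is quantified by the
overlap coefficient o_GH = |G∩H| / min(|G|, |H|) (1 for nested sets, 0 for
disjoint ones — the property that makes redundant annotations conspicuous)
and tested with a one-sided Fisher's exact test on the 2 × 2 table of
(shared, unique-to-G, unique-to-H, neither) over the measured-gene
background, BH-adjusted across pairs.

## Validation harness

A structured gene set is repeatedly permuted and split into two sets —
disjoint halves, or overlapping sets from a stepping schema in which step
*t* applies a = ⌈t/2⌉ shrink and b = ⌊t/2⌋ shift operations to produce
s₁ = {1…n−a}, s₂ = {b+1…n} with n − a − b shared elements. On n = 126 the
steps t = 33, 78, 123 give overlap coefficients 93/109 ≈ 0.8532,
48/87 ≈ 0.5517 and 3/64 ≈ 0.0469; these three configurations are the
default step list (scaled proportionally for other set sizes). A step list
spanning the full range [1, n] is *not* the default because near t = 1 the
sets are nested and the shared-gene summary coincides with one of the
pathway summaries, making the conditioned estimate degenerate by
construction.

At every iteration a size-matched random gene set is split with identical
geometry as the paired negative control. Significant p-values for
structured splits count as true positives and for random splits as false
positives; sweeping the cutoff over the union of observed p-values yields a
ROC curve whose trapezoidal AUC equals the Mann–Whitney statistic of the
two p-value samples. Experiments in which a summary's ordering coincides
exactly with the shared-gene summary (a finite-sample event at high
overlap) carry no information about the conditioned association and are
skipped.

## Synthetic backgrounds

The generator plants coexpression modules with a Gaussian latent-factor
model: per sample, module factors f ~ N(0, C) for a user-chosen correlation
matrix C, and gene g in module m has x_g = loading·f_m + ε_g with
ε_g ~ N(0, noise_sd²); background genes are pure noise. Gaussian margins
suffice because the pipeline consumes only ranks. The generator emits one
gene set per module, plus confounded-pair fixtures: two annotations that are
each half pure-noise genes and half a common coexpressed block, so the raw
summary correlation is large while the generative dependence between the
unique parts is exactly zero.

What the generator does *not* emulate: array-specific artifacts, batch
effects, heavy-tailed intensity distributions, and — importantly — the
pervasive low-level gene–gene correlation of real transcriptomes. Passing
tests on these backgrounds demonstrate the estimator's calibration, power
and overlap-adjustment under a known truth, not performance on any
particular real compendium.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| α (edge FDR cutoff) | 0.05 | conventional; applied to BH-adjusted combined p |
| min experiment size | 5 samples | keeps df = n − 3 ≥ 2 for the conditioned t-test |
| min measured genes per set | 2 | a 1-gene set makes conditioning degenerate |
| probe collapse | mean over probes | deterministic, uses all probes; `max_mean` available |
| shrinkage | on (`pre`) | shrink the correlation matrix first, then condition; `off` for sensitivity checks |
| p-value clamp ε | 10⁻¹⁵ | keeps normal quantiles finite at p ∈ {0, 1} |
| benchmark steps | t/n = 33/126, 78/126, 123/126 | the three canonical overlap configurations |
| bin step (enrichment curve) | 10 | bins of 10, 20, 30, … most-correlated pathways |

Study-condition sizes used by the test suite (chosen once as a scaled-down
but structurally faithful regime): null calibration uses 2 000 disjoint
20-gene pairs in one 30-sample experiment over a 2 000-gene background;
parameter recovery uses two 40-gene modules with factor correlation 0.6 in
a 500-gene background over 20 experiments × 30 samples, 50 replicates;
confounded pairs use 10 unique + 10 shared genes over 5 experiments × 30
samples, 200 replicates; the split benchmark uses a single 126-gene module
(loading 1, noise 1) in a 5 000-gene background over 10 experiments × 30
samples, 100 iterations per case.

## Numerical and design choices

- **Spearman realization.** Summaries are means of ranks but not themselves
  ranks; each summary vector is rank-transformed within the experiment
  (average ties) before correlating, so r_raw is invariant under monotone
  transforms of either summary.
- **Shrink-then-condition.** The shrinkage target is the correlation
  matrix, so the 3 × 3 matrix is shrunk with one common λ\* and the partial
  correlation is computed from the shrunk entries. This keeps the 2- and
  3-variable paths symmetric; `shrink="off"` exposes the unshrunk
  alternative, under which the conditioning formula agrees with a
  residual-regression partial correlation to 10⁻¹⁰.
- **Overlap-case summaries** are computed over the *full* gene sets (not
  the non-shared remainders), matching the estimator's definition.
- **Degenerate conditioning.** If a summary's raw correlation with the
  shared-gene summary reaches 1 (nested annotations, or an exact ordering
  coincidence in a small experiment), the pair is skipped in that
  experiment with a logged reason rather than producing an unstable ratio.
- **Two-sided p-values** are combined directly by Liptak; directional
  consistency is carried by r̄, not by the combiner. A consequence worth
  knowing: an experiment whose estimate shrinks to exactly 0 contributes
  p = 1 and hence a large *negative* quantile (≈ −7.9 after clamping),
  which materially lowers the combined evidence. This is the estimator as
  defined, not a bug; it makes the pair-level λ\* clamp consequential in
  low-signal regimes.
- **Ties and determinism.** All orderings (edge tables, neighbor rankings,
  cluster leaves) break ties deterministically (q, then lexicographic ids);
  all randomness flows from explicit seeds.

## Known limitations

- The rank-based partial correlation retains a small *positive* bias when
  the conditioning summary is almost collinear with a pathway summary
  (raw correlation ≳ 0.95): ranking is monotone but nonlinear, so the
  regression on the ranked shared summary leaves shared curvature in both
  residual vectors. In confounded-pair simulations the adjustment removes
  ~98 % of the squared association but the residual median adjusted
  correlation (~0.15 at summary-overlap ~0.96) remains detectable in a
  minority of replicates once combined over experiments.
- Attenuation: gene-level noise and the rank transform attenuate the
  summary-level correlation below the planted factor correlation (≈ 0.34
  recovered for a planted 0.6 at the recovery study's sizes). A noise-free
  reference computed on the factors quantifies the rank/shrinkage part of
  the attenuation but cannot contain the gene-noise part by definition.
- Pair-level λ\* is noisy: with only two vectors, small empirical
  correlations clamp λ\* to 1 and the estimate to 0. The matrix-level λ\*
  of a full many-pathway background is far more stable.
- Fixed-weight meta-analysis only: no random-effects model or
  heterogeneity statistics; experiments are weighted by sample size alone.
- Gene identifiers are opaque strings; no namespace translation, no
  expression preprocessing (normalization is assumed done upstream).
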