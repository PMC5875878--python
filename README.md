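# pathcor

Pathway coexpression networks from heterogeneous multi-experiment gene
expression backgrounds, with correlations adjusted for shared gene
annotations.

Pathway databases describe biological processes as gene sets, but the
*relationships between* pathways are usually inferred only from shared
members — which conflates redundant annotations with genuinely coupled
biology. `pathcor` is for computational biologists who want a
coexpression-based map of pathway relationships: it scores each pathway in
each sample by the mean within-array expression rank of its member genes,
correlates pathway scores within each experiment using an
analytically-shrunk Spearman estimator, replaces the correlation by a
partial correlation conditioned on the shared-gene score whenever two
annotations overlap, aggregates across experiments (Hunter–Schmidt weighted
mean r̄ = Σnᵢrᵢ/Σnᵢ; Liptak combined p, Y = Σnᵢ Φ⁻¹(1−pᵢ)/√(Σnᵢ²)), and
connects two pathways when the BH-adjusted combined p-value passes the FDR
cutoff. Annotation overlap itself is reported alongside
(overlap coefficient o = |G∩H|/min(|G|,|H|), one-sided Fisher's exact test).

The package also ships:

- a **query** workflow that integrates an external gene signature as an
  extra network node (joint FDR with all pathway pairs) and ranks its most
  correlated pathways;
- a **validation harness** that splits a structured gene set into pairs
  with controlled overlap (a stepping schema: after step *t*, a = ⌈t/2⌉
  shrinks and b = ⌊t/2⌋ shifts give s₁ = {1…n−a}, s₂ = {b+1…n}) and
  benchmarks the estimator against size-matched random sets via ROC/AUC
  over p-value cutoffs;
- a **synthetic-data generator** planting latent-factor coexpression
  modules and shared-gene confounding, so the whole pipeline is testable
  with a known ground truth.

See `docs/methods.md` for the model, assumptions and design choices.

## Worked example

Simulate a background of 2 000 genes in 10 experiments of 30 samples, with
four 40-gene modules whose latent factors correlate at 0.45, then build the
network:

```sh
$ pathcor simulate --n-genes 2000 --experiments 10 --samples 30 \
    --modules 4 --module-size 40 --factor-correlation 0.45 --seed 7 --outdir sim
wrote 2000x300 background to sim

$ pathcor build --expression sim/expression.tsv --grouping sim/grouping.tsv \
    --gmt sim/pathways.gmt --outdir net
6 pairs, 2 significant edges -> net

$ head -4 net/edges.tsv | cut -f1-5
pathway_a       pathway_b       pathcor p_combined      q
module_3        module_4        0.345225441658  6.02207207422e-07       3.61324324453e-06
module_1        module_4        0.26616670639   0.0012769636704 0.0038308910112
module_1        module_3        0.300829876679  0.0467185439479 0.0913353708177
```

All C(4,2) = 6 pairs are estimated; `pathcor` is the aggregated correlation
r̄ (attenuated below the planted 0.45 by gene-level noise and the rank
transform), `p_combined` the Liptak-combined p-value across the 10
experiments, and `q` its BH adjustment — the first two pairs clear q < 0.05
and become edges (the third misses the cutoff in this noise realization).
The run also writes `overlap.tsv` (all pairs are annotation-disjoint here,
overlap coefficient 0) and a GraphML export of the significant subnetwork.

Benchmark a 40-gene module against random gene sets (splits at the scaled
canonical overlap steps plus the disjoint split):

```sh
$ head -1 sim/pathways.gmt | cut -f3- | tr '\t' '\n' > module1.txt
$ pathcor validate --expression sim/expression.tsv --grouping sim/grouping.tsv \
    --structured-set module1.txt --iterations 20 --seed 3 --outdir val
no_overlap: AUC = 1.0000
step_10: AUC = 1.0000
step_25: AUC = 1.0000
step_39: AUC = 1.0000
```

AUC = 1 means every structured split's combined p-value was smaller than
every random split's: the planted module is perfectly separable from noise
at these sizes, with or without overlap adjustment.

`pathcor query` integrates a gene-list signature and prints its top
correlated pathways; `pathcor cluster` writes an average-linkage dendrogram
of an edge table using 1 − |pathcor| as the distance.

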