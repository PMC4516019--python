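# Methods

This note documents the models, conventions and design choices behind
`confoundr`, and what its synthetic-data tests do and do not establish
about real data.

## Design reconstruction from read headers

Illumina FASTQ identifier lines come in two dialects. Pre-1.8 headers
(`@machine:lane:tile:x:y#index/read`) carry no run or flowcell field;
1.8+ headers (`@machine:run:flowcell:lane:tile:x:y read:filtered:control:index`)
carry all four batch-relevant fields. A *sequencing batch* is the
equivalence class of samples sharing `(machine, run, flowcell, lane)` —
a multiplexed single run on a single lane. Batch inference reads only
the first header of each FASTQ by default (all reads of a file share one
batch key; `scan_all` verifies this and errors on mixtures). With
pre-1.8 headers, batches degrade to `(machine, lane)`; run and flowcell
are recorded as empty strings — a documented limitation of the dialect,
not of the method.

Confounding between batch and a factor (species, tissue) is reported
three ways: the batch × level contingency table, the number of *pure*
batches and the fraction of samples in them, and Cramér's V
(chi-squared without continuity correction; a degenerate single-row or
single-column table is reported as V = 1 with a flag, since a
single-level grouping is vacuously confounded).

## Ortholog and annotation handling

One-to-one ortholog pairs are records whose last two columns (the
per-species group sizes) are both exactly `"1"` (*strict*). The *prefix*
mode reproduces a plausible command-line filtering slip — accepting any
last column that merely *begins* with `"1"` — and therefore admits
1-to-10+ groups, from which the first-listed gene is taken. Prefix
output is a superset of strict output by construction. Field splitting
is on arbitrary whitespace runs; declared group sizes inconsistent with
the gene lists are logged, not fatal.

Per-gene GC is computed over the union of all transcript exons
(overlapping and book-ended intervals merged per chromosome):
gc = (#G + #C) / (#A + #C + #G + #T), with ambiguity codes excluded from
numerator and denominator and soft-masked lowercase counted as valid —
strand is irrelevant because G+C is complement-closed. GTF coordinates
are 1-based inclusive throughout. Chromosome names are harmonized
against the FASTA via an optional rename map plus an automatic "chr"
prefix add/strip pass.

Matrix assembly resolves quantifier gene ids to common names through the
GC table. Retired identifiers are dropped; when several surviving ids
share a common name the first appearance in GC-table order wins. A gene
missing from a quant table contributes 0 (quantifiers emit explicit zero
rows, so absence usually signals identifier drift) with a warning. The
column sums of the quantifier's *full* output are captured once as the
library-size proxy and never recomputed after filtering.

## Normalization stack

Steps, in order, on raw fragment counts:

1. **Low-expression filter** — remove exactly `floor(0.30 · n_genes)`
   genes with the smallest total count (stable sort; ties keep row
   order). On 14,744 genes this removes 4,423; removing the 12
   mitochondrial genes afterwards leaves 10,309. `floor` rather than
   `ceil` is forced by that arithmetic.
2. **Mitochondrial removal** — a configured name list (the 12 planted
   `MT-*` genes in the synthetic study); mitochondrial reads were
   over-represented in the emulated libraries.
3. **Within-sample GC normalization** — default `full_quantile`: genes
   are stratified into 10 equal-occupancy GC bins and each bin's counts
   are quantile-matched to the column's pooled distribution (average
   ranks at ties); deterministic and rank-preserving within bins.
   `median` (bin nonzero-medians scaled to the global nonzero-median)
   and `loess` (lowess of log(count+0.5) on GC, residuals recentered)
   are selectable. Output is rounded and floored at 0 to stay
   count-like. Note that exact quantile matching makes the per-bin
   means equal to ~0.1%, so any residual "trend" across bins is
   numerical noise; the tests therefore assert a bin-mean spread bound
   rather than a correlation of near-tied values.
4. **TMM factors** — reference sample: 75th percentile of
   depth-scaled counts closest to the mean such percentile. For sample
   *k* vs reference *r* over genes positive in both:
   M = log2((y_k/N_k)/(y_r/N_r)), A = ½·log2((y_k/N_k)(y_r/N_r));
   genes in the top/bottom 30% of M or 5% of A are discarded (rank
   bounds `floor(n·f)+1 … n−floor(n·f)`, either criterion suffices);
   the factor is 2 to the precision-weighted mean of the surviving M,
   with delta-method weights
   w = [(N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r)]⁻¹. Fewer than 10
   survivors → factor 1 with a warning. Factors are rescaled to
   geometric mean 1. The implementation agrees with edgeR's
   `calcNormFactors(method="TMM")` to 1e-6 on test fixtures and with a
   scalar step-by-step recomputation to 1e-10. Scale invariance under a
   pure depth change is exact for M/A/trimming but only approximate
   (~1e-3) through the weights, as in edgeR.
5. **Depth normalization** — divide each column by its effective
   library size (proxy × TMM factor) and rescale by the mean effective
   size, keeping magnitudes count-like. All downstream diagnostics
   (correlations, standardized PCA) are invariant to this scale choice;
   per-million is available.
6. **log2(x + 1).**

## Empirical-Bayes batch adjustment

The model and estimation follow the standard parametric location/scale
batch-adjustment recipe. Per gene, the full design
[B batch indicators | dummy-coded covariates] is fit by least squares;
the grand mean is the batch-size-weighted average of the batch
coefficients (equivalently, batch effects obey a weighted zero-sum
constraint); the pooled variance divides by *n*. Standardized data keep
their per-batch deviations, from which per-batch per-gene means γ̂ and
variances δ̂² are taken. Hyperparameters come from the method of moments
across genes: a normal prior (γ̄, τ²) for locations and an inverse-gamma
(λ, θ) for scales, with the coupled updates

    γ* = (n_i τ² γ̂ + δ*² γ̄) / (n_i τ² + δ*²)
    δ*² = (θ + ½ Σ_j (Z_j − γ*)²) / (n_i/2 + λ − 1)

iterated until the maximum absolute change falls below `tol = 1e-4`
(configurable; `max_iter = 500`, non-convergence is an error; the
residual trace is recorded and is empirically non-increasing). The
corrected value is σ/δ*·(Z − γ*) + α + Xβ.

Conventions: **all** variance estimates divide by the number of
observations (pooled σ² by *n*, per-batch δ̂² by n_i). The divide-by-n
choice for δ̂² makes a single-batch adjustment an exact identity
(τ² = 0 so γ* = 0, and δ̂² ≡ 1 by construction); the n−1 convention
would instead shrink every gene by √((n−1)/n). Genes with exactly zero
sample variance are excluded from the EB machinery and pass through
bit-identical. Batches of size 1 are rejected (scale not estimable).
Only the parametric variant is implemented; there is no reference-batch
or mean-only mode.

The rank check is the package's central diagnostic: if any covariate
column lies in the span of the batch indicators (e.g. species when
every batch is single-species), the fit refuses with a message naming
the absorbed factor. No adjustment can separate perfectly collinear
batch and biology; the emulated study is correctable only because one
batch contained both species.

## Clustering diagnostics

PCA operates on the transposed matrix (samples as observations) after
removing genes with exactly zero variance, centering and scaling by the
(n−1)-denominator SD; variance fractions are squared singular values
over their sum, and component signs are fixed so each loading vector's
largest-magnitude entry is positive. The heatmap-style clustering
follows the common heatmap tool's default when handed a correlation
matrix: complete linkage on Euclidean distances *between the rows of
the correlation matrix*; 1−correlation and data-space Euclidean
distances, average and Ward linkage, and Spearman correlations are
offered as robustness variants. The agglomeration is implemented
directly (n ≤ a few dozen samples) with a deterministic tie rule: among
equal minimum distances, merge the lexicographically smallest cluster-id
pair. Agreement scores: ARI between a dendrogram cut and a label set,
and nearest-neighbor purity (fraction of samples whose most-correlated
other sample shares the label).

## The synthetic study

The generator emulates the study conditions: 26 samples = 13 tissues ×
2 species in five single-lane batches — two human-only lanes sharing
run and flowcell, two mouse-only lanes on two other machines, and one
mixed lane. Per-batch sample counts are not published, so the default
layout places the last two human tissues plus two mouse samples (one
sharing a tissue with a mixed-lane human) in the mixed batch
(5/6/4/5/6 samples). This choice is deliberate: a 2-sample mixed lane
holding only one tissue of each species makes that tissue's indicator
collinear with the batch (the model becomes rank-deficient), while many
cross-species same-tissue pairs in one lane would leave too few samples
whose nearest neighbor is same-species for the uncorrected data to
"cluster by species" at all. The default sits between: the design is
full-rank but near-singular (species-coefficient variance 1.55σ²), and
exactly two samples pair cross-species before correction.

Counts are negative-binomial with log2-scale mean
base + tissue + species + batch-location (+ batch-scaled residual
noise), multiplied by a per-sample exponential GC-bias curve and a
log-normal library-size factor. Defaults (log2 SDs): tissue 1.0,
species 0.5, batch 2.0, batch scale jitter 0.2 — a technically
dominated regime. The 12 mitochondrial genes receive a high baseline so
they rank in the top expression stratum. Free noise parameters are set
to technical-noise levels — NB dispersion 0.01 (near-Poisson, as for
lane-level technical variation) and residual log-noise SD 0.1 (~7% CV)
— because all biological structure is modeled explicitly; the
dispersion here is *not* biological replicate variance. This matters
quantitatively: the EB fit's covariate-coefficient noise scales with
the residual σ² times the near-singular design's variance inflation,
and at biological-replicate dispersions that estimation noise re-creates
species- and batch-shaped correlation blocks in the corrected data.
Even at the defaults, the post-correction 13-cluster tissue recovery is
marginal (the corrected matrix retains the genuine species effect plus
estimation noise); nearest-neighbor tissue purity is robustly 1.0
across seeds, while the cut-at-13 ARI comparison favors tissue at the
pinned seed but not at every seed. This mirrors the real reanalysis,
where batch correction left a residual species component (visible in a
later principal component) and tissue clustering was "considerable"
rather than perfect.

One property deserves emphasis: after correction, the standardized
species separation on PC1–PC2 does **not** halve when a genuine species
effect (SD 0.5) is planted — even an oracle that subtracts the true
batch effects leaves it intact, because a coherent two-group effect
across all genes dominates the leading components regardless of batch.
The separation *does* drop by ≥ 50% when species variance is purely a
batch artifact (species SD 0), which is the scenario the claim is
about; the test suite pins that regime.

What passing tests show — and don't. The generator's counts are NB with
a common dispersion, its GC bias is a one-parameter exponential curve,
and its effects are additive on the log scale with no gene-gene
correlation structure. Real libraries have gene-specific dispersions,
more complex GC and length biases, and correlated modules; numbers such
as "tissue NN purity 1.0" are statements about this model at these
effect sizes, not about any real dataset. Problem sizes in tests and in
`scripts/acceptance.py` (2,000 genes for pipeline runs; 14,744 only for
filter arithmetic) were chosen to keep the suite fast while leaving
every algorithmic path exercised; all pipeline behaviors are
size-independent by construction.

## Numerical conventions and degenerate inputs

- Filtering ties: stable sort by original row order.
- GC bins: equal-occupancy by stable GC rank; bins of unequal size by at
  most one gene.
- TMM: reference column included with factor 1 before geometric-mean
  rescaling; all-zero columns are errors.
- EB: degenerate across-gene spread of δ̂² collapses the inverse-gamma
  prior onto its mean (shape 1e12).
- Cramér's V: computed without Yates correction; degenerate tables
  flagged.
- PCA sign fix and the clustering tie rule exist purely to make outputs
  bit-reproducible.
- Every generator output is a pure function of its `SimConfig`,
  including the seed.
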